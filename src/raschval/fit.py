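"""Fit diagnostics: residuals, fit residuals, item-trait chi-square, PSI.

Every statistic here is defined on model-expected scores and variances at the
estimated person abilities, so it is agnostic to the calibration algorithm.

The cell-level standardized residual is

    z_ni = (x_ni - E[X_ni | theta_n]) / sqrt(Var[X_ni | theta_n]).

Item (person) fit residuals summarize the squared z over persons (items):
the sum S = sum z^2 is matched in its first two model-implied moments to a
scaled chi-square (Satterthwaite) and mapped to an approximate N(0, 1) scale
with the Wilson-Hilferty cube-root transform.  |fit residual| > 2.5 flags
misfit.  The item-trait interaction chi-square compares observed and expected
item scores across ability-ordered class intervals; person separation (PSI)
is the Rasch analogue of reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pcm import ItemParameters, PersonEstimates, _log_probs, _moments
from .scale import MISSING, ResponseMatrix

FIT_RESIDUAL_LIMIT = 2.5  # |fit residual| beyond this flags misfit


def default_class_intervals(n_persons: int) -> int:
    """3 strata for small samples, up to 10 as n grows (>= ~50 persons each)."""
    if n_persons <= 150:
        return 3
    return int(min(10, n_persons // 50))


@dataclass
class ResidualMatrix:
    """Person x item standardized residuals plus ability-ordered strata."""

    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    z: np.ndarray                 # nan where missing/degenerate
    expected: np.ndarray          # E[X | theta-hat]
    variance: np.ndarray          # Var[X | theta-hat]
    z4: np.ndarray                # model-implied E[z^4 | theta-hat] per cell
    leverage: np.ndarray          # h_ni = Var_ni / sum_i Var_ni (ability-fit leverage)
    class_interval: np.ndarray    # per-person stratum label 0..G-1
    n_intervals: int
    # exact moments conditional on the person's sufficient raw total:
    cond_mean_x: np.ndarray | None = None   # E[X | r]
    cond_var_x: np.ndarray | None = None    # Var[X | r]
    cond_mean_z2: np.ndarray | None = None  # E[z^2 | r]
    cond_var_z2: np.ndarray | None = None   # Var[z^2 | r]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.z)


def assign_class_intervals(
    theta: np.ndarray, n_intervals: int, min_size: int = 10
) -> np.ndarray:
    """Quantile strata of ability; ties stay together; small strata merged."""
    n = theta.size
    n_intervals = max(2, min(n_intervals, n // max(min_size, 1)) or 2)
    qs = np.quantile(theta, np.linspace(0, 1, n_intervals + 1)[1:-1])
    labels = np.searchsorted(qs, theta, side="right")
    # merge undersized strata into the nearer neighbour
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size <= 2 or counts.min() >= min_size:
            break
        k = uniq[np.argmin(counts)]
        pos = np.where(uniq == k)[0][0]
        target = uniq[pos - 1] if pos > 0 else uniq[pos + 1]
        labels[labels == k] = target
    # relabel contiguous 0..G-1
    uniq = np.unique(labels)
    remap = {u: g for g, u in enumerate(uniq)}
    return np.vectorize(remap.get)(labels)


def standardized_residuals(
    data: ResponseMatrix,
    items: ItemParameters,
    persons: PersonEstimates,
    *,
    n_class_intervals: int | None = None,
    min_stratum: int = 10,
) -> ResidualMatrix:
    """Standardized residuals at the estimated abilities, with strata attached.

    Cells with numerically zero conditional variance are set missing with a
    warning rather than producing infinities.
    """
    n, n_items = data.n_persons, data.n_items
    z = np.full((n, n_items), np.nan)
    e_mat = np.full((n, n_items), np.nan)
    v_mat = np.full((n, n_items), np.nan)
    z4 = np.full((n, n_items), np.nan)
    theta = persons.theta
    degenerate = 0
    for i, item in enumerate(data.spec.item_ids):
        thr = items.thresholds[items.index(item)]
        _, e, v, _, m4 = _moments(theta, thr)
        obs = data.values[:, i] != MISSING
        ok = obs & (v > 1e-10)
        degenerate += int((obs & ~ok).sum())
        z[ok, i] = (data.values[ok, i] - e[ok]) / np.sqrt(v[ok])
        e_mat[obs, i] = e[obs]
        v_mat[obs, i] = v[obs]
        z4[ok, i] = m4[ok] / v[ok] ** 2
    if degenerate:
        warnings.warn(
            f"{degenerate} cell(s) with ~zero conditional variance set missing",
            RuntimeWarning,
        )
    # leverage of the ability fit: the share of person n's information carried
    # by item i; residual variance shrinks by (1 - h) once theta is estimated
    with np.errstate(invalid="ignore"):
        total_info = np.nansum(v_mat, axis=1, keepdims=True)
        leverage = v_mat / np.where(total_info > 0, total_info, np.nan)
    g = n_class_intervals or default_class_intervals(n)
    labels = assign_class_intervals(theta, g, min_stratum)
    res = ResidualMatrix(
        tuple(data.persons),
        tuple(data.spec.item_ids),
        z,
        e_mat,
        v_mat,
        z4,
        leverage,
        labels,
        int(labels.max()) + 1,
    )
    (
        res.cond_mean_x,
        res.cond_var_x,
        res.cond_mean_z2,
        res.cond_var_z2,
    ) = _conditional_item_moments(data, items, persons, res)
    return res


def fit_residual(
    z_values: np.ndarray,
    z4_values: np.ndarray,
    leverage: np.ndarray | None = None,
    df_loss: float = 0.0,
) -> float:
    """Wilson-Hilferty normalized fit residual for one item or person.

    ``z_values``/``z4_values`` are the observed standardized residuals and the
    model-implied E[z^4] of the same cells.  The sum of squares is treated as
    a scaled chi-square with its model df: E[z^2] per cell is 1 - h (residual
    shrinkage from fitting the person ability, leverage h) and ``df_loss``
    further subtracts parameters estimated from exactly these cells (an item's
    own thresholds).  The moment-matched sum is cube-root transformed to an
    approximate N(0, 1) scale.  Returns nan (with a warning) for fewer than 3
    observed cells.
    """
    ok = ~np.isnan(z_values)
    n_obs = int(ok.sum())
    if n_obs < 3:
        warnings.warn("fewer than 3 observations; fit residual undefined", RuntimeWarning)
        return float("nan")
    w = np.ones(n_obs) if leverage is None else 1.0 - leverage[ok]
    s = float(np.sum(z_values[ok] ** 2))
    mean_s = max(float(np.sum(w)) - df_loss, 1.0)
    var_s = float(np.sum(np.clip(z4_values[ok] - 1.0, 1e-6, None) * w**2))
    nu = 2.0 * mean_s**2 / var_s
    c = 2.0 / (9.0 * nu)
    return float(((s / mean_s) ** (1.0 / 3.0) - (1.0 - c)) / np.sqrt(c))


def _wh_transform(s: float, mean_s: float, var_s: float) -> float:
    """Wilson-Hilferty cube-root normalization of a moment-matched sum of squares."""
    nu = 2.0 * mean_s**2 / max(var_s, 1e-12)
    c = 2.0 / (9.0 * nu)
    return float(((s / mean_s) ** (1.0 / 3.0) - (1.0 - c)) / np.sqrt(c))


def _conditional_item_moments(
    data: ResponseMatrix, items: ItemParameters, persons: PersonEstimates, res: ResidualMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-cell model moments conditional on the person's raw total.

    The raw total is sufficient for theta in the PCM, so conditioning on it is
    conditioning on the estimated ability.  P(x_i | total r) follows from the
    elementary-symmetric-function (polynomial-product) recursion:
    P(x_i = x | r) ~ p_i(x) * gamma_{-i}(r - x), with gamma_{-i} the score
    distribution of the remaining items.  Returns (E[X|r], Var[X|r],
    E[z^2|r], Var[z^2|r]) per observed cell (nan where missing).
    """
    n, n_items = data.n_persons, data.n_items
    out = [np.full((n, n_items), np.nan) for _ in range(4)]
    mask = data.mask
    thr_by_col = [items.thresholds[items.index(i)] for i in data.spec.item_ids]
    cache: dict[tuple, tuple] = {}
    for p in range(n):
        obs = np.where(mask[p])[0]
        if obs.size < 2:
            continue
        r = int(data.values[p, obs].sum())
        key = (mask[p].tobytes(), r)
        if key not in cache:
            theta = persons.theta[p]
            probs = [np.exp(_log_probs(theta, thr_by_col[i]))[0] for i in obs]
            # prefix/suffix polynomial products over the observed items
            k = obs.size
            prefix = [np.ones(1)] * (k + 1)
            for j in range(k):
                prefix[j + 1] = np.convolve(prefix[j], probs[j])
            suffix = [np.ones(1)] * (k + 1)
            for j in range(k - 1, -1, -1):
                suffix[j] = np.convolve(probs[j], suffix[j + 1])
            cells = np.empty((4, k))
            for j, i in enumerate(obs):
                gamma_minus = np.convolve(prefix[j], suffix[j + 1])
                e_i = res.expected[p, i]
                v_i = res.variance[p, i]
                xs = np.arange(probs[j].size)
                idx = r - xs
                ok = (idx >= 0) & (idx < gamma_minus.size)
                w = np.zeros(xs.size)
                w[ok] = probs[j][ok] * gamma_minus[idx[ok]]
                tot = w.sum()
                if tot <= 0:  # numerically unreachable total; fall back
                    cells[:, j] = (e_i, v_i, 1.0, 0.0)
                    continue
                w /= tot
                ex = float(w @ xs)
                vx = max(float(w @ xs**2) - ex**2, 0.0)
                d = (xs - e_i) ** 2 / max(v_i, 1e-12)
                m1 = float(w @ d)
                m2 = float(w @ d**2)
                cells[:, j] = (ex, vx, m1, max(m2 - m1**2, 0.0))
            cache[key] = cells
        cells = cache[key]
        for a in range(4):
            out[a][p, obs] = cells[a]
    return out[0], out[1], out[2], out[3]


def item_fit_residuals(res: ResidualMatrix) -> pd.DataFrame:
    """Per-item fit residuals (approximate N(0, 1) under the model).

    The sum of squared residuals per item is moment-matched against its exact
    model moments conditional on each person's sufficient raw total, then
    Wilson-Hilferty transformed.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, item in enumerate(res.item_ids):
            ok = ~np.isnan(res.z[:, i]) & ~np.isnan(res.cond_mean_z2[:, i])
            if ok.sum() < 3:
                fr = float("nan")
            else:
                s = float(np.sum(res.z[ok, i] ** 2))
                fr = _wh_transform(
                    s,
                    float(res.cond_mean_z2[ok, i].sum()),
                    float(res.cond_var_z2[ok, i].sum()),
                )
            rows.append((item, fr, abs(fr) > FIT_RESIDUAL_LIMIT if np.isfinite(fr) else False))
    return pd.DataFrame(rows, columns=["item", "fit_residual", "misfit"])


def person_fit_residuals(res: ResidualMatrix) -> pd.DataFrame:
    """Per-person fit residuals.

    The mean of the squared-residual sum is exact (conditional on the total);
    its variance uses the leverage approximation, since within-person
    covariances of z^2 would need every pairwise joint distribution.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for p, person in enumerate(res.person_ids):
            ok = ~np.isnan(res.z[p]) & ~np.isnan(res.cond_mean_z2[p])
            if ok.sum() < 3:
                fr = float("nan")
            else:
                s = float(np.sum(res.z[p, ok] ** 2))
                mean_s = float(res.cond_mean_z2[p, ok].sum())
                w = 1.0 - res.leverage[p, ok]
                var_s = float(np.sum(np.clip(res.z4[p, ok] - 1.0, 1e-6, None) * w**2))
                fr = _wh_transform(s, max(mean_s, 1e-6), var_s)
            rows.append((person, fr, abs(fr) > FIT_RESIDUAL_LIMIT if np.isfinite(fr) else False))
    return pd.DataFrame(rows, columns=["person", "fit_residual", "misfit"])


def item_trait_chisq(
    res: ResidualMatrix,
    data: ResponseMatrix,
    *,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, tuple[float, int, float]]:
    """Item-trait interaction chi-square per item and in total.

    Per item, class intervals contribute (sum of observed-minus-expected)^2 /
    (sum of variances), with the expectation and variance taken conditional
    on each person's sufficient raw total so the statistic is centred even
    for few-item analyses; strata with no observation for an item fold into
    their neighbour.  Per-item p-values are judged against the Bonferroni
    level alpha / I; the total statistic sums items, df = sum of per-item df.
    """
    n_items = len(res.item_ids)
    rows = []
    total = 0.0
    total_df = 0
    for i, item in enumerate(res.item_ids):
        obs = res.observed[:, i] & ~np.isnan(res.cond_mean_x[:, i])
        chis = []
        for g in range(res.n_intervals):
            sel = obs & (res.class_interval == g)
            if not sel.any():
                continue  # stratum empty for this item: folds into its neighbour
            diff = data.values[sel, i] - res.cond_mean_x[sel, i]
            den = float(res.cond_var_x[sel, i].sum())
            chis.append(float(diff.sum()) ** 2 / max(den, 1e-12))
        chi2 = float(np.sum(chis))
        df = max(len(chis) - 1, 1)
        p = float(stats.chi2.sf(chi2, df))
        rows.append((item, chi2, df, p))
        total += chi2
        total_df += df
    item_df = pd.DataFrame(rows, columns=["item", "chisq", "df", "p"])
    item_df["significant"] = item_df["p"] < alpha / n_items
    total_p = float(stats.chi2.sf(total, total_df))
    return item_df, (total, total_df, total_p)


def check_threshold_order(items: ItemParameters) -> list[str]:
    """Items whose thresholds are not strictly increasing (disordered)."""
    return [
        item
        for item, thr in zip(items.item_ids, items.thresholds)
        if thr.size > 1 and not np.all(np.diff(thr) > 0)
    ]


def category_curves(
    items: ItemParameters, theta_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Category characteristic curve data (long format) for plotting."""
    if theta_grid is None:
        lo = min(float(t.min()) for t in items.thresholds) - 2.0
        hi = max(float(t.max()) for t in items.thresholds) + 2.0
        theta_grid = np.linspace(lo, hi, 101)
    frames = []
    for item, thr in zip(items.item_ids, items.thresholds):
        p, *_ = _moments(theta_grid, thr)
        for x in range(p.shape[1]):
            frames.append(
                pd.DataFrame(
                    {"item": item, "category": x, "theta": theta_grid, "probability": p[:, x]}
                )
            )
    return pd.concat(frames, ignore_index=True)


def remove_misfitting_persons(
    data: ResponseMatrix,
    person_fit: pd.DataFrame,
    threshold: float = FIT_RESIDUAL_LIMIT,
    *,
    min_remaining: int = 10,
) -> tuple[ResponseMatrix, list[str]]:
    """Drop persons with |fit residual| beyond ``threshold``; report who."""
    fr = person_fit.set_index("person")["fit_residual"]
    removed = [p for p in data.persons if abs(fr.get(p, 0.0)) > threshold]
    if len(data.persons) - len(removed) < min_remaining:
        raise ValueError(
            f"removing {len(removed)} misfitting persons would leave fewer than "
            f"{min_remaining}"
        )
    if not removed:
        return data, []
    keep = [k for k, p in enumerate(data.persons) if p not in set(removed)]
    return data.subset_persons(keep), removed


def person_separation_index(persons: PersonEstimates) -> float:
    """PSI = (Var(theta-hat) - mean SE^2) / Var(theta-hat), extremes excluded.

    At most 1; can be negative when measurement error swamps the observed
    spread (reported as-is).
    """
    sel = ~persons.extreme
    if sel.sum() < 2:
        raise ValueError("need at least 2 non-extreme persons for PSI")
    var = float(np.var(persons.theta[sel], ddof=1))
    if var <= 1e-12:
        raise ValueError("zero variance of ability estimates; PSI undefined")
    return (var - float(np.mean(persons.se[sel] ** 2))) / var


@dataclass
class FitReport:
    """Bundle of one analysis run's fit evidence."""

    item_fit: pd.DataFrame          # item, location, se, fit_residual, chisq, df, p, ...
    person_fit: pd.DataFrame
    total_chisq: tuple[float, int, float]
    psi: float
    disordered_items: list[str]
    n_class_intervals: int
    summary: dict = field(default_factory=dict)


def fit_battery(
    data: ResponseMatrix,
    items: ItemParameters,
    persons: PersonEstimates,
    res: ResidualMatrix,
    *,
    alpha: float = 0.05,
) -> FitReport:
    """Assemble the per-run fit report (item/person fit, chi-square, PSI)."""
    ifit = item_fit_residuals(res)
    pfit = person_fit_residuals(res)
    chisq_df, total = item_trait_chisq(res, data, alpha=alpha)
    disordered = check_threshold_order(items)
    table = ifit.merge(chisq_df, on="item")
    table.insert(1, "location", items.locations)
    table.insert(2, "se", items.se_locations)
    table["ordered_thresholds"] = ~table["item"].isin(disordered)
    psi = person_separation_index(persons)
    summary = {
        "item_fit_mean": float(np.nanmean(ifit["fit_residual"])),
        "item_fit_sd": float(np.nanstd(ifit["fit_residual"], ddof=1)),
        "person_fit_mean": float(np.nanmean(pfit["fit_residual"])),
        "person_fit_sd": float(np.nanstd(pfit["fit_residual"], ddof=1)),
        "n_persons": data.n_persons,
        "n_items": data.n_items,
    }
    return FitReport(table, pfit, total, psi, disordered, res.n_intervals, summary)
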