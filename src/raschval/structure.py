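"""Residual structure: local dependence, DIF, dimensionality, shared variance.

Everything in this module consumes the person x item standardized-residual
matrix.  Under the Rasch model responses are conditionally independent given
ability, so the residuals of distinct items should be essentially
uncorrelated; clusters of elevated correlations indicate local dependence
(testlet structure or redundant items).  Group differences in the residuals
at matched ability indicate differential item functioning.  A dominant first
principal component whose sign pattern splits the items into two sets that
yield systematically different person measures indicates multidimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fit import ResidualMatrix
from .pcm import ItemParameters, PersonEstimates, estimate_persons
from .scale import ResponseMatrix

Q3_MARGIN = 0.2  # flag pairs this far above the mean residual correlation


@dataclass
class DependenceReport:
    """Item-pair residual correlations (Q3) and the mean + 0.2 screen."""

    q3: pd.DataFrame                  # items x items, unit diagonal, nan if sparse
    mean_q3: float
    threshold: float
    flagged_pairs: list[tuple[str, str, float]]

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flagged_pairs, columns=["item_a", "item_b", "correlation"])


def residual_correlations(
    res: ResidualMatrix, *, min_pairs: int = 20, margin: float = Q3_MARGIN
) -> DependenceReport:
    """Pairwise-complete Pearson correlations of residuals with the 0.2 rule.

    Pairs with fewer than ``min_pairs`` complete observations get a missing
    correlation and are excluded from the mean; flagged pairs (correlation
    above mean + ``margin``) come back sorted descending.
    """
    items = list(res.item_ids)
    n_items = len(items)
    if n_items < 3:
        raise ValueError("need at least 3 items for a residual-correlation screen")
    z = res.z
    q3 = np.eye(n_items)
    q3[q3 == 0] = np.nan
    for a in range(n_items):
        for b in range(a + 1, n_items):
            ok = ~np.isnan(z[:, a]) & ~np.isnan(z[:, b])
            if ok.sum() < min_pairs:
                continue
            za, zb = z[ok, a], z[ok, b]
            if za.std() < 1e-12 or zb.std() < 1e-12:
                continue
            q3[a, b] = q3[b, a] = float(np.corrcoef(za, zb)[0, 1])
    off = q3[np.triu_indices(n_items, 1)]
    valid = off[~np.isnan(off)]
    if valid.size == 0:
        raise ValueError("no item pair had enough complete observations")
    mean_q3 = float(valid.mean())
    threshold = mean_q3 + margin
    flagged = []
    for a in range(n_items):
        for b in range(a + 1, n_items):
            r = q3[a, b]
            if np.isfinite(r) and r > threshold:
                flagged.append((items[a], items[b], float(r)))
    flagged.sort(key=lambda t: -t[2])
    frame = pd.DataFrame(q3, index=items, columns=items)
    return DependenceReport(frame, mean_q3, threshold, flagged)


@dataclass
class DIFReport:
    """Two-way ANOVA DIF screen for one covariate across items."""

    covariate: str
    table: pd.DataFrame               # item, uniform_p, nonuniform_p, flags
    bonferroni_level: float


def dif_anova(
    res: ResidualMatrix,
    data: ResponseMatrix,
    covariate: str,
    *,
    alpha: float = 0.05,
    min_cell: int = 2,
) -> DIFReport:
    """Uniform and non-uniform DIF by two-way ANOVA on residuals.

    Per item the residuals are modelled on group, ability stratum (class
    interval) and their interaction with type-III (marginal) tests; the group
    main effect is uniform DIF, the interaction non-uniform DIF.  P-values
    are flagged at the Bonferroni level alpha / I.  Group x stratum cells
    with fewer than ``min_cell`` observations trigger a warning (the marginal
    tests tolerate imbalance).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    groups = data.covariates[covariate].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate!r} has a single level")
    n_items = len(res.item_ids)
    level = alpha / n_items
    rows = []
    for i, item in enumerate(res.item_ids):
        ok = ~np.isnan(res.z[:, i])
        df = pd.DataFrame(
            {
                "z": res.z[ok, i],
                "group": pd.Categorical(groups.to_numpy()[ok]),
                "stratum": pd.Categorical(res.class_interval[ok]),
            }
        )
        cells = df.groupby(["group", "stratum"], observed=False).size()
        if (cells < min_cell).any():
            warnings.warn(
                f"item {item!r}, covariate {covariate!r}: sparse group x stratum "
                f"cell(s); interaction test may be unstable",
                RuntimeWarning,
            )
        model = smf.ols(
            "z ~ C(group, Sum) * C(stratum, Sum)", data=df
        ).fit()
        try:
            an = anova_lm(model, typ=3)
            uniform_p = float(an.loc["C(group, Sum)", "PR(>F)"])
            nonuni_p = float(an.loc["C(group, Sum):C(stratum, Sum)", "PR(>F)"])
        except (ValueError, KeyError):
            uniform_p = nonuni_p = float("nan")
        rows.append((item, uniform_p, nonuni_p))
    table = pd.DataFrame(rows, columns=["item", "uniform_p", "nonuniform_p"])
    table["uniform_dif"] = table["uniform_p"] < level
    table["nonuniform_dif"] = table["nonuniform_p"] < level
    return DIFReport(covariate, table, level)


@dataclass
class DimensionalityReport:
    """PCA-of-residuals split and the independent-t-test verdict."""

    pc1_loadings: pd.Series
    positive_set: list[str]
    negative_set: list[str]
    t_values: np.ndarray
    n_tested: int
    prop_significant: float
    ci_lower: float
    unidimensional: bool
    n_excluded: int = 0
    subset_estimates: tuple[PersonEstimates, PersonEstimates] | None = field(
        default=None, repr=False
    )


def _wilson_lower(k: int, n: int, z: float = 1.959963984540054) -> float:
    if n == 0:
        return 0.0
    p = k / n
    denom = 1 + z**2 / n
    centre = p + z**2 / (2 * n)
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return max((centre - half) / denom, 0.0)


def unidimensionality_ttest(
    res: ResidualMatrix,
    data: ResponseMatrix,
    items: ItemParameters,
    *,
    alpha: float = 0.05,
) -> DimensionalityReport:
    """Independent-t-test check of unidimensionality.

    The first principal component of the residual correlation matrix splits
    the items by loading sign; person abilities are re-estimated on each
    subset with the full-calibration item parameters anchored, and each
    person is tested with t = (theta1 - theta2) / sqrt(se1^2 + se2^2) against
    a normal reference.  The scale passes as unidimensional when the
    significant fraction is <= alpha or the Wilson 95% lower bound is
    <= alpha.  Persons lacking responses on either subset are excluded from
    the denominator and counted.
    """
    # pairwise-complete residual correlations (works down to 2 items, where
    # the first component trivially opposes the pair)
    q3 = pd.DataFrame(res.z, columns=list(res.item_ids)).corr(min_periods=2).to_numpy()
    cm = np.where(np.isfinite(q3), q3, 0.0)
    np.fill_diagonal(cm, 1.0)
    cm = (cm + cm.T) / 2.0
    evals, evecs = np.linalg.eigh(cm)
    pc1 = evecs[:, -1]
    if pc1.sum() < 0:  # orient deterministically
        pc1 = -pc1
    loadings = pd.Series(pc1, index=list(res.item_ids))
    pos = [i for i, l in loadings.items() if l >= -1e-12]
    neg = [i for i, l in loadings.items() if l < -1e-12]
    if not pos or not neg:
        warnings.warn(
            "first residual component has single-signed loadings; "
            "verdict trivially unidimensional",
            RuntimeWarning,
        )
        return DimensionalityReport(loadings, pos, neg, np.empty(0), 0, 0.0, 0.0, True)
    if min(len(pos), len(neg)) < 2:
        warnings.warn(
            "a loading-sign subset has a single item; subset measures are noisy",
            RuntimeWarning,
        )
    est = []
    excluded = np.zeros(data.n_persons, dtype=bool)
    for subset in (pos, neg):
        sub = data.subset_items(subset)
        observed = sub.mask.any(axis=1)
        excluded |= ~observed
        est.append((sub, observed))
    usable = ~excluded
    thetas, ses = [], []
    sub_estimates = []
    for sub, _ in est:
        keep = np.where(usable)[0]
        pe = estimate_persons(sub.subset_persons(keep), items.subset(sub.spec.item_ids))
        sub_estimates.append(pe)
        thetas.append(pe.theta)
        ses.append(pe.se)
    t = (thetas[0] - thetas[1]) / np.sqrt(ses[0] ** 2 + ses[1] ** 2)
    crit = stats.norm.ppf(1 - alpha / 2)
    k = int(np.sum(np.abs(t) > crit))
    n_tested = t.size
    prop = k / n_tested if n_tested else 0.0
    ci_lo = _wilson_lower(k, n_tested)
    verdict = (prop <= alpha) or (ci_lo <= alpha)
    return DimensionalityReport(
        loadings,
        pos,
        neg,
        t,
        n_tested,
        float(prop),
        float(ci_lo),
        bool(verdict),
        int(excluded.sum()),
        (sub_estimates[0], sub_estimates[1]),
    )


def shared_variance(est_a: PersonEstimates, est_b: PersonEstimates) -> float:
    """Disattenuated shared variance of two ability estimates, in [0, 1].

    r^2 / (rel_a * rel_b) with rel = (Var(theta) - mean SE^2) / Var(theta):
    the squared correlation corrected for the unreliability of each measure,
    i.e. the fraction of common non-error variance.
    """
    if len(est_a) != len(est_b):
        raise ValueError("estimates must be paired")
    sel = ~(est_a.extreme & est_b.extreme)
    if sel.sum() < 10:
        raise ValueError("need at least 10 paired persons")
    ta, tb = est_a.theta[sel], est_b.theta[sel]
    var_a, var_b = np.var(ta, ddof=1), np.var(tb, ddof=1)
    rel_a = (var_a - np.mean(est_a.se[sel] ** 2)) / var_a
    rel_b = (var_b - np.mean(est_b.se[sel] ** 2)) / var_b
    if rel_a <= 0 or rel_b <= 0:
        raise ValueError(
            f"non-positive reliability (rel_a={rel_a:.3f}, rel_b={rel_b:.3f}); "
            "shared variance undefined"
        )
    r = float(np.corrcoef(ta, tb)[0, 1])
    return float(np.clip(r**2 / (rel_a * rel_b), 0.0, 1.0))
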