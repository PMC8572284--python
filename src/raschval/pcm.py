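"""Partial credit model: probabilities, item calibration, person measurement.

The partial credit model (PCM) gives person ``n`` on item ``i`` the category
probabilities

    P(X = x | theta) = exp(sum_{k<=x} (theta - delta_k)) /
                       sum_h exp(sum_{k<=h} (theta - delta_k)),   x = 0..m,

with item thresholds ``delta_1..delta_m`` on the same logit scale as the
person ability ``theta`` (the empty sum for x = 0 is 0).  Higher theta means
higher expected item scores; for limitation-scored scales that is "more
limitation".

Items are calibrated by marginal maximum likelihood (MML): an EM algorithm
integrates the latent ability over a normal distribution with fixed-node
Gauss-Hermite quadrature, estimating the thresholds together with the latent
mean and SD under the identification constraint that item locations (mean
threshold per item) sum to zero.  Persons are then measured by Warm's
weighted likelihood (WLE); zero and perfect raw scores get a maximum
likelihood estimate of a score adjusted inward by a configurable amount and
are flagged as extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .scale import MISSING, ResponseMatrix, ScaleError


class EstimationError(RuntimeError):
    """Raised when calibration preconditions fail or iteration diverges."""


# ---------------------------------------------------------------------------
# model probabilities and conditional moments
# ---------------------------------------------------------------------------

def _cumulative(thresholds: np.ndarray) -> np.ndarray:
    """Cumulative threshold sums c_x = sum_{k<=x} delta_k, with c_0 = 0."""
    t = np.asarray(thresholds, dtype=float)
    return np.concatenate(([0.0], np.cumsum(t)))


def _log_probs(theta, thresholds) -> np.ndarray:
    """Log category probabilities; theta may be scalar or 1-D (returns T x (m+1))."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    c = _cumulative(thresholds)
    x = np.arange(c.size)
    logits = theta[:, None] * x[None, :] - c[None, :]
    return logits - logsumexp(logits, axis=1, keepdims=True)


def category_probs(theta, thresholds) -> np.ndarray:
    """PCM category probability vector(s) of length m + 1.

    Scalar ``theta`` returns a 1-D vector; an array returns one row per value.
    Probabilities are non-negative and sum to one.
    """
    p = np.exp(_log_probs(theta, thresholds))
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return p[0]
    return p


def _moments(theta, thresholds):
    """(p, E, Var, mu3, mu4) of the item score at each theta (vectorized)."""
    p = np.exp(_log_probs(theta, thresholds))
    x = np.arange(p.shape[1], dtype=float)
    e = p @ x
    d = x[None, :] - e[:, None]
    var = np.einsum("tx,tx->t", p, d**2)
    mu3 = np.einsum("tx,tx->t", p, d**3)
    mu4 = np.einsum("tx,tx->t", p, d**4)
    return p, e, var, mu3, mu4


def expected_score(theta, thresholds):
    """Model-expected item score E[X | theta]; strictly increasing in theta."""
    _, e, *_ = _moments(theta, thresholds)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(e[0])
    return e


def score_variance(theta, thresholds):
    """Conditional score variance Var[X | theta] (= dE[X]/dtheta for the PCM)."""
    _, _, v, *_ = _moments(theta, thresholds)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(v[0])
    return v


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ItemParameters:
    """Calibrated PCM item side: thresholds, standard errors, latent moments."""

    item_ids: tuple[str, ...]
    thresholds: tuple[np.ndarray, ...]
    se_thresholds: tuple[np.ndarray, ...]
    latent_mean: float = 0.0
    latent_sd: float = 1.0

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def max_category(self) -> tuple[int, ...]:
        return tuple(len(t) for t in self.thresholds)

    @property
    def locations(self) -> np.ndarray:
        """Per-item location = mean of its thresholds (logits)."""
        return np.array([float(np.mean(t)) for t in self.thresholds])

    @property
    def se_locations(self) -> np.ndarray:
        # mean of threshold SEs in quadrature; off-diagonal covariances are
        # not retained, so this is an upper-bound style approximation
        return np.array(
            [float(np.sqrt(np.mean(se**2) / len(se))) for se in self.se_thresholds]
        )

    def index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(str(item_id))
        except ValueError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def subset(self, item_ids) -> "ItemParameters":
        idx = [self.index(i) for i in item_ids]
        return ItemParameters(
            tuple(self.item_ids[j] for j in idx),
            tuple(self.thresholds[j] for j in idx),
            tuple(self.se_thresholds[j] for j in idx),
            self.latent_mean,
            self.latent_sd,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for item, t, se in zip(self.item_ids, self.thresholds, self.se_thresholds):
            for k, (est, s) in enumerate(zip(t, se), start=1):
                rows.append((item, k, est, s))
        return pd.DataFrame(rows, columns=["item", "threshold", "estimate", "se"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, latent_mean: float = 0.0, latent_sd: float = 1.0):
        df = pd.read_csv(path)
        ids, thr, ses = [], [], []
        for item, grp in df.groupby("item", sort=False):
            grp = grp.sort_values("threshold")
            ids.append(str(item))
            thr.append(grp["estimate"].to_numpy(dtype=float))
            ses.append(grp["se"].to_numpy(dtype=float))
        return cls(tuple(ids), tuple(thr), tuple(ses), latent_mean, latent_sd)


@dataclass
class PersonEstimates:
    """Person abilities (logits) with standard errors and extreme-score flags."""

    person_ids: tuple[str, ...]
    theta: np.ndarray
    se: np.ndarray
    extreme: np.ndarray
    raw_total: np.ndarray

    def __len__(self) -> int:
        return len(self.person_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person": list(self.person_ids),
                "theta": self.theta,
                "se": self.se,
                "extreme": self.extreme,
                "raw_total": self.raw_total,
            }
        )


# ---------------------------------------------------------------------------
# item calibration (MML / EM with Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------

def _item_loglik_table(values_col, m, log_p):
    """Sum over persons of log P(x | theta_q) gathered per node. Unused cells skipped."""
    obs = values_col != MISSING
    return log_p[:, values_col[obs]].sum(axis=1), obs


def _newton_thresholds(delta, counts, theta_q, max_inner=30, tol=1e-10):
    """Maximize sum_{q,x} counts[q,x] log P(x | theta_q) over the thresholds.

    counts is the expected (Q x (m+1)) category-count table from the E-step.
    Newton with step-halving; gradient uses survivor probabilities
    S_q(k) = P(X >= k | theta_q).
    """
    m = delta.size
    n_q = counts.sum(axis=1)
    # observed cumulative counts R[q, k-1] = sum_{x>=k} counts[q, x]
    rev = counts[:, ::-1].cumsum(axis=1)[:, ::-1]
    robs = rev[:, 1:]

    def loglik(d):
        lp = _log_probs(theta_q, d)
        return float((counts * lp).sum())

    ll = loglik(delta)
    for _ in range(max_inner):
        p = np.exp(_log_probs(theta_q, delta))
        s = p[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]  # Q x m survivor probs
        grad = (n_q[:, None] * s - robs).sum(axis=0)
        # H[k,l] = sum_q n_q (S_q[max(k,l)] - S_q[k] S_q[l])
        smax = np.maximum.outer(np.arange(m), np.arange(m))
        h = np.einsum("q,qkl->kl", n_q, s[:, smax]) - np.einsum("qk,ql->kl", n_q[:, None] * s, s)
        h[np.diag_indices(m)] += 1e-10
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.diag(h), 1e-8)
        if not np.all(np.isfinite(step)):
            break
        lam = 1.0
        for _ in range(25):
            new = np.clip(delta + lam * step, -30.0, 30.0)
            ll_new = loglik(new)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        if ll_new < ll - 1e-9:
            break
        moved = np.max(np.abs(new - delta))
        delta, ll = new, ll_new
        if moved < tol:
            break
    return delta


def _initial_thresholds(values, max_category):
    """Adjacent-category log-odds starting values from marginal frequencies."""
    thresholds = []
    for i, m in enumerate(max_category):
        col = values[:, i]
        counts = np.bincount(col[col != MISSING], minlength=m + 1).astype(float) + 0.5
        d = np.log(counts[:-1] / counts[1:])
        thresholds.append(d - 0.0)
    return thresholds


def estimate_items(
    data: ResponseMatrix,
    *,
    n_quad: int = 41,
    max_iter: int = 500,
    tol: float = 1e-8,
    smoothing: float = 0.05,
    on_maxiter: str = "error",
) -> ItemParameters:
    """Calibrate PCM thresholds by marginal maximum likelihood.

    Parameters
    ----------
    n_quad
        Gauss-Hermite nodes for the normal latent distribution.
    max_iter, tol
        EM stops when the relative marginal log-likelihood change drops below
        ``tol``; after ``max_iter`` iterations behaviour follows ``on_maxiter``
        ("error" raises with diagnostics, "warn" returns the current solution).
    smoothing
        Total phantom-person mass spread over nodes and categories in the
        M-step.  Keeps thresholds finite when a category has no observations
        (routine for many-category testlet super-items); negligible at the
        sample sizes where calibration is meaningful.

    Identification: item locations are re-centred to sum to zero every
    iteration (the latent mean absorbs the shift).  Threshold standard errors
    come from the empirical (outer-product) information of the marginal
    per-person scores, with extreme-scoring persons excluded.
    """
    if data.n_items < 2:
        raise EstimationError("need at least 2 items to calibrate")
    values = data.values
    mask = data.mask
    keep = mask.any(axis=1)
    if not keep.all():
        values, mask = values[keep], mask[keep]
    n, n_items = values.shape
    max_cat = data.spec.max_category
    for i, item in enumerate(data.spec.item_ids):
        col = values[:, i]
        observed = np.unique(col[col != MISSING])
        if observed.size < 2:
            raise EstimationError(
                f"item {item!r} has fewer than 2 observed categories; cannot calibrate"
            )

    nodes, gh_w = np.polynomial.hermite_e.hermegauss(n_quad)  # N(0,1) nodes
    gh_w = gh_w / gh_w.sum()

    thresholds = _initial_thresholds(values, max_cat)
    mu, sigma = 0.0, 1.0
    ll_old = -np.inf
    obs_cols = [values[:, i] != MISSING for i in range(n_items)]

    for iteration in range(1, max_iter + 1):
        theta_q = mu + sigma * nodes  # quadrature nodes adapted to latent
        log_p_items = [_log_probs(theta_q, thresholds[i]) for i in range(n_items)]
        # log joint likelihood of each person at each node
        log_l = np.tile(np.log(gh_w)[None, :], (n, 1))
        for i in range(n_items):
            obs = obs_cols[i]
            log_l[obs] += log_p_items[i][:, values[obs, i]].T
        norm = logsumexp(log_l, axis=1)
        ll = float(norm.sum())
        post = np.exp(log_l - norm[:, None])  # n x Q posterior node weights

        # M-step: latent moments
        mu = float((post @ theta_q).mean())
        second = float((post @ theta_q**2).mean())
        sigma = float(np.sqrt(max(second - mu**2, 1e-6)))

        # M-step: thresholds per item from expected category counts
        for i in range(n_items):
            obs = obs_cols[i]
            counts = np.zeros((n_quad, max_cat[i] + 1))
            col = values[obs, i]
            pobs = post[obs]
            for x in range(max_cat[i] + 1):
                sel = col == x
                if sel.any():
                    counts[:, x] = pobs[sel].sum(axis=0)
            counts += smoothing * gh_w[:, None] / (max_cat[i] + 1)
            thresholds[i] = _newton_thresholds(thresholds[i], counts, theta_q)

        # identification: mean item location 0, latent mean absorbs the shift
        shift = float(np.mean([np.mean(t) for t in thresholds]))
        thresholds = [t - shift for t in thresholds]
        mu -= shift

        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    else:
        msg = (
            f"MML did not converge in {max_iter} iterations "
            f"(last log-likelihood {ll:.6f}, relative change "
            f"{abs(ll - ll_old) / (abs(ll) + 1.0):.3e})"
        )
        if on_maxiter == "error":
            raise EstimationError(msg)
        warnings.warn(msg, RuntimeWarning)

    se = _threshold_ses(values, mask, thresholds, mu, sigma, nodes, gh_w)
    return ItemParameters(
        tuple(data.spec.item_ids),
        tuple(np.asarray(t, dtype=float) for t in thresholds),
        tuple(se),
        mu,
        sigma,
    )


def _threshold_ses(values, mask, thresholds, mu, sigma, nodes, gh_w):
    """Empirical-information SEs of the thresholds (extreme persons excluded)."""
    n, n_items = values.shape
    theta_q = mu + sigma * nodes
    max_total = np.array([mask[p] @ np.array([t.size for t in thresholds]) for p in range(n)])
    totals = np.where(mask, values, 0).sum(axis=1)
    non_extreme = (totals > 0) & (totals < max_total)

    log_l = np.tile(np.log(gh_w)[None, :], (n, 1))
    log_p_items = [_log_probs(theta_q, t) for t in thresholds]
    for i in range(n_items):
        obs = mask[:, i]
        log_l[obs] += log_p_items[i][:, values[obs, i]].T
    post = np.exp(log_l - logsumexp(log_l, axis=1, keepdims=True))

    sizes = [t.size for t in thresholds]
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    scores = np.zeros((n, offsets[-1]))
    for i in range(n_items):
        m = sizes[i]
        p = np.exp(log_p_items[i])
        s = p[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]  # Q x m
        obs = mask[:, i]
        ind = values[obs, i][:, None] >= np.arange(1, m + 1)[None, :]
        # Fisher identity: marginal score = posterior mean of complete score
        scores[obs, offsets[i]:offsets[i + 1]] = post[obs] @ s - ind
    sc = scores[non_extreme]
    info = sc.T @ sc
    cov = np.linalg.pinv(info, rcond=1e-10)
    diag = np.clip(np.diag(cov), 0.0, None)
    se = np.sqrt(diag)
    return [se[offsets[i]:offsets[i + 1]] for i in range(n_items)]


# ---------------------------------------------------------------------------
# person measurement (WLE)
# ---------------------------------------------------------------------------

def _test_moments(theta: float, thr_list):
    """Sum over items of (E, Var, mu3) at scalar theta."""
    e = v = j = 0.0
    for t in thr_list:
        _, ei, vi, m3, _ = _moments(theta, t)
        e += ei[0]
        v += vi[0]
        j += m3[0]
    return e, v, j


def _solve_monotone(fun, lo=-12.0, hi=12.0):
    flo, fhi = fun(lo), fun(hi)
    for _ in range(6):
        if flo * fhi <= 0:
            break
        lo, hi = lo * 1.5, hi * 1.5
        flo, fhi = fun(lo), fun(hi)
    if flo * fhi > 0:  # flat likelihood; return the better endpoint
        return lo if abs(flo) < abs(fhi) else hi
    return brentq(fun, lo, hi, xtol=1e-10)


def estimate_persons(
    data: ResponseMatrix,
    items: ItemParameters,
    *,
    method: str = "wle",
    extreme_adjust: float = 0.3,
) -> PersonEstimates:
    """Measure person abilities with item parameters held fixed.

    Non-extreme persons get Warm's weighted likelihood estimate (the ML score
    equation plus the bias-correction term I'/(2I)); persons at a zero or
    perfect raw total get the ML estimate of the total adjusted inward by
    ``extreme_adjust`` score points and are flagged.  SE = 1 / sqrt(I(theta)).
    Responses to items absent from the calibration are ignored; a person with
    no observed calibrated item raises an error.
    """
    idx = [items.index(i) if str(i) in items.item_ids else None for i in data.spec.item_ids]
    cols = [c for c, j in enumerate(idx) if j is not None]
    thr_all = [items.thresholds[idx[c]] for c in cols]
    values = data.values[:, cols]
    mask = values != MISSING
    m_vec = np.array([t.size for t in thr_all])

    n = data.n_persons
    theta = np.empty(n)
    se = np.empty(n)
    extreme = np.zeros(n, dtype=bool)
    totals = np.where(mask, values, 0).sum(axis=1)

    cache: dict[tuple, tuple[float, float, bool]] = {}
    for p in range(n):
        obs = mask[p]
        if not obs.any():
            raise EstimationError(
                f"person {data.persons[p]!r} has no responses on calibrated items"
            )
        key = (obs.tobytes(), int(totals[p]))
        if key in cache:
            theta[p], se[p], extreme[p] = cache[key]
            continue
        thr = [t for t, o in zip(thr_all, obs) if o]
        r = float(totals[p])
        r_max = float(m_vec[obs].sum())
        if r <= 0 or r >= r_max:
            extreme_p = True
            target = extreme_adjust if r <= 0 else r_max - extreme_adjust

            def score(th, target=target, thr=thr):
                e, _, _ = _test_moments(th, thr)
                return target - e

        else:
            extreme_p = False
            if method == "mle":

                def score(th, r=r, thr=thr):
                    e, _, _ = _test_moments(th, thr)
                    return r - e

            else:

                def score(th, r=r, thr=thr):
                    e, v, j = _test_moments(th, thr)
                    return r - e + j / (2.0 * max(v, 1e-12))

        th_hat = _solve_monotone(score)
        _, info, _ = _test_moments(th_hat, thr)
        se_p = 1.0 / np.sqrt(max(info, 1e-12))
        cache[key] = (th_hat, se_p, extreme_p)
        theta[p], se[p], extreme[p] = th_hat, se_p, extreme_p

    return PersonEstimates(tuple(data.persons), theta, se, extreme, totals.astype(int))
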