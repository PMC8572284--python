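"""Raw-total to interval-score conversion tables.

When the partial credit model fits, the raw total score is sufficient for the
latent ability, so a complete-response raw total maps one-to-one onto a logit
value through the test characteristic curve (TCC): theta(r) solves
sum_i E[X_i | theta] = r.  The logit column is then rescaled affinely to
0-100 with the endpoints anchored exactly (0 at raw 0, 100 at the maximum
total), preserving the interval-scale property.  Zero and perfect totals have
no finite maximum-likelihood value; they use the conventional score
adjustment (0.3 by default) pulled inward before inversion, which only shapes
the extreme theta entries, never the 0/100 anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .pcm import ItemParameters, _moments
from .scale import ResponseMatrix


@dataclass
class ConversionTable:
    """Raw score -> (theta logits, 0-100 interval score) lookup."""

    table: pd.DataFrame               # columns: raw_score, theta, scaled
    item_ids: tuple[str, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, item_ids=(), provenance="imported"):
        df = pd.read_csv(path)
        required = {"raw_score", "theta", "scaled"}
        if not required.issubset(df.columns):
            raise ValueError(f"conversion table needs columns {sorted(required)}")
        return cls(df[["raw_score", "theta", "scaled"]].copy(), tuple(item_ids), provenance)


def _tcc(theta: float, thresholds: list[np.ndarray]) -> float:
    return float(sum(_moments(theta, t)[1][0] for t in thresholds))


def build_conversion_table(
    items: ItemParameters,
    *,
    extreme_adjust: float = 0.3,
    tol: float = 1e-8,
    provenance: str = "",
) -> ConversionTable:
    """Invert the test characteristic curve at every raw total.

    Produces one row per raw score 0..sum(m_i); theta and the scaled column
    are strictly increasing, with scaled(0) = 0 and scaled(max) = 100 exactly.
    Assumes complete responses on the calibrated items.
    """
    thresholds = list(items.thresholds)
    max_raw = int(sum(t.size for t in thresholds))
    targets = np.arange(max_raw + 1, dtype=float)
    targets[0] = extreme_adjust
    targets[-1] = max_raw - extreme_adjust

    lo, hi = -40.0, 40.0
    thetas = np.empty(max_raw + 1)
    for r, target in enumerate(targets):
        f = lambda th: _tcc(th, thresholds) - target  # noqa: E731
        a, b = lo, hi
        fa, fb = f(a), f(b)
        while fa > 0:
            a *= 1.5
            fa = f(a)
        while fb < 0:
            b *= 1.5
            fb = f(b)
        thetas[r] = brentq(f, a, b, xtol=tol)
    if not np.all(np.diff(thetas) > 0):
        raise RuntimeError("test characteristic curve inversion produced non-monotone theta")
    scaled = 100.0 * (thetas - thetas[0]) / (thetas[-1] - thetas[0])
    scaled[0], scaled[-1] = 0.0, 100.0
    table = pd.DataFrame(
        {"raw_score": np.arange(max_raw + 1), "theta": thetas, "scaled": scaled}
    )
    return ConversionTable(table, tuple(items.item_ids), provenance)


def apply_conversion(data: ResponseMatrix, table: ConversionTable) -> pd.DataFrame:
    """Look up each person's interval score by raw total.

    Only persons with complete responses on the table's items get a score;
    incomplete persons get missing values (the table assumes completeness).
    """
    if table.item_ids:
        sub = data.subset_items([i for i in table.item_ids])
    else:
        sub = data
    totals = sub.total_scores()
    complete = sub.mask.all(axis=1)
    max_raw = int(table.table["raw_score"].max())
    if (totals[complete] > max_raw).any():
        raise ValueError("raw total outside the conversion table's range")
    lookup = table.table.set_index("raw_score")
    theta = np.full(len(totals), np.nan)
    scaled = np.full(len(totals), np.nan)
    idx = np.where(complete)[0]
    theta[idx] = lookup.loc[totals[idx], "theta"].to_numpy()
    scaled[idx] = lookup.loc[totals[idx], "scaled"].to_numpy()
    return pd.DataFrame(
        {
            "person": list(data.persons),
            "raw_score": np.where(complete, totals, pd.NA),
            "theta": theta,
            "interval_score": scaled,
        }
    )
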