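"""Synthetic polytomous response data with controllable model violations.

The generator draws from a generalized partial credit model with three
violation knobs, each mapped to the diagnostic that should detect it:

* **testlets** — person-specific normal effects shared by the member items of
  a cluster (bifactor-style).  They induce exactly the within-cluster positive
  residual correlations that the local-dependence screen (Q3) targets.
* **uniform DIF** — a constant logit offset added to an item's difficulty for
  one level of a binary covariate; targeted by the residual two-way ANOVA.
* **discrimination** ``a_i != 1`` — generalized-PCM slopes; under-discriminating
  items (a < 1) tend to positive fit residuals, over-discriminating to
  negative, which is what the item fit-residual statistic flags.

With all knobs at their neutral values the generator reduces to a pure PCM
with a normal latent trait, so estimator and generator can serve as mutual
oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .scale import MISSING, ResponseMatrix, ScaleSpec, dash_spec


@dataclass(frozen=True)
class ItemSpec:
    """Generating side of one item: thresholds (length m) and GPCM slope."""

    thresholds: tuple[float, ...]
    discrimination: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        if self.discrimination < 0:
            raise ValueError("discrimination must be >= 0")


@dataclass(frozen=True)
class TestletSpec:
    """Items sharing a person-specific normal effect with SD ``effect_sd``."""

    __test__ = False  # not a test class, despite the name

    name: str
    members: tuple[str, ...]
    effect_sd: float

    def __post_init__(self) -> None:
        if self.effect_sd < 0:
            raise ValueError("testlet effect SD must be >= 0")


@dataclass(frozen=True)
class DIFSpec:
    """Uniform DIF: ``offset`` logits of extra difficulty for ``level`` of ``covariate``."""

    item: str
    covariate: str
    level: str
    offset: float


@dataclass
class SimulationConfig:
    """Full description of one simulated dataset.

    ``covariates`` maps a covariate name to ``{level: probability}``;
    ``missing`` maps item ids to independent missingness probabilities.
    """

    n_persons: int
    items: dict[str, ItemSpec]
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    testlets: tuple[TestletSpec, ...] = ()
    dif: tuple[DIFSpec, ...] = ()
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    missing: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 2 or len(self.items) < 2:
            raise ValueError("need at least 2 persons and 2 items")
        if self.theta_sd < 0:
            raise ValueError("theta_sd must be >= 0")
        ids = set(self.items)
        for t in self.testlets:
            unknown = set(t.members) - ids
            if unknown:
                raise ValueError(f"testlet {t.name!r} references unknown items {sorted(unknown)}")
        for d in self.dif:
            if d.item not in ids:
                raise ValueError(f"DIF references unknown item {d.item!r}")
            if d.covariate not in self.covariates:
                raise ValueError(f"DIF references unknown covariate {d.covariate!r}")
            if d.level not in self.covariates[d.covariate]:
                raise ValueError(f"DIF level {d.level!r} not a level of {d.covariate!r}")
        for name, levels in self.covariates.items():
            p = np.array(list(levels.values()), dtype=float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"covariate {name!r} probabilities must be >= 0 and sum to 1")
        for item, p in self.missing.items():
            if item not in ids:
                raise ValueError(f"missingness references unknown item {item!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing probability for {item!r} outside [0, 1]")

    def scale_spec(self) -> ScaleSpec:
        tmap = {t.name: t.members for t in self.testlets} or None
        return ScaleSpec(
            tuple(self.items),
            tuple(len(s.thresholds) for s in self.items.values()),
            tuple(self.missing.get(i, 0.0) > 0.25 for i in self.items),
            None,
            tmap,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


@dataclass
class SimulationTruth:
    """Generating quantities kept for recovery checks."""

    theta: np.ndarray
    thresholds: dict[str, np.ndarray]
    testlet_effects: dict[str, np.ndarray]
    dif: tuple[DIFSpec, ...]
    misfit_items: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"theta": self.theta})
        for name, eff in self.testlet_effects.items():
            df[f"testlet_{name}"] = eff
        return df


def _gpcm_sample(rng, eff_theta: np.ndarray, thresholds: np.ndarray, a: float) -> np.ndarray:
    """Draw GPCM categories for a vector of effective abilities."""
    c = np.concatenate(([0.0], np.cumsum(thresholds)))
    x = np.arange(c.size)
    logits = a * (eff_theta[:, None] * x[None, :] - c[None, :])
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(eff_theta.size)
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def simulate(config: SimulationConfig) -> tuple[ResponseMatrix, SimulationTruth]:
    """Generate one dataset; the same config (incl. seed) is bit-reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    theta = config.theta_mean + config.theta_sd * rng.standard_normal(n)

    cov = {}
    for name, levels in config.covariates.items():
        labels = list(levels)
        cov[name] = rng.choice(labels, size=n, p=list(levels.values()))
    covariates = pd.DataFrame(cov)

    effects = {t.name: t.effect_sd * rng.standard_normal(n) for t in config.testlets}
    in_testlet = {m: t.name for t in config.testlets for m in t.members}
    dif_by_item: dict[str, list[DIFSpec]] = {}
    for d in config.dif:
        dif_by_item.setdefault(d.item, []).append(d)

    item_ids = list(config.items)
    values = np.empty((n, len(item_ids)), dtype=np.int64)
    for i, item in enumerate(item_ids):
        ispec = config.items[item]
        eff = theta.copy()
        tl = in_testlet.get(item)
        if tl is not None:
            eff += effects[tl]
        for d in dif_by_item.get(item, ()):
            eff -= d.offset * (covariates[d.covariate].to_numpy() == d.level)
        values[:, i] = _gpcm_sample(rng, eff, np.asarray(ispec.thresholds), ispec.discrimination)
    for item, p_miss in config.missing.items():
        if p_miss > 0:
            i = item_ids.index(item)
            values[rng.random(n) < p_miss, i] = MISSING

    persons = tuple(f"p{k + 1}" for k in range(n))
    covariates.index = list(persons)
    data = ResponseMatrix(persons, config.scale_spec(), values, covariates)
    truth = SimulationTruth(
        theta,
        {i: np.asarray(config.items[i].thresholds) for i in item_ids},
        effects,
        config.dif,
        tuple(i for i, s in config.items.items() if s.discrimination != 1.0),
    )
    return data, truth


def evenly_spread_items(
    n_items: int,
    n_categories: int = 5,
    *,
    location_range: tuple[float, float] = (-1.2, 1.2),
    threshold_spread: float = 1.0,
    prefix: str = "item",
) -> dict[str, ItemSpec]:
    """Simple item bank: locations evenly spaced, thresholds evenly spread."""
    m = n_categories - 1
    locs = np.linspace(*location_range, n_items)
    steps = threshold_spread * (np.arange(m) - (m - 1) / 2.0)
    return {
        f"{prefix}{i + 1}": ItemSpec(tuple(loc + steps)) for i, loc in enumerate(locs)
    }


def dash_like_preset(
    *,
    n_persons: int = 109,
    activity_sd: float = 0.9,
    impairment_sd: float = 0.9,
    optional_missing: float = 0.54,
    dif: tuple[DIFSpec, ...] = (),
    misfit_items: dict[str, float] | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """Conditions emulating a DASH-style administration.

    30 five-category items; activity items 1-20 and impairment items 22-30
    form two locally dependent clusters (person-specific testlet effects);
    three impairment items under-discriminate (symptom items routinely misfit
    on this instrument); item 21 is optional with high missingness; covariate
    marginals follow a typical upper-extremity outpatient sample (57.8% male,
    median-split age, 36.7% surgical, 66.1% dominant side affected).
    ``misfit_items`` maps item ids to GPCM discriminations and overrides the
    default planted misfit.
    """
    if misfit_items is None:
        misfit_items = {"item26": 0.5, "item29": 0.6, "item30": 0.5}
    spec = dash_spec()
    m = 4
    steps = 1.0 * (np.arange(m) - (m - 1) / 2.0)
    locs = np.linspace(-1.4, 0.9, 30)
    items = {}
    for item, loc in zip(spec.item_ids, locs):
        a = (misfit_items or {}).get(item, 1.0)
        items[item] = ItemSpec(tuple(loc + steps), a)
    testlets = (
        TestletSpec("activity", tuple(f"item{i}" for i in range(1, 21)), activity_sd),
        TestletSpec("impairment", tuple(f"item{i}" for i in range(22, 31)), impairment_sd),
    )
    covariates = {
        "sex": {"male": 0.578, "female": 0.422},
        "age_group": {"lt42": 0.5, "ge42": 0.5},
        "surgery": {"yes": 0.367, "no": 0.633},
        "affected_side": {"dominant": 0.661, "nondominant": 0.339},
    }
    return SimulationConfig(
        n_persons=n_persons,
        items=items,
        testlets=testlets,
        dif=dif,
        covariates=covariates,
        missing={"item21": optional_missing},
        seed=seed,
    )
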