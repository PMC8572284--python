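"""Response matrices and scale specifications for polytomous item data.

A scale is an ordered set of items, each with integer response categories
``0..m_i`` (stored 0-based even when the printed questionnaire counts from 1,
matching partial-credit-model conventions and the usual 0-based raw-score
ranges such as 0-116 for 29 five-category items).  A :class:`ResponseMatrix`
holds the persons x items responses with an explicit missing code, plus
per-person categorical covariates used for differential-item-functioning
analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

MISSING = -1  # internal missing code in response arrays


class ScaleError(ValueError):
    """Raised for invalid scale specifications or response data."""


@dataclass(frozen=True)
class ScaleSpec:
    """Item layout of a polytomous scale.

    Parameters
    ----------
    item_ids
        Ordered, unique item labels.
    max_category
        Per-item top category ``m_i`` (categories run ``0..m_i``); an int is
        broadcast to every item.
    optional_flags
        Per-item flags for optional items (may be dropped before analysis).
    category_labels
        Optional per-item response-option labels (``m_i + 1`` strings).
    testlet_map
        Optional partition ``name -> [item ids]``; no item may belong to two
        testlets.
    """

    item_ids: tuple[str, ...]
    max_category: tuple[int, ...]
    optional_flags: tuple[bool, ...] = ()
    category_labels: dict[str, list[str]] | None = None
    testlet_map: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.item_ids)
        if len(set(ids)) != len(ids):
            raise ScaleError("item_ids must be unique")
        if isinstance(self.max_category, (int, np.integer)):
            mc = (int(self.max_category),) * len(ids)
        else:
            mc = tuple(int(m) for m in self.max_category)
        if len(mc) != len(ids):
            raise ScaleError("max_category length must match item_ids")
        if any(m < 1 for m in mc):
            raise ScaleError("every item needs max_category >= 1")
        flags = self.optional_flags or (False,) * len(ids)
        flags = tuple(bool(f) for f in flags)
        if len(flags) != len(ids):
            raise ScaleError("optional_flags length must match item_ids")
        if self.testlet_map is not None:
            seen: set[str] = set()
            tmap = {}
            for name, members in self.testlet_map.items():
                members = tuple(str(m) for m in members)
                unknown = [m for m in members if m not in ids]
                if unknown:
                    raise ScaleError(f"testlet {name!r} references unknown items {unknown}")
                dup = seen.intersection(members)
                if dup:
                    raise ScaleError(f"items {sorted(dup)} appear in more than one testlet")
                seen.update(members)
                tmap[name] = members
            object.__setattr__(self, "testlet_map", tmap)
        object.__setattr__(self, "item_ids", ids)
        object.__setattr__(self, "max_category", mc)
        object.__setattr__(self, "optional_flags", flags)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def max_total(self) -> int:
        """Largest possible raw total score (sum of the m_i)."""
        return int(sum(self.max_category))

    def index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(str(item_id))
        except ValueError:
            raise ScaleError(f"unknown item id {item_id!r}") from None

    def drop(self, item_id: str) -> "ScaleSpec":
        j = self.index(item_id)
        keep = [k for k in range(self.n_items) if k != j]
        tmap = None
        if self.testlet_map is not None:
            tmap = {
                name: tuple(m for m in members if m != self.item_ids[j])
                for name, members in self.testlet_map.items()
            }
            tmap = {k: v for k, v in tmap.items() if v}
        labels = None
        if self.category_labels is not None:
            labels = {k: v for k, v in self.category_labels.items() if k != self.item_ids[j]}
        return ScaleSpec(
            tuple(self.item_ids[k] for k in keep),
            tuple(self.max_category[k] for k in keep),
            tuple(self.optional_flags[k] for k in keep),
            labels,
            tmap,
        )

    def with_testlets(self, testlet_map: dict) -> "ScaleSpec":
        """Copy of the spec with a (new) testlet partition attached."""
        return ScaleSpec(
            self.item_ids,
            self.max_category,
            self.optional_flags,
            self.category_labels,
            {k: tuple(v) for k, v in testlet_map.items()},
        )

    def to_dict(self) -> dict:
        d: dict = {
            "item_ids": list(self.item_ids),
            "max_category": list(self.max_category),
            "optional_flags": list(self.optional_flags),
        }
        if self.category_labels is not None:
            d["category_labels"] = self.category_labels
        if self.testlet_map is not None:
            d["testlet_map"] = {k: list(v) for k, v in self.testlet_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleSpec":
        return cls(
            tuple(d["item_ids"]),
            tuple(d["max_category"]) if not isinstance(d["max_category"], int) else d["max_category"],
            tuple(d.get("optional_flags") or ()),
            d.get("category_labels"),
            {k: tuple(v) for k, v in d["testlet_map"].items()} if d.get("testlet_map") else None,
        )

    @classmethod
    def from_file(cls, path) -> "ScaleSpec":
        """Load a spec from a YAML or JSON document."""
        text = open(path).read()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=1)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with missingness and covariates.

    ``values[n, i]`` is the 0-based category of person ``n`` on item ``i`` or
    :data:`MISSING`.  ``covariates`` is indexed like ``persons`` and holds
    categorical person characteristics (sex, age group, ...).
    """

    persons: tuple[str, ...]
    spec: ScaleSpec
    values: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.persons = tuple(str(p) for p in self.persons)
        if len(set(self.persons)) != len(self.persons):
            dup = pd.Series(self.persons).value_counts()
            raise ScaleError(f"duplicate person id(s): {list(dup[dup > 1].index)}")
        v = np.asarray(self.values, dtype=np.int64)
        if v.shape != (len(self.persons), self.spec.n_items):
            raise ScaleError(
                f"values shape {v.shape} does not match "
                f"{len(self.persons)} persons x {self.spec.n_items} items"
            )
        for i, (item, m) in enumerate(zip(self.spec.item_ids, self.spec.max_category)):
            col = v[:, i]
            bad = np.where((col != MISSING) & ((col < 0) | (col > m)))[0]
            if bad.size:
                n = bad[0]
                raise ScaleError(
                    f"response {col[n]} out of range 0..{m} "
                    f"for person {self.persons[n]!r}, item {item!r}"
                )
        # single-item matrices arise from subset views (e.g. one super-item
        # side of a dimensionality test); files must still have >= 2 items
        if len(self.persons) < 2 or self.spec.n_items < 1:
            raise ScaleError("need at least 2 persons and 1 item")
        self.values = v
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=list(self.persons))
        else:
            self.covariates = self.covariates.loc[list(self.persons)]

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return self.spec.n_items

    @property
    def mask(self) -> np.ndarray:
        """Boolean observed-cell mask."""
        return self.values != MISSING

    def total_scores(self) -> np.ndarray:
        """Per-person raw total over observed items."""
        return np.where(self.mask, self.values, 0).sum(axis=1)

    def subset_items(self, item_ids) -> "ResponseMatrix":
        idx = [self.spec.index(i) for i in item_ids]
        sub = ScaleSpec(
            tuple(self.spec.item_ids[j] for j in idx),
            tuple(self.spec.max_category[j] for j in idx),
            tuple(self.spec.optional_flags[j] for j in idx),
        )
        return ResponseMatrix(self.persons, sub, self.values[:, idx], self.covariates.copy())

    def subset_persons(self, keep_idx) -> "ResponseMatrix":
        keep_idx = np.asarray(keep_idx)
        persons = tuple(self.persons[k] for k in keep_idx)
        return ResponseMatrix(
            persons, self.spec, self.values[keep_idx], self.covariates.iloc[keep_idx].copy()
        )


def read_responses(
    path,
    spec: ScaleSpec,
    *,
    person_col: str = "person_id",
    missing_sentinels: tuple[str, ...] = ("", "NA", "nan"),
    category_base: int = 0,
    sep: str = ",",
) -> ResponseMatrix:
    """Read a delimited-text response file.

    The file must have a header with ``person_col``, one column per item id in
    ``spec`` and optionally extra columns, which are kept as covariates.
    ``category_base`` is the code of the lowest printed category (1 for scales
    printed 1..5); responses are recoded to 0-based on input.  Empty cells and
    ``missing_sentinels`` become missing, never zero.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if person_col not in df.columns:
        raise ScaleError(f"person id column {person_col!r} not found in {path}")
    missing_items = [i for i in spec.item_ids if i not in df.columns]
    if missing_items:
        raise ScaleError(f"items missing from file header: {missing_items}")
    persons = [str(p) for p in df[person_col]]
    n = len(persons)
    values = np.full((n, spec.n_items), MISSING, dtype=np.int64)
    sentinels = set(missing_sentinels)
    for i, (item, m) in enumerate(zip(spec.item_ids, spec.max_category)):
        for r, raw in enumerate(df[item]):
            raw = raw.strip()
            if raw in sentinels:
                continue
            try:
                code = int(float(raw)) - category_base
            except ValueError:
                raise ScaleError(
                    f"non-numeric response {raw!r} for person {persons[r]!r}, item {item!r}"
                ) from None
            if not 0 <= code <= m:
                raise ScaleError(
                    f"response {raw!r} out of range for person {persons[r]!r}, "
                    f"item {item!r} (categories {category_base}..{category_base + m})"
                )
            values[r, i] = code
    if spec.n_items < 2:
        raise ScaleError("a response file needs at least 2 items")
    cov_cols = [c for c in df.columns if c != person_col and c not in spec.item_ids]
    cov = df[cov_cols].copy()
    cov.index = persons
    return ResponseMatrix(tuple(persons), spec, values, cov)


def write_responses(
    data: ResponseMatrix,
    path,
    *,
    person_col: str = "person_id",
    category_base: int = 0,
    sep: str = ",",
) -> None:
    """Write a response matrix in the dialect :func:`read_responses` reads."""
    out = pd.DataFrame(index=list(data.persons))
    out[person_col] = list(data.persons)
    for i, item in enumerate(data.spec.item_ids):
        col = data.values[:, i].astype(object)
        col = [("" if v == MISSING else str(int(v) + category_base)) for v in col]
        out[item] = col
    for c in data.covariates.columns:
        out[c] = data.covariates[c].values
    out.to_csv(path, sep=sep, index=False)


def drop_item(data: ResponseMatrix, item_id: str) -> ResponseMatrix:
    """Remove one item (e.g. an optional item with heavy missingness)."""
    j = data.spec.index(item_id)
    keep = [k for k in range(data.n_items) if k != j]
    return ResponseMatrix(
        data.persons, data.spec.drop(item_id), data.values[:, keep], data.covariates.copy()
    )


def classic_score(data: ResponseMatrix, max_missing_fraction: float = 0.1) -> np.ndarray:
    """Classical summary score on a 0-100 scale.

    ``score = mean(observed 0-based codes) / mean(m_i of observed items) * 100``
    reduces to ``mean code x 25`` for uniform five-category items, i.e. the
    customary "(mean 1-5 item score - 1) x 25" rule.  Persons with more than
    ``max_missing_fraction`` of their items missing get ``nan``.
    """
    mask = data.mask
    n_miss = (~mask).sum(axis=1)
    mi = np.asarray(data.spec.max_category, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.where(mask, data.values, 0).sum(axis=1).astype(float)
        den = (mask * mi).sum(axis=1)
        score = 100.0 * num / den
    score[n_miss > max_missing_fraction * data.n_items] = np.nan
    score[den == 0] = np.nan
    return score


def collapse_testlets(data: ResponseMatrix, spec: ScaleSpec | None = None) -> ResponseMatrix:
    """Replace each testlet by one polytomous super-item.

    The super-item score is the sum of member codes (max = sum of member
    maxima) and is missing whenever any member is missing; non-testlet items
    pass through.  Each super-item is placed at the position of its first
    member, so person raw totals over covered items are preserved exactly.
    """
    spec = spec or data.spec
    if spec.testlet_map is None:
        raise ScaleError("collapse_testlets requires a spec with a testlet_map")
    in_testlet = {m: name for name, members in spec.testlet_map.items() for m in members}
    new_ids: list[str] = []
    new_max: list[int] = []
    new_cols: list[np.ndarray] = []
    emitted: set[str] = set()
    for i, item in enumerate(data.spec.item_ids):
        name = in_testlet.get(item)
        if name is None:
            new_ids.append(item)
            new_max.append(data.spec.max_category[i])
            new_cols.append(data.values[:, i])
        elif name not in emitted:
            emitted.add(name)
            idx = [data.spec.index(m) for m in spec.testlet_map[name]]
            block = data.values[:, idx]
            obs = (block != MISSING).all(axis=1)
            col = np.where(obs, block.sum(axis=1), MISSING)
            new_ids.append(name)
            new_max.append(int(sum(data.spec.max_category[j] for j in idx)))
            new_cols.append(col)
    new_spec = ScaleSpec(tuple(new_ids), tuple(new_max))
    return ResponseMatrix(
        data.persons, new_spec, np.column_stack(new_cols), data.covariates.copy()
    )


def dash_spec() -> ScaleSpec:
    """Scale layout of the 30-item DASH questionnaire.

    Five response categories per item (printed 1-5, stored 0-4), item 21
    optional, and the two testlets used to absorb local dependence: activity
    limitation (items 1-20) and impairment (items 22-30).
    """
    ids = tuple(f"item{i}" for i in range(1, 31))
    flags = tuple(i == 21 for i in range(1, 31))
    tmap = {
        "activity": tuple(f"item{i}" for i in range(1, 21)),
        "impairment": tuple(f"item{i}" for i in range(22, 31)),
    }
    return ScaleSpec(ids, (4,) * 30, flags, None, tmap)
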