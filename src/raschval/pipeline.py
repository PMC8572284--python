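"""Three-run structural-validity workflow and report rendering.

The default profile mirrors a common Rasch validation sequence for a
polytomous scale suspected of local dependence:

1. **initial** — calibrate, measure, and run the full battery (overall and
   per-item fit, threshold ordering, local dependence, DIF, dimensionality,
   PSI) on all persons;
2. **persons_removed** — drop persons with |fit residual| beyond the
   threshold and repeat;
3. **testlets** — collapse locally dependent item clusters into polytomous
   super-items and repeat, which absorbs the shared variance that inflates
   the overall chi-square and the PSI.

A run is satisfactory when the total item-trait chi-square is non-significant
at alpha.  Later runs only execute while the verdict is unsatisfactory; the
ordinal-to-interval conversion table is built from the final run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import (
    FIT_RESIDUAL_LIMIT,
    FitReport,
    fit_battery,
    remove_misfitting_persons,
    standardized_residuals,
)
from .pcm import EstimationError, ItemParameters, PersonEstimates, estimate_items, estimate_persons
from .scale import ResponseMatrix, ScaleError, collapse_testlets
from .scoring import ConversionTable, build_conversion_table
from .structure import (
    DependenceReport,
    DIFReport,
    DimensionalityReport,
    dif_anova,
    residual_correlations,
    shared_variance,
    unidimensionality_ttest,
)

log = logging.getLogger("raschval")


@dataclass
class RunResult:
    """Everything computed in one analysis run."""

    name: str
    n_persons: int
    n_items: int
    items: ItemParameters
    persons: PersonEstimates
    fit: FitReport
    dependence: DependenceReport | None
    dif: dict[str, DIFReport]
    dimensionality: DimensionalityReport | None
    removed_persons: list[str] = field(default_factory=list)
    testlet_map: dict | None = None
    satisfactory: bool = False
    shared_variance: float | None = None


@dataclass
class ValidationReport:
    """Run sequence plus the conversion table of the final run."""

    runs: list[RunResult]
    conversion: ConversionTable | None
    settings: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for k, run in enumerate(self.runs, start=1):
            chi2, df, p = run.fit.total_chisq
            s = run.fit.summary
            rows.append(
                {
                    "run": k,
                    "analysis": run.name,
                    "n": run.n_persons,
                    "items": run.n_items,
                    "item_fit_mean": s["item_fit_mean"],
                    "item_fit_sd": s["item_fit_sd"],
                    "person_fit_mean": s["person_fit_mean"],
                    "person_fit_sd": s["person_fit_sd"],
                    "chisq": chi2,
                    "df": df,
                    "p": p,
                    "psi": run.fit.psi,
                    "pct_significant_ttests": (
                        100.0 * run.dimensionality.prop_significant
                        if run.dimensionality is not None
                        else np.nan
                    ),
                    "satisfactory": run.satisfactory,
                }
            )
        return pd.DataFrame(rows)


def derive_testlets_from_residuals(dep: DependenceReport, n_clusters: int = 2) -> dict:
    """Heuristic testlet map: average-linkage clustering of 1 - Q3 distances."""
    from scipy.cluster.hierarchy import average, fcluster
    from scipy.spatial.distance import squareform

    q3 = dep.q3.to_numpy().copy()
    items = list(dep.q3.index)
    q3[~np.isfinite(q3)] = 0.0
    d = np.clip(1.0 - q3, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    labels = fcluster(average(squareform(d, checks=False)), n_clusters, criterion="maxclust")
    tmap: dict[str, list[str]] = {}
    for item, lab in zip(items, labels):
        tmap.setdefault(f"testlet{lab}", []).append(item)
    if len(tmap) < n_clusters:
        raise ScaleError("residual clustering produced fewer clusters than requested")
    log.info("derived testlets heuristically from residual correlations: %s", tmap)
    return {k: tuple(v) for k, v in sorted(tmap.items())}


def _analyze(
    data: ResponseMatrix,
    name: str,
    *,
    covariates: list[str],
    n_class_intervals: int | None,
    alpha: float,
    max_iter: int,
    run_battery: bool = True,
) -> RunResult:
    items = estimate_items(data, max_iter=max_iter, on_maxiter="warn")
    persons = estimate_persons(data, items)
    res = standardized_residuals(data, items, persons, n_class_intervals=n_class_intervals)
    fit = fit_battery(data, items, persons, res, alpha=alpha)
    dep = dim = None
    dif: dict[str, DIFReport] = {}
    if run_battery:
        try:
            dep = residual_correlations(res)
        except ValueError as exc:
            log.info("run %s: dependence screen skipped (%s)", name, exc)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            for cov in covariates:
                try:
                    dif[cov] = dif_anova(res, data, cov, alpha=alpha)
                except ValueError as exc:
                    log.info("run %s: DIF for %r skipped (%s)", name, cov, exc)
            try:
                dim = unidimensionality_ttest(res, data, items, alpha=alpha)
            except ValueError as exc:
                log.info("run %s: dimensionality test skipped (%s)", name, exc)
    chi2, df, p = fit.total_chisq
    run = RunResult(
        name,
        data.n_persons,
        data.n_items,
        items,
        persons,
        fit,
        dep,
        dif,
        dim,
        satisfactory=p >= alpha,
    )
    log.info(
        "run %s: n=%d items=%d chi2=%.2f (df=%d, p=%.4f) PSI=%.3f %s",
        name, data.n_persons, data.n_items, chi2, df, p, fit.psi,
        "satisfactory" if run.satisfactory else "NOT satisfactory",
    )
    return run


def run_validation(
    data: ResponseMatrix,
    *,
    covariates: list[str] | None = None,
    n_class_intervals: int | None = None,
    fit_threshold: float = FIT_RESIDUAL_LIMIT,
    alpha: float = 0.05,
    testlet_map: dict | None = None,
    max_iter: int = 1000,
    always_run_all: bool = False,
) -> ValidationReport:
    """Execute the validation sequence and bundle every run's evidence.

    ``testlet_map`` defaults to the scale spec's testlets; if neither is
    available the map is derived heuristically from the residual-correlation
    clustering (logged as such).  With ``always_run_all`` later runs execute
    even when an earlier run is already satisfactory.
    """
    covariates = (
        list(covariates)
        if covariates is not None
        else [c for c in data.covariates.columns]
    )
    settings = {
        "alpha": alpha,
        "fit_threshold": fit_threshold,
        "n_class_intervals": n_class_intervals,
        "covariates": covariates,
    }
    runs: list[RunResult] = []
    kw = dict(
        covariates=covariates,
        n_class_intervals=n_class_intervals,
        alpha=alpha,
        max_iter=max_iter,
    )

    run1 = _analyze(data, "initial", **kw)
    runs.append(run1)
    current = data
    last = run1

    if not last.satisfactory or always_run_all:
        reduced, removed = remove_misfitting_persons(
            current, last.fit.person_fit, fit_threshold
        )
        if removed:
            log.info("removing %d misfitting person(s): %s", len(removed), removed)
            run2 = _analyze(reduced, "persons_removed", **kw)
            run2.removed_persons = removed
            runs.append(run2)
            current, last = reduced, run2
        else:
            log.info("no persons beyond |%.1f|; person-removal run skipped", fit_threshold)

    if not last.satisfactory or always_run_all:
        tmap = testlet_map or (data.spec.testlet_map if data.spec.testlet_map else None)
        if tmap is None:
            if last.dependence is None or not last.dependence.flagged_pairs:
                raise ScaleError(
                    "no testlet map available and no dependence structure to derive "
                    "one from; supply testlets explicitly"
                )
            tmap = derive_testlets_from_residuals(last.dependence)
        collapsed = collapse_testlets(current, current.spec.with_testlets(tmap))
        run3 = _analyze(collapsed, "testlets", **kw)
        run3.testlet_map = {k: list(v) for k, v in tmap.items()}
        if run3.dimensionality is not None and run3.dimensionality.subset_estimates:
            try:
                run3.shared_variance = shared_variance(*run3.dimensionality.subset_estimates)
            except ValueError as exc:
                log.info("shared variance undefined (%s)", exc)
        runs.append(run3)
        last = run3

    conversion = None
    try:
        conversion = build_conversion_table(
            last.items, provenance=f"run:{last.name}"
        )
        if not last.satisfactory:
            log.warning(
                "conversion table built from run %r, which did not reach "
                "satisfactory fit", last.name,
            )
    except RuntimeError as exc:
        log.warning("conversion table not built: %s", exc)
    return ValidationReport(runs, conversion, settings)


def render_report(report: ValidationReport, out_dir) -> list[str]:
    """Write the run summary, per-run tables, and a machine-readable index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(name)

    _save(report.summary_frame(), "run_summary.csv")
    index: dict = {"runs": [], "settings": report.settings}
    for k, run in enumerate(report.runs, start=1):
        tag = f"run{k}"
        _save(run.fit.item_fit, f"{tag}_items.csv")
        _save(run.fit.person_fit, f"{tag}_persons.csv")
        if run.dependence is not None:
            _save(run.dependence.pair_frame(), f"{tag}_dependence_pairs.csv")
        for cov, rep in run.dif.items():
            _save(rep.table, f"{tag}_dif_{cov}.csv")
        if run.dimensionality is not None:
            dim = run.dimensionality
            _save(
                pd.DataFrame(
                    {
                        "item": dim.pc1_loadings.index,
                        "pc1_loading": dim.pc1_loadings.to_numpy(),
                        "subset": [
                            "positive" if i in dim.positive_set else "negative"
                            for i in dim.pc1_loadings.index
                        ],
                    }
                ),
                f"{tag}_pca_loadings.csv",
            )
        chi2, df, p = run.fit.total_chisq
        index["runs"].append(
            {
                "run": k,
                "name": run.name,
                "n_persons": run.n_persons,
                "n_items": run.n_items,
                "total_chisq": chi2,
                "df": df,
                "p": p,
                "psi": run.fit.psi,
                "satisfactory": run.satisfactory,
                "removed_persons": run.removed_persons,
                "testlet_map": run.testlet_map,
                "disordered_items": run.fit.disordered_items,
                "n_class_intervals": run.fit.n_class_intervals,
                "prop_significant_ttests": (
                    run.dimensionality.prop_significant
                    if run.dimensionality is not None
                    else None
                ),
                "shared_variance": run.shared_variance,
            }
        )
    if report.conversion is not None:
        report.conversion.to_csv(out / "conversion_table.csv")
        written.append("conversion_table.csv")
    index["files"] = written
    with open(out / "index.json", "w") as fh:
        json.dump(index, fh, indent=1)
    written.append("index.json")
    return written
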