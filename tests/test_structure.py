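"""Local dependence, DIF, dimensionality, and shared variance."""

import warnings

import numpy as np
import pytest

from raschval.fit import standardized_residuals
from raschval.pcm import estimate_items, estimate_persons
from raschval.scale import ResponseMatrix
from raschval.structure import (
    dif_anova,
    residual_correlations,
    shared_variance,
    unidimensionality_ttest,
)
from raschval.simulate import (
    DIFSpec,
    SimulationConfig,
    TestletSpec,
    evenly_spread_items,
    simulate,
)


def _residuals(cfg):
    data, truth = simulate(cfg)
    items = estimate_items(data)
    persons = estimate_persons(data, items)
    return data, items, persons, standardized_residuals(data, items, persons)


@pytest.fixture(scope="module")
def null_fit():
    return _residuals(
        SimulationConfig(n_persons=500, items=evenly_spread_items(10), seed=23)
    )


class TestResidualCorrelations:
    def test_matrix_symmetric_unit_diagonal(self, null_fit):
        _, _, _, res = null_fit
        dep = residual_correlations(res)
        q3 = dep.q3.to_numpy()
        np.testing.assert_allclose(q3, q3.T)
        np.testing.assert_allclose(np.diag(q3), 1.0)
        assert dep.threshold == pytest.approx(dep.mean_q3 + 0.2)

    def test_person_order_invariance(self, null_fit):
        data, items, persons, res = null_fit
        perm = np.random.default_rng(3).permutation(data.n_persons)
        shuffled = data.subset_persons(perm)
        pe = estimate_persons(shuffled, items)
        res2 = standardized_residuals(shuffled, items, pe)
        dep1 = residual_correlations(res)
        dep2 = residual_correlations(res2)
        np.testing.assert_allclose(dep1.q3.to_numpy(), dep2.q3.to_numpy(), atol=1e-10)

    def test_null_flags_rare(self):
        total_pairs = flagged = 0
        for s in range(8):
            _, _, _, res = _residuals(
                SimulationConfig(n_persons=400, items=evenly_spread_items(10), seed=800 + s)
            )
            dep = residual_correlations(res)
            flagged += len(dep.flagged_pairs)
            total_pairs += 45
        assert flagged / total_pairs < 0.05

    def test_duplicated_item_pair_has_maximum_correlation(self, null_fit):
        data, _, _, _ = null_fit
        values = data.values.copy()
        values[:, 1] = values[:, 0]  # response dependency by construction
        dup = ResponseMatrix(data.persons, data.spec, values)
        items = estimate_items(dup)
        persons = estimate_persons(dup, items)
        res = standardized_residuals(dup, items, persons)
        dep = residual_correlations(res)
        top = max(
            (
                (a, b, r)
                for a, b, r in (
                    (i, j, dep.q3.iloc[ii, jj])
                    for ii, i in enumerate(dep.q3.index)
                    for jj, j in enumerate(dep.q3.columns)
                    if ii < jj
                )
            ),
            key=lambda t: t[2],
        )
        assert {top[0], top[1]} == {"item1", "item2"}

    def test_planted_testlets_dominate_flags(self):
        flagged_within = flagged_total = 0
        for s in range(6):
            cfg = SimulationConfig(
                n_persons=500,
                items=evenly_spread_items(10),
                seed=60 + s,
                testlets=(
                    TestletSpec("A", tuple(f"item{i}" for i in range(1, 6)), 0.6),
                    TestletSpec("B", tuple(f"item{i}" for i in range(6, 11)), 0.6),
                ),
            )
            _, _, _, res = _residuals(cfg)
            dep = residual_correlations(res)
            for a, b, _ in dep.flagged_pairs:
                flagged_total += 1
                flagged_within += (int(a[4:]) <= 5) == (int(b[4:]) <= 5)
        assert flagged_total > 0
        assert flagged_within / flagged_total > 0.8


class TestDIF:
    def test_null_covariate_rarely_flagged(self, quiet_warnings):
        flags = 0
        for s in range(5):
            cfg = SimulationConfig(
                n_persons=400,
                items=evenly_spread_items(10),
                covariates={"coin": {"heads": 0.5, "tails": 0.5}},
                seed=900 + s,
            )
            data, items, persons, res = _residuals(cfg)
            rep = dif_anova(res, data, "coin")
            flags += int(rep.table["uniform_dif"].sum() + rep.table["nonuniform_dif"].sum())
        assert flags <= 2

    def test_planted_uniform_dif_detected(self, quiet_warnings):
        hits = 0
        for s in range(5):
            cfg = SimulationConfig(
                n_persons=1000,
                items=evenly_spread_items(10),
                covariates={"grp": {"A": 0.5, "B": 0.5}},
                dif=(DIFSpec("item4", "grp", "B", 0.8),),
                seed=40 + s,
            )
            data, items, persons, res = _residuals(cfg)
            rep = dif_anova(res, data, "grp")
            hits += bool(rep.table.set_index("item").loc["item4", "uniform_dif"])
        assert hits >= 4  # power > 0.8

    def test_permuted_labels_follow_null(self, quiet_warnings):
        from scipy import stats

        cfg = SimulationConfig(
            n_persons=600,
            items=evenly_spread_items(10),
            covariates={"grp": {"A": 0.5, "B": 0.5}},
            dif=(DIFSpec("item4", "grp", "B", 0.8),),
            seed=44,
        )
        data, items, persons, res = _residuals(cfg)
        rng = np.random.default_rng(5)
        data.covariates["grp"] = rng.permutation(data.covariates["grp"].to_numpy())
        rep = dif_anova(res, data, "grp")
        ps = np.concatenate([rep.table["uniform_p"], rep.table["nonuniform_p"]])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_level_covariate_errors(self, null_fit, quiet_warnings):
        data, _, _, res = null_fit
        data.covariates["const"] = "x"
        with pytest.raises(ValueError, match="single level"):
            dif_anova(res, data, "const")


class TestUnidimensionality:
    def test_unidimensional_null_passes(self, quiet_warnings):
        _ = None
        data, items, persons, res = _residuals(
            SimulationConfig(n_persons=500, items=evenly_spread_items(20), seed=77)
        )
        rep = unidimensionality_ttest(res, data, items)
        assert rep.unidimensional
        assert rep.positive_set and rep.negative_set

    def test_two_factor_structure_detected(self, quiet_warnings):
        sd = float(np.sqrt(1.5))  # factor correlation 1 / (1 + sd^2) = 0.4
        hits = 0
        for s in range(5):
            cfg = SimulationConfig(
                n_persons=500,
                items=evenly_spread_items(20),
                seed=130 + s,
                testlets=(
                    TestletSpec("F1", tuple(f"item{i}" for i in range(1, 11)), sd),
                    TestletSpec("F2", tuple(f"item{i}" for i in range(11, 21)), sd),
                ),
            )
            data, items, persons, res = _residuals(cfg)
            rep = unidimensionality_ttest(res, data, items)
            hits += not rep.unidimensional
        assert hits >= 4  # power > 0.8

    def test_identical_estimates_never_significant(self):
        from raschval.structure import _wilson_lower

        t = np.zeros(50)  # theta1 == theta2 for every person
        assert np.mean(np.abs(t) > 1.96) == 0.0
        assert _wilson_lower(0, 50) < 1e-12  # CI rule passes as unidimensional


class TestSharedVariance:
    def test_identical_estimates_give_one(self, null_fit):
        _, _, persons, _ = null_fit
        assert shared_variance(persons, persons) == pytest.approx(1.0, abs=1e-9)

    def test_single_factor_two_testlets_high(self, quiet_warnings):
        cfg = SimulationConfig(n_persons=1000, items=evenly_spread_items(20), seed=19)
        data, items, persons, res = _residuals(cfg)
        a = estimate_persons(data.subset_items([f"item{i}" for i in range(1, 11)]),
                             items.subset([f"item{i}" for i in range(1, 11)]))
        b = estimate_persons(data.subset_items([f"item{i}" for i in range(11, 21)]),
                             items.subset([f"item{i}" for i in range(11, 21)]))
        assert shared_variance(a, b) > 0.9

    def test_noise_only_estimates_near_zero(self, rng):
        from raschval.pcm import PersonEstimates

        n = 400
        vals = []
        for s in range(10):
            r = np.random.default_rng(s)
            a = PersonEstimates(
                tuple(map(str, range(n))), r.normal(size=n), np.full(n, 0.1),
                np.zeros(n, bool), np.zeros(n),
            )
            b = PersonEstimates(
                tuple(map(str, range(n))), r.normal(size=n), np.full(n, 0.1),
                np.zeros(n, bool), np.zeros(n),
            )
            vals.append(shared_variance(a, b))
        assert np.mean(vals) < 0.05
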