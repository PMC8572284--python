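"""Residuals, fit residuals, chi-square strata, threshold order, PSI."""

import numpy as np
import pandas as pd
import pytest

from raschval.fit import (
    assign_class_intervals,
    category_curves,
    check_threshold_order,
    fit_battery,
    item_trait_chisq,
    person_fit_residuals,
    person_separation_index,
    remove_misfitting_persons,
    standardized_residuals,
)
from raschval.pcm import ItemParameters, PersonEstimates, estimate_items, estimate_persons
from raschval.scale import MISSING, ResponseMatrix, ScaleSpec
from raschval.simulate import ItemSpec, SimulationConfig, evenly_spread_items, simulate


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(n_persons=600, items=evenly_spread_items(10), seed=99)
    data, truth = simulate(cfg)
    items = estimate_items(data)
    persons = estimate_persons(data, items)
    res = standardized_residuals(data, items, persons)
    return data, truth, items, persons, res


class TestStandardizedResiduals:
    def test_sign_and_magnitude(self, fitted):
        data, _, _, _, res = fitted
        obs = res.observed
        # response above model expectation -> positive residual
        above = data.values[obs] > res.expected[obs]
        assert np.all(np.sign(res.z[obs][above]) > 0)
        # direct arithmetic: z = (x - E) / sqrt(V)
        np.testing.assert_allclose(
            res.z[obs],
            (data.values[obs] - res.expected[obs]) / np.sqrt(res.variance[obs]),
        )

    def test_exact_example(self):
        # x=4, E=2, Var=2 -> sqrt(2)
        assert (4 - 2) / np.sqrt(2.0) == pytest.approx(1.4142, abs=1e-4)

    def test_per_item_mean_near_zero(self, fitted):
        _, _, _, _, res = fitted
        means = np.nanmean(res.z, axis=0)
        assert np.all(np.abs(means) < 0.1)


class TestClassIntervals:
    def test_quantile_strata_ordered_and_sized(self, rng):
        theta = rng.normal(size=300)
        labels = assign_class_intervals(theta, 5, min_size=10)
        assert labels.min() == 0
        for g in range(labels.max()):
            assert theta[labels == g].max() <= theta[labels == g + 1].min() + 1e-12
        assert np.bincount(labels).min() >= 10

    def test_small_samples_get_few_strata(self, rng):
        theta = rng.normal(size=25)
        labels = assign_class_intervals(theta, 10, min_size=10)
        assert labels.max() + 1 == 2


class TestFitResiduals:
    def test_flag_boundary(self, fitted):
        _, _, _, _, res = fitted
        pf = person_fit_residuals(res)
        flagged = pf.loc[pf["misfit"], "fit_residual"].abs()
        unflagged = pf.loc[~pf["misfit"], "fit_residual"].abs()
        if len(flagged):
            assert flagged.min() > 2.5
        assert unflagged.max() <= 2.5

    def test_type_i_rate_across_items(self):
        # under the model, few items should be flagged
        frs = []
        for s in range(10):
            cfg = SimulationConfig(n_persons=500, items=evenly_spread_items(10), seed=700 + s)
            data, _ = simulate(cfg)
            items = estimate_items(data)
            persons = estimate_persons(data, items)
            res = standardized_residuals(data, items, persons)
            rep = fit_battery(data, items, persons, res)
            frs.extend(rep.item_fit["fit_residual"].tolist())
        frs = np.asarray(frs)
        assert np.abs(frs.mean()) < 0.2
        assert 0.7 < frs.std(ddof=1) < 1.3
        assert np.mean(np.abs(frs) > 2.5) < 0.10

    def test_underdiscriminating_item_flags_positive(self):
        items = evenly_spread_items(10)
        items["item5"] = ItemSpec(items["item5"].thresholds, 0.3)
        cfg = SimulationConfig(n_persons=1000, items=items, seed=55)
        data, _ = simulate(cfg)
        est = estimate_items(data)
        persons = estimate_persons(data, est)
        res = standardized_residuals(data, est, persons)
        rep = fit_battery(data, est, persons, res)
        row = rep.item_fit.set_index("item").loc["item5"]
        assert row["fit_residual"] > 2.5


class TestItemTraitChisq:
    def test_df_bookkeeping(self, fitted):
        data, _, _, _, res = fitted
        table, (chi2, df, p) = item_trait_chisq(res, data)
        g = res.n_intervals
        assert df == 10 * (g - 1)
        assert np.isclose(table["chisq"].sum(), chi2)
        assert 0.0 <= p <= 1.0

    def test_bonferroni_level_for_29_items(self, fitted):
        data, _, _, _, res = fitted
        # the significance column uses alpha / I
        table, _ = item_trait_chisq(res, data, alpha=0.05)
        assert (table["significant"] == (table["p"] < 0.005)).all()


class TestThresholdOrder:
    def test_ordered_and_disordered(self):
        items = ItemParameters(
            ("ok", "bad"),
            (np.array([-2.0, -1.0, 0.0, 1.0]), np.array([-1.0, -1.5, 0.0, 1.0])),
            (np.zeros(4), np.zeros(4)),
        )
        assert check_threshold_order(items) == ["bad"]

    def test_modal_category_criterion(self):
        # ordered item: every category modal somewhere; disordered: some never
        ordered = ItemParameters(("a",), (np.array([-2.0, 0.0, 2.0]),), (np.zeros(3),))
        disordered = ItemParameters(("b",), (np.array([1.0, -1.0, 0.5]),), (np.zeros(3),))
        for pars, expect_all_modal in ((ordered, True), (disordered, False)):
            curves = category_curves(pars, np.linspace(-6, 6, 241))
            wide = curves.pivot_table(
                index="theta", columns="category", values="probability"
            )
            modal = set(np.asarray(wide).argmax(axis=1))
            assert (modal == set(range(wide.shape[1]))) == expect_all_modal


class TestRemoveMisfittingPersons:
    def test_no_misfit_no_change(self, fitted):
        data, _, _, _, res = fitted
        pf = pd.DataFrame({"person": list(data.persons), "fit_residual": 0.0})
        out, removed = remove_misfitting_persons(data, pf)
        assert removed == []
        assert out is data

    def test_exactly_the_flagged_person_removed(self, fitted):
        data, _, _, _, _ = fitted
        fr = np.zeros(data.n_persons)
        fr[3] = 3.1
        pf = pd.DataFrame({"person": list(data.persons), "fit_residual": fr})
        out, removed = remove_misfitting_persons(data, pf)
        assert removed == [data.persons[3]]
        assert out.n_persons == data.n_persons - 1

    def test_idempotent(self, fitted):
        data, _, _, _, _ = fitted
        fr = np.where(np.arange(data.n_persons) < 5, 3.0, 0.0)
        pf = pd.DataFrame({"person": list(data.persons), "fit_residual": fr})
        once, removed1 = remove_misfitting_persons(data, pf)
        twice, removed2 = remove_misfitting_persons(once, pf)
        assert removed2 == []
        assert twice.persons == once.persons

    def test_planted_random_responders_detected(self):
        cfg = SimulationConfig(n_persons=500, items=evenly_spread_items(10), seed=31)
        data, _ = simulate(cfg)
        rng = np.random.default_rng(17)
        values = data.values.copy()
        planted = [3, 77, 150, 333, 444]
        for p in planted:
            values[p] = rng.integers(0, 5, size=10)
        noisy = ResponseMatrix(data.persons, data.spec, values)
        items = estimate_items(noisy)
        persons = estimate_persons(noisy, items)
        res = standardized_residuals(noisy, items, persons)
        pf = person_fit_residuals(res)
        _, removed = remove_misfitting_persons(noisy, pf)
        hits = sum(noisy.persons[p] in removed for p in planted)
        assert hits >= 3

    def test_refuses_to_empty_the_sample(self, fitted):
        data, _, _, _, _ = fitted
        pf = pd.DataFrame(
            {"person": list(data.persons), "fit_residual": np.full(data.n_persons, 9.0)}
        )
        with pytest.raises(ValueError, match="fewer than"):
            remove_misfitting_persons(data, pf)


class TestPSI:
    def test_limits(self):
        theta = np.array([-1.0, 0.0, 1.0, 2.0])
        perfect = PersonEstimates(
            ("a", "b", "c", "d"), theta, np.full(4, 1e-9), np.zeros(4, bool), np.arange(4)
        )
        assert person_separation_index(perfect) == pytest.approx(1.0, abs=1e-6)
        var = np.var(theta, ddof=1)
        noisy = PersonEstimates(
            ("a", "b", "c", "d"), theta, np.full(4, np.sqrt(var)), np.zeros(4, bool), np.arange(4)
        )
        assert person_separation_index(noisy) == pytest.approx(0.0, abs=1e-9)

    def test_matches_generating_reliability(self):
        cfg = SimulationConfig(n_persons=1000, items=evenly_spread_items(20), seed=61)
        data, truth = simulate(cfg)
        items = estimate_items(data)
        persons = estimate_persons(data, items)
        psi = person_separation_index(persons)
        sel = ~persons.extreme
        expected = 1.0 / (1.0 + np.mean(persons.se[sel] ** 2))  # Var(theta) = 1
        assert psi == pytest.approx(expected, abs=0.05)

    def test_zero_variance_errors(self):
        flat = PersonEstimates(
            ("a", "b", "c"), np.zeros(3), np.ones(3), np.zeros(3, bool), np.zeros(3)
        )
        with pytest.raises(ValueError, match="variance"):
            person_separation_index(flat)
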