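"""Weighted estimators, thresholds, iron risk curve, gaps, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcesfort.adequacy import (IronRiskCurve, ThresholdSet, micronutrient_gap,
                               prevalence_excess, prevalence_inadequate_cutpoint,
                               prevalence_inadequate_iron, safety_gap,
                               stratified_summaries, weighted_quantile)
from hcesfort.fortification import SCENARIOS


class TestWeightedQuantile:
    def test_plain_median_with_unit_weights(self):
        v = np.arange(1.0, 10.0)
        assert weighted_quantile(v, np.ones(9), 0.5) == 5.0

    def test_boundaries(self):
        v = np.array([3.0, 1.0, 2.0])
        w = np.array([1.0, 2.0, 1.0])
        assert weighted_quantile(v, w, 0.0) == 1.0
        assert weighted_quantile(v, w, 1.0) == 3.0

    def test_weight_pulls_toward_heavier_value(self):
        assert weighted_quantile([1.0, 2.0], [1.0, 3.0], 0.5) == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_quantile([], [], 0.5)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30),
           st.data(), st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_integer_weights_equal_replication_oracle(self, values, data, q):
        w = data.draw(st.lists(st.integers(1, 5), min_size=len(values),
                               max_size=len(values)))
        v = np.array(values)
        expanded = np.repeat(v, w)
        assert weighted_quantile(v, np.array(w, dtype=float), q) \
            == pytest.approx(np.quantile(expanded, q), abs=1e-9)


class TestCutpointPrevalence:
    def test_symmetric_split(self):
        assert prevalence_inadequate_cutpoint([5.0, 15.0], [1.0, 1.0], 10.2) == 50.0

    def test_all_above_har_is_zero(self):
        assert prevalence_inadequate_cutpoint([11.0, 12.0], [1.0, 1.0], 10.2) == 0.0

    def test_matches_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(2, 50)
            v = rng.lognormal(2.0, 0.8, n)
            w = rng.integers(1, 6, n).astype(float)
            har = float(rng.uniform(2, 20))
            oracle = 100.0 * np.repeat(v, w.astype(int) )[
                np.repeat(v, w.astype(int)) < har].size / w.sum()
            assert prevalence_inadequate_cutpoint(v, w, har) == pytest.approx(oracle)


class TestIronFullProbability:
    def test_step_curve_reduces_to_cutpoint(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(3.0, 0.5, 200)
        w = rng.uniform(0.5, 2.0, 200)
        t = 25.0
        assert prevalence_inadequate_iron(v, w, IronRiskCurve.step(t)) \
            == pytest.approx(prevalence_inadequate_cutpoint(v, w, t))

    def test_flat_risk_region_gives_constant_prevalence(self):
        curve = IronRiskCurve(np.array([0.0, 10.0, 20.0]), np.array([1.0, 0.3, 0.3]))
        v = np.array([12.0, 15.0, 19.0])
        assert prevalence_inadequate_iron(v, np.ones(3), curve) == pytest.approx(30.0)

    def test_piecewise_curve_hand_summed_expectation(self):
        curve = IronRiskCurve(np.array([0.0, 10.0, 20.0, 40.0]),
                              np.array([1.0, 0.8, 0.2, 0.0]))
        v = np.array([0.0, 5.0, 10.0, 15.0, 30.0])
        w = np.array([1.0, 2.0, 1.0, 1.0, 1.0])
        risks = np.array([1.0, 0.9, 0.8, 0.5, 0.1])
        expect = 100.0 * np.sum(w * risks) / w.sum()
        assert prevalence_inadequate_iron(v, w, curve) == pytest.approx(expect)

    def test_default_curve_monotone_and_bounded(self):
        from hcesfort.adequacy import DEFAULT_IRON_CURVE as c
        x = np.linspace(0, 200, 500)
        r = c.risk(x)
        assert np.all((r >= 0) & (r <= 1))
        assert np.all(np.diff(r) <= 1e-12)
        assert c.risk(0.0) == pytest.approx(1.0)

    def test_invalid_curve_rejected(self):
        with pytest.raises(ValueError):
            IronRiskCurve(np.array([0.0, 1.0]), np.array([0.2, 0.9]))  # increasing
        with pytest.raises(ValueError):
            IronRiskCurve(np.array([1.0, 0.5]), np.array([1.0, 0.5]))  # bad grid


class TestExcess:
    def test_zinc_straddles_the_two_authorities(self):
        v, w = [20.0, 30.0], [1.0, 1.0]
        assert prevalence_excess(v, w, "zinc_mg", zinc_authority="efsa") == 50.0
        assert prevalence_excess(v, w, "zinc_mg", zinc_authority="iom") == 0.0

    def test_retinol_below_ul_is_zero(self):
        assert prevalence_excess([2000.0, 2999.0], [1.0, 1.0], "retinol_ug") == 0.0

    @pytest.mark.parametrize("nutrient", ["folate_dfe_ug", "vitb12_ug"])
    def test_low_toxicity_nutrients_rejected(self, nutrient):
        with pytest.raises(ValueError):
            prevalence_excess([1.0], [1.0], nutrient)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            v = rng.lognormal(3.5, 0.6, n)
            w = rng.integers(1, 5, n).astype(float)
            rep = np.repeat(v, w.astype(int))
            oracle = 100.0 * (rep > 45.0).sum() / len(rep)
            assert prevalence_excess(v, w, "iron_mg") == pytest.approx(oracle)


class TestGaps:
    def test_micronutrient_gap_arithmetic(self):
        v = np.full(8, 300.0)
        assert micronutrient_gap(v, np.ones(8), 250.0) == pytest.approx(50.0)
        assert micronutrient_gap(v, np.ones(8), 300.0) == pytest.approx(0.0)

    def test_safety_gap_boundary(self):
        v = np.full(8, 25.0)
        assert safety_gap(v, np.ones(8), 25.0) == pytest.approx(0.0)

    def test_authority_difference_is_constant_15mg(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            v = rng.lognormal(2.5, 0.7, 50)
            w = rng.uniform(0.5, 3.0, 50)
            efsa = safety_gap(v, w, 25.0)
            iom = safety_gap(v, w, 40.0)
            assert iom - efsa == pytest.approx(15.0)


def test_threshold_invariants():
    t = ThresholdSet()
    assert t.hul["zinc_mg_efsa"] == 25.0 and t.hul["zinc_mg_iom"] == 40.0
    assert t.zinc_hul("iom") > t.zinc_hul("efsa") > t.har["zinc_mg"]
    with pytest.raises(ValueError):
        ThresholdSet(har={"zinc_mg": -1.0})


class TestStratifiedSummaries:
    @staticmethod
    def _inputs(strata):
        n = len(strata)
        hids = [f"h{i}" for i in range(n)]
        meta = pd.DataFrame({"household_id": hids, "stratum": strata,
                             "urban": [1] * n, "survey_weight": [1.0] * n})
        afe = pd.DataFrame({"household_id": hids, "afe": [1.0] * n})
        veh = pd.DataFrame({"household_id": hids, "cooking_oil": [10.0] * n,
                            "wheat_flour": [5.0] * n, "maize_flour": [0.0] * n})
        rows = []
        for s in SCENARIOS:
            for i, h in enumerate(hids):
                rows.append({"household_id": h, "scenario": s,
                             "iron_mg": 10.0 + i, "zinc_mg": 8.0 + i,
                             "vita_rae_ug": 300.0, "retinol_ug": 100.0,
                             "folate_dfe_ug": 260.0, "folic_acid_ug": 0.0,
                             "vitb12_ug": 1.5, "energy_kcal": 2000.0})
        return pd.DataFrame(rows), veh, meta, afe

    def test_single_stratum_national_equals_stratum(self):
        intakes, veh, meta, afe = self._inputs(["Zanzibar"] * 6)
        out = stratified_summaries(intakes, veh, meta, afe)
        inad = out["inadequacy"]
        nat = inad[inad.stratum == "national"].set_index(["scenario", "nutrient"])
        zan = inad[inad.stratum == "Zanzibar"].set_index(["scenario", "nutrient"])
        assert np.allclose(nat["prevalence_pct"], zan.loc[nat.index, "prevalence_pct"])

    def test_full_coverage_reports_100_percent(self):
        intakes, veh, meta, afe = self._inputs(["Zanzibar"] * 4)
        out = stratified_summaries(intakes, veh, meta, afe)
        cov = out["coverage"]
        oil = cov[(cov.stratum == "national") & (cov.vehicle == "cooking_oil")]
        assert oil["coverage_pct"].iloc[0] == 100.0
        maize = cov[(cov.stratum == "national") & (cov.vehicle == "maize_flour")]
        assert maize["coverage_pct"].iloc[0] == 0.0

    def test_unweighted_mode_ignores_weights(self):
        intakes, veh, meta, afe = self._inputs(["Zanzibar"] * 5)
        meta2 = meta.assign(survey_weight=[1.0, 10.0, 10.0, 10.0, 10.0])
        out_w = stratified_summaries(intakes, veh, meta2, afe)
        out_u = stratified_summaries(intakes, veh, meta2, afe, weighted=False)
        key = ["stratum", "scenario", "nutrient"]
        merged = out_w["inadequacy"].merge(out_u["inadequacy"], on=key)
        assert not np.allclose(merged["prevalence_pct_x"], merged["prevalence_pct_y"])

    def test_ground_truth_prevalence_recovered_on_small_survey(self, small_survey,
                                                               fixtures_tables):
        """Pipeline summaries on true quantities equal ground-truth prevalence."""
        from hcesfort import afe as afe_mod
        from hcesfort import quantify
        from hcesfort.fortification import all_scenarios, default_spec
        roster, _, gt = small_survey
        cleaned = gt.true_daily.assign(source="purchase")
        fct = quantify.resolve_composites(fixtures_tables["fct"],
                                          fixtures_tables["weights"])
        veh = quantify.vehicle_equivalents(cleaned, fixtures_tables["recipes"])
        afe_df = afe_mod.household_afe(roster)
        base = afe_mod.intake_per_afe(
            quantify.household_nutrient_supply(cleaned, fct), afe_df)
        intakes = all_scenarios(base, veh, afe_df, default_spec())
        meta = roster.drop_duplicates("household_id")[
            ["household_id", "stratum", "cluster", "urban", "survey_weight"]]
        out = stratified_summaries(intakes, veh, meta, afe_df)
        nat = out["inadequacy"].query("stratum == 'national'")
        merged = nat.merge(gt.prevalence, on=["scenario", "nutrient"],
                           suffixes=("", "_gt"))
        assert len(merged) == len(gt.prevalence)
        cut = merged[merged.nutrient != "iron_mg"]
        assert np.allclose(cut["prevalence_pct"], cut["prevalence_pct_gt"], atol=1e-9)
        # iron: the pipeline evaluates a tabulated risk curve, the ground
        # truth the exact lognormal CDF; agreement to curve-grid resolution
        fe = merged[merged.nutrient == "iron_mg"]
        assert np.allclose(fe["prevalence_pct"], fe["prevalence_pct_gt"], atol=0.05)
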