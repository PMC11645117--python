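"""Unit conversion, refuse, cleaning, composites, vehicles, nutrient supply."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcesfort.quantify import (UnresolvableUnitError, clean_quantities,
                               composite_composition, edible_grams,
                               exclude_zero_consumption, household_nutrient_supply,
                               records_to_daily_grams, to_grams, vehicle_equivalents)
from hcesfort.foods import NUTRIENTS


@pytest.mark.parametrize("qty,unit,portion,density,expect", [
    (2.0, "kg", None, None, 2000.0),
    (500.0, "g", None, None, 500.0),
    (1.0, "L", None, 0.92, 920.0),
    (250.0, "mL", None, 1.03, 257.5),
    (3.0, "pieces", 50.0, None, 150.0),
])
def test_to_grams_conversions(qty, unit, portion, density, expect):
    assert to_grams(qty, unit, "item", portion, density) == pytest.approx(expect)


@pytest.mark.parametrize("unit,portion,density", [
    ("pieces", None, None), ("L", None, None), ("mL", None, None),
    ("litres", None, None),
])
def test_to_grams_unresolvable_unit_names_food(unit, portion, density):
    with pytest.raises(UnresolvableUnitError, match="oil"):
        to_grams(1.0, unit, "oil", portion, density)


@pytest.mark.parametrize("grams,refuse,expect", [
    (100.0, 0.0, 100.0), (100.0, 0.36, 64.0), (0.0, 0.5, 0.0)])
def test_edible_grams(grams, refuse, expect):
    assert edible_grams(grams, refuse) == pytest.approx(expect)


def test_edible_grams_rejects_full_refuse():
    with pytest.raises(ValueError):
        edible_grams(100.0, 1.0)


def _daily(quantities, code="item"):
    return pd.DataFrame({
        "household_id": [f"h{i}" for i in range(len(quantities))],
        "food_code": code, "source": "purchase", "grams_per_day": quantities})


class TestCleaning:
    def test_constant_quantities_unchanged(self):
        out = clean_quantities(_daily([10.0] * 5))
        assert not out["was_outlier"].any() and not out["was_imputed"].any()
        assert (out["grams_per_day"] == 10.0).all()

    def test_extreme_value_detected_and_median_replaced(self):
        vals = [10.0, 12.0, 9.0, 11.0, 10.0, 1e6]
        # brute-force check that 1e6 exceeds 3 leave-one-out SDs of the logs
        # from the median of the logs (its own log must not inflate the SD)
        logs = np.log(vals)
        assert abs(logs[-1] - np.median(logs)) > 3 * np.std(logs[:-1], ddof=1)
        out = clean_quantities(_daily(vals)).set_index("household_id")
        assert out.loc["h5", "was_outlier"]
        assert out.loc["h5", "grams_per_day"] == np.median(vals)
        assert not out.loc[out.index != "h5", "was_outlier"].any()

    def test_missing_replaced_by_consumer_median(self):
        out = clean_quantities(_daily([8.0, 10.0, 12.0, np.nan])).set_index(
            "household_id")
        assert out.loc["h3", "was_imputed"]
        assert out.loc["h3", "grams_per_day"] == 10.0

    def test_single_consumer_passes_through(self):
        out = clean_quantities(_daily([42.0]))
        assert out["grams_per_day"].iloc[0] == 42.0
        assert not out["was_outlier"].any()

    def test_all_missing_item_dropped_with_warning(self, caplog):
        df = pd.concat([_daily([np.nan, np.nan], "ghost"), _daily([1.0, 2.0])])
        with caplog.at_level("WARNING"):
            out = clean_quantities(df)
        assert "ghost" not in set(out["food_code"])
        assert any("ghost" in r.message for r in caplog.records)

    def test_cleaning_idempotent_on_survey_data(self, small_survey, fixtures_tables):
        _, consumption, _ = small_survey
        daily = records_to_daily_grams(consumption, fixtures_tables["refuse_density"],
                                       fixtures_tables["portions"])
        once = clean_quantities(daily)
        twice = clean_quantities(once.drop(columns=["was_outlier", "was_imputed"]))
        pdt.assert_series_equal(once["grams_per_day"], twice["grams_per_day"])


class TestComposite:
    def test_single_component_identity(self, fixtures_tables):
        fct = fixtures_tables["fct"].set_index("food_code", drop=False)
        row = fct.loc["c_tomato"]
        out = composite_composition([(row, 1.0)], "x")
        for n in NUTRIENTS:
            assert out[n] == row[n]

    @pytest.mark.parametrize("weights,expect", [((0.5, 0.5), 3.0), ((0.75, 0.25), 2.5)])
    def test_weighted_mean(self, weights, expect):
        a = pd.Series({**{n: 0.0 for n in NUTRIENTS}, "iron_mg": 2.0, "food_code": "a"})
        b = pd.Series({**{n: 0.0 for n in NUTRIENTS}, "iron_mg": 4.0, "food_code": "b"})
        out = composite_composition([(a, weights[0]), (b, weights[1])], "ab")
        assert out["iron_mg"] == pytest.approx(expect)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError):
            composite_composition([], "empty")

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0.01, 5)),
                    min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mean_bounded_by_components(self, pairs):
        comps = [(pd.Series({**{n: 0.0 for n in NUTRIENTS}, "iron_mg": v,
                             "food_code": f"c{i}"}), w)
                 for i, (v, w) in enumerate(pairs)]
        out = composite_composition(comps, "x")
        vals = [v for v, _ in pairs]
        assert min(vals) - 1e-9 <= out["iron_mg"] <= max(vals) + 1e-9


def _cleaned(rows):
    return pd.DataFrame(rows, columns=["household_id", "food_code", "grams_per_day"]) \
        .assign(source="purchase")


@pytest.fixture(scope="module")
def recipes():
    from hcesfort.synthetic import generate_fixtures
    return generate_fixtures(0)["recipes"]


class TestVehicleEquivalents:
    def test_bread_contributes_flour_by_recipe_fraction(self, recipes):
        out = vehicle_equivalents(_cleaned([("h1", "bread", 100.0)]), recipes)
        assert out["wheat_flour"].iloc[0] == pytest.approx(70.0)

    def test_macaroni_contributes_no_flour(self, recipes):
        out = vehicle_equivalents(_cleaned([("h1", "macaroni_spaghetti", 200.0)]),
                                  recipes)
        assert out["wheat_flour"].iloc[0] == 0.0

    def test_direct_and_product_flour_add(self, recipes):
        out = vehicle_equivalents(
            _cleaned([("h1", "wheat_flour", 50.0), ("h1", "bread", 100.0)]), recipes)
        assert out["wheat_flour"].iloc[0] == pytest.approx(120.0)

    def test_maize_flour_is_direct_only(self, recipes):
        out = vehicle_equivalents(
            _cleaned([("h1", "maize_flour", 200.0), ("h1", "bread", 100.0)]), recipes)
        assert out["maize_flour"].iloc[0] == pytest.approx(200.0)

    def test_mass_conservation_on_survey(self, small_survey, fixtures_tables, recipes):
        _, consumption, _ = small_survey
        daily = clean_quantities(records_to_daily_grams(
            consumption, fixtures_tables["refuse_density"], fixtures_tables["portions"]))
        veh = vehicle_equivalents(daily, recipes).set_index("household_id")
        totals = daily.groupby("household_id")["grams_per_day"].sum()
        for vcol in ("wheat_flour", "cooking_oil", "maize_flour"):
            assert (veh[vcol] <= totals.loc[veh.index] + 1e-9).all()


class TestNutrientSupply:
    def test_unit_case_and_additivity(self, fixtures_tables):
        fct = pd.DataFrame([
            {"food_code": "a", **{n: 0.0 for n in NUTRIENTS}, "iron_mg": 2.0},
            {"food_code": "b", **{n: 0.0 for n in NUTRIENTS}, "iron_mg": 1.0},
        ])
        out = household_nutrient_supply(
            _cleaned([("h1", "a", 100.0), ("h1", "b", 200.0)]), fct)
        assert out["iron_mg"].iloc[0] == pytest.approx(2.0 + 2.0)

    def test_unmatched_food_code_is_hard_error(self):
        fct = pd.DataFrame([{"food_code": "a", **{n: 0.0 for n in NUTRIENTS}}])
        with pytest.raises(KeyError, match="mystery"):
            household_nutrient_supply(_cleaned([("h1", "mystery", 1.0)]), fct)

    @given(st.floats(1.0, 1e4), st.floats(1.1, 3.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_supply_monotone_in_quantity(self, grams, factor):
        fct = pd.DataFrame([{"food_code": "a", **{n: 1.0 for n in NUTRIENTS}}])
        low = household_nutrient_supply(_cleaned([("h1", "a", grams)]), fct)
        high = household_nutrient_supply(_cleaned([("h1", "a", grams * factor)]), fct)
        for n in NUTRIENTS:
            assert high[n].iloc[0] >= low[n].iloc[0]


def test_zero_consumption_households_excluded():
    households = pd.DataFrame({"household_id": ["h1", "h2", "h3"]})
    consumption = pd.DataFrame({"household_id": ["h1", "h3"], "food_code": "a"})
    kept, n = exclude_zero_consumption(households, consumption)
    assert n == 1 and set(kept["household_id"]) == {"h1", "h3"}
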