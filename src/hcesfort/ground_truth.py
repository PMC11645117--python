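"""Straight-line recomputation of a synthetic survey's true results.

Everything in here is deliberately written as plain per-household,
per-member, per-item Python loops that duplicate the *science* — unit
conversion, refuse subtraction, recipe disaggregation, Schofield energy
requirements, scenario arithmetic, weighted prevalence — without calling
any pipeline operation. The pipeline's tests compare its vectorised
implementations against these loops; sharing code would make those
comparisons vacuous. Only constant tables (food metadata, Schofield
coefficients, fortification parameters, thresholds) are shared, since they
are data, not logic.

Ground truth is computed from the generator's pre-injection quantities, so
it represents what a perfect cleaning stage should recover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .adequacy import DEFAULT_HAR, DEFAULT_HUL
from .afe import COMPLEMENTARY_KCAL, LACTATION_KCAL, SCHOFIELD, _DEFAULT_WEIGHT_ANCHORS
from .foods import FOOD_INDEX, NUTRIENTS, RECIPES, VEHICLES
from .fortification import default_spec
from .synthetic import GroundTruth

_SCENARIOS = ["no_fortification", "status_quo", "full", "full_no_maize"]
_IRON_MEDIAN, _IRON_SIGMA = 29.2, 0.4256


def _composition_lookup(fixtures) -> dict[str, dict[str, float]]:
    fct = fixtures["fct"].set_index("food_code")
    weights = fixtures["weights"]
    comp = {}
    for code, row in fct.iterrows():
        comp[code] = {n: float(row[n]) for n in NUTRIENTS}
    for composite, grp in weights.groupby("composite_code"):
        total = grp["frequency_weight"].sum()
        vals = {n: 0.0 for n in NUTRIENTS}
        for r in grp.itertuples(index=False):
            for n in NUTRIENTS:
                vals[n] += comp[r.component_code][n] * r.frequency_weight / total
        comp[composite] = vals
    return comp


def _member_eer_plain(sex, age_years, age_months, weight_kg, lactating,
                      mean_f_19_49, mean_m_15) -> float:
    if age_months is not None and age_months < 24:
        for lo, hi, kcal in COMPLEMENTARY_KCAL:
            if lo <= age_months < hi:
                return kcal
        raise AssertionError("unreachable complementary band")
    # resolve weight with the survey fallback rules
    w = weight_kg
    if w is None or (isinstance(w, float) and np.isnan(w)):
        if sex == "M" and age_years >= 18:
            w = 65.0
        elif sex == "M" and 16 <= age_years < 18:
            w15 = mean_m_15 if mean_m_15 is not None else _interp_weight(15, "M")
            frac = 1 / 3 if age_years < 17 else 2 / 3
            w = w15 + frac * (65.0 - w15)
        elif sex == "F" and age_years > 50 and mean_f_19_49 is not None:
            w = mean_f_19_49
        else:
            w = _interp_weight(age_years, sex)
    for lo, hi, slope, intercept in SCHOFIELD[sex]:
        if lo <= age_years < hi:
            eer = (slope * w + intercept) * 1.85
            if lactating:
                eer += LACTATION_KCAL
            return eer
    raise AssertionError("unreachable Schofield band")


def _interp_weight(age, sex):
    anchors = _DEFAULT_WEIGHT_ANCHORS[sex]
    return float(np.interp(age, [a for a, _ in anchors], [w for _, w in anchors]))


def compute(roster: pd.DataFrame, true_grams: pd.DataFrame, fixtures) -> GroundTruth:
    """Ground truth for one generated survey (see module docstring)."""
    comp = _composition_lookup(fixtures)
    ref_eer = (14.818 * 55.0 + 486.6) * 1.85
    spec = default_spec()

    # survey-wide weight means for the fallback rules
    meas = roster[pd.to_numeric(roster["weight_kg"], errors="coerce").notna()]
    f_sel = meas[(meas["sex"] == "F") & (meas["age_years"] >= 19)
                 & (meas["age_years"] <= 49)]
    mean_f = float(f_sel["weight_kg"].mean()) if len(f_sel) else None
    m_sel = meas[(meas["sex"] == "M") & (meas["age_years"] >= 14.5)
                 & (meas["age_years"] <= 15.5)]
    mean_m15 = float(m_sel["weight_kg"].mean()) if len(m_sel) else None

    # mothers of under-2s are assumed lactating
    lact = set()
    for r in roster.itertuples(index=False):
        months = r.age_months
        if months is not pd.NA and months is not None and not pd.isna(months) \
                and int(months) < 24 and not pd.isna(r.mother_member_id):
            lact.add((r.household_id, r.mother_member_id))

    afe_map = {}
    for hid, grp in roster.groupby("household_id"):
        total = 0.0
        for r in grp.itertuples(index=False):
            months = None if pd.isna(r.age_months) else int(r.age_months)
            lac = (r.household_id, r.member_id) in lact and r.sex == "F"
            total += _member_eer_plain(r.sex, float(r.age_years), months,
                                       None if pd.isna(r.weight_kg) else float(r.weight_kg),
                                       lac, mean_f, mean_m15)
        afe_map[hid] = total / ref_eer

    recipes = {}  # ingredient -> list of (product, fraction)
    for product, ingredient, frac in RECIPES:
        recipes.setdefault(ingredient, []).append((product, frac))

    # per-household edible grams/day, nutrient totals, vehicle equivalents
    daily_rows, supply, vehicles = [], {}, {}
    for r in true_grams.itertuples(index=False):
        item = FOOD_INDEX[r.food_code]
        g_day = r.true_grams_7d * (1.0 - item.refuse) / 7.0
        daily_rows.append({"household_id": r.household_id, "food_code": r.food_code,
                           "grams_per_day": g_day})
        tot = supply.setdefault(r.household_id, {n: 0.0 for n in NUTRIENTS})
        for n in NUTRIENTS:
            tot[n] += g_day / 100.0 * comp[r.food_code][n]
        veh = vehicles.setdefault(r.household_id, {v: 0.0 for v in VEHICLES})
        if r.food_code in VEHICLES:
            veh[r.food_code] += g_day
        for vehicle, prods in recipes.items():
            for product, frac in prods:
                if r.food_code == product:
                    veh[vehicle] += g_day * frac

    ledger = {"iron": [("iron_mg", 0.001)], "zinc": [("zinc_mg", 0.001)],
              "vitamin_a": [("vita_rae_ug", 1.0), ("retinol_ug", 1.0)],
              "folic_acid": [("folic_acid_ug", 1.0), ("folate_dfe_ug", 1.7)],
              "vitamin_b12": [("vitb12_ug", 1.0)]}

    intake_rows = []
    for hid, tot in supply.items():
        afe = afe_map[hid]
        if afe <= 0:
            continue
        base = {n: tot[n] / afe for n in NUTRIENTS}
        for scenario in _SCENARIOS:
            row = {"household_id": hid, "scenario": scenario, **base}
            for (vehicle, nutrient), p in spec.params.items():
                if scenario == "no_fortification":
                    mg_kg = 0.0
                elif scenario == "status_quo":
                    mg_kg = p.standard_mg_kg * p.compliance * (1 - p.loss)
                elif scenario == "full_no_maize" and vehicle == "maize_flour":
                    mg_kg = 0.0
                else:
                    mg_kg = p.standard_mg_kg * (1 - p.loss)
                grams = vehicles[hid][vehicle]
                for col, factor in ledger[nutrient]:
                    row[col] += grams * mg_kg * factor / afe
            intake_rows.append(row)
    intakes = pd.DataFrame(intake_rows)

    hh_meta = roster.drop_duplicates("household_id").set_index("household_id")
    reporting = sorted(supply.keys())
    w = hh_meta.loc[reporting, "survey_weight"].to_numpy(dtype=float)

    prev_rows, excess_rows = [], []
    for scenario in _SCENARIOS:
        sub = intakes[intakes["scenario"] == scenario].set_index("household_id")
        sub = sub.loc[reporting]
        for nutrient, har in DEFAULT_HAR.items():
            v = sub[nutrient].to_numpy(dtype=float)
            prev_rows.append({"scenario": scenario, "nutrient": nutrient,
                              "prevalence_pct": 100.0 * w[v < har].sum() / w.sum()})
        fe = sub["iron_mg"].to_numpy(dtype=float)
        risk = 1.0 - norm.cdf((np.log(np.maximum(fe, 1e-12)) - np.log(_IRON_MEDIAN))
                              / _IRON_SIGMA)
        prev_rows.append({"scenario": scenario, "nutrient": "iron_mg",
                          "prevalence_pct": 100.0 * float(np.sum(w * risk)) / w.sum()})
        for nutrient, hul_key, auth in (
                ("iron_mg", "iron_mg", "harmonised"),
                ("zinc_mg", "zinc_mg_efsa", "efsa"),
                ("zinc_mg", "zinc_mg_iom", "iom"),
                ("retinol_ug", "retinol_ug", "harmonised"),
                ("folic_acid_ug", "folic_acid_ug", "harmonised")):
            v = sub[nutrient].to_numpy(dtype=float)
            excess_rows.append({"scenario": scenario, "nutrient": nutrient,
                                "authority": auth,
                                "prevalence_pct": 100.0 * w[v > DEFAULT_HUL[hul_key]].sum()
                                / w.sum()})

    cov_rows = []
    for vehicle in VEHICLES:
        consuming = np.array([vehicles[h][vehicle] > 0 for h in reporting])
        cov_rows.append({"vehicle": vehicle,
                         "coverage_pct": 100.0 * w[consuming].sum() / w.sum()})

    afe_df = pd.DataFrame({"household_id": list(afe_map), "afe": list(afe_map.values())})
    return GroundTruth(
        true_daily=pd.DataFrame(daily_rows),
        afe=afe_df,
        intakes=intakes,
        prevalence=pd.DataFrame(prev_rows),
        excess=pd.DataFrame(excess_rows),
        coverage=pd.DataFrame(cov_rows),
    )
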