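"""Large-scale food fortification (LSFF) scenario modelling.

Tanzania's fortification legislation mandates vitamin A in cooking oil and
iron, zinc, folic acid and vitamin B12 in wheat and maize flour. Each
(vehicle, nutrient) pair is parameterised by

* ``A`` — the legislated mean fortificant content (mg per kg of vehicle);
* ``B`` — compliance, the fraction of marketed samples fortified to
  standard;
* ``C`` — the fraction of the added *vitamin* lost between production and
  consumption (zero for the minerals).

Added content per kg of vehicle under each scenario:

* ``no_fortification`` — 0
* ``status_quo``       — A x B x (1 - C)
* ``full``             — A x (1 - C)
* ``full_no_maize``    — as ``full``, but maize flour contributes nothing

Additions flow to households through their fortifiable-vehicle consumption
(direct plus the recipe-embedded share in bread, buns/cakes/biscuits and
sweets), are divided by household AFE, and land on the nutrient ledgers:
vitamin A (retinyl palmitate) accrues to both total RAE and preformed
retinol; folic acid accrues to dietary folate equivalents (x 1.7) for
adequacy and to folic-acid mass for excess-risk assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .foods import VEHICLES

SCENARIOS = ["no_fortification", "status_quo", "full", "full_no_maize"]

#: mg of added compound per kg of vehicle -> reporting-unit increments per
#: gram of vehicle consumed. Keys are fortificant nutrients; values list
#: (intake column, unit factor per mg/kg per g of vehicle).
_LEDGERS = {
    # 1 g vehicle x 1 mg/kg = 0.001 mg compound
    "iron": [("iron_mg", 0.001)],
    "zinc": [("zinc_mg", 0.001)],
    "vitamin_a": [("vita_rae_ug", 1.0), ("retinol_ug", 1.0)],  # 0.001 mg = 1 ug
    "folic_acid": [("folic_acid_ug", 1.0), ("folate_dfe_ug", 1.7)],
    "vitamin_b12": [("vitb12_ug", 1.0)],
}

FOLIC_ACID_TO_DFE = 1.7


@dataclass(frozen=True)
class FortificationParams:
    """Standard A (mg/kg), compliance B and loss C for one vehicle-nutrient."""

    vehicle: str
    nutrient: str
    standard_mg_kg: float  # A
    compliance: float      # B
    loss: float = 0.0      # C, vitamins only

    def __post_init__(self):
        if self.standard_mg_kg < 0:
            raise ValueError("standard A must be >= 0")
        if not 0 <= self.compliance <= 1 or not 0 <= self.loss <= 1:
            raise ValueError("compliance B and loss C must lie in [0, 1]")


@dataclass
class FortificationSpec:
    """The full parameter set across vehicles and nutrients."""

    params: dict = field(default_factory=dict)  # (vehicle, nutrient) -> FortificationParams

    @classmethod
    def from_rows(cls, rows) -> "FortificationSpec":
        spec = cls()
        for r in rows:
            p = FortificationParams(**r) if isinstance(r, dict) else r
            spec.params[(p.vehicle, p.nutrient)] = p
        return spec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"vehicle": p.vehicle, "nutrient": p.nutrient,
              "standard_mg_kg": p.standard_mg_kg, "compliance": p.compliance,
              "loss": p.loss} for p in self.params.values()])


def default_spec() -> FortificationSpec:
    """Parameters of the Tanzanian programme as used throughout the package.

    Standards follow the East African fortification standards (oil: 25
    mg/kg retinol equivalents as retinyl palmitate; flours: Fe 33, Zn 44,
    B12 0.013, folic acid 2 mg/kg). Compliance reflects market-level
    assessment: 28% of oils and 47% of wheat flour within the legislated
    range, no fortified maize flour found. Loss fractions apply to vitamins
    only and are package defaults (country measurements can override them
    in the spec file).
    """
    rows = [
        dict(vehicle="cooking_oil", nutrient="vitamin_a",
             standard_mg_kg=25.0, compliance=0.28, loss=0.30),
    ]
    for vehicle, b in (("wheat_flour", 0.47), ("maize_flour", 0.0)):
        rows += [
            dict(vehicle=vehicle, nutrient="iron", standard_mg_kg=33.0,
                 compliance=b, loss=0.0),
            dict(vehicle=vehicle, nutrient="zinc", standard_mg_kg=44.0,
                 compliance=b, loss=0.0),
            dict(vehicle=vehicle, nutrient="vitamin_b12", standard_mg_kg=0.013,
                 compliance=b, loss=0.10),
            dict(vehicle=vehicle, nutrient="folic_acid", standard_mg_kg=2.0,
                 compliance=b, loss=0.25),
        ]
    return FortificationSpec.from_rows(rows)


def added_content(vehicle: str, nutrient: str, scenario: str,
                  spec: FortificationSpec) -> float:
    """Added fortificant (mg per kg of vehicle) under a scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "no_fortification":
        return 0.0
    if scenario == "full_no_maize" and vehicle == "maize_flour":
        return 0.0
    key = (vehicle, nutrient)
    if key not in spec.params:
        raise KeyError(f"fortification spec lacks ({vehicle}, {nutrient})")
    p = spec.params[key]
    if scenario == "status_quo":
        return p.standard_mg_kg * p.compliance * (1.0 - p.loss)
    return p.standard_mg_kg * (1.0 - p.loss)  # full or full_no_maize


def folic_acid_to_dfe(mg_folic_acid: float) -> float:
    """Convert folic-acid mass to dietary folate equivalents (x 1.7).

    2 mg/kg of folic acid is equivalent to 3.4 mg/kg folate DFE. The
    unconverted folic-acid mass is tracked separately because excess-risk
    assessment uses folic acid itself, not DFE.
    """
    if mg_folic_acid < 0:
        raise ValueError("folic acid mass must be >= 0")
    return mg_folic_acid * FOLIC_ACID_TO_DFE


def scenario_additions_per_afe(vehicle_grams: pd.DataFrame, afe: pd.DataFrame,
                               spec: FortificationSpec, scenario: str) -> pd.DataFrame:
    """Fortificant-only per-AFE intake additions for one scenario.

    ``vehicle_grams`` columns: household_id plus one column per vehicle
    (grams/day, recipe-inclusive). Returns household_id plus the nutrient
    reporting columns touched by fortification, all >= 0.
    """
    merged = vehicle_grams.merge(afe, on="household_id", how="inner")
    out = merged[["household_id"]].copy()
    cols: dict[str, pd.Series] = {}
    for (vehicle, nutrient), _p in spec.params.items():
        if vehicle not in merged.columns:
            continue
        mg_kg = added_content(vehicle, nutrient, scenario, spec)
        for col, factor in _LEDGERS[nutrient]:
            add = merged[vehicle] * mg_kg * factor / merged["afe"]
            cols[col] = cols.get(col, 0.0) + add
    for col, series in cols.items():
        out[col] = series
    return out


def apply_scenario(base_per_afe: pd.DataFrame, vehicle_grams: pd.DataFrame,
                   afe: pd.DataFrame, spec: FortificationSpec,
                   scenario: str) -> pd.DataFrame:
    """Per-AFE intakes under a fortification scenario.

    ``base_per_afe`` holds the no-fortification per-AFE intakes (household
    id plus nutrient columns); additions are computed per household from
    its vehicle consumption, divided by AFE, and added on. The result
    carries a ``scenario`` column.
    """
    adds = scenario_additions_per_afe(vehicle_grams, afe, spec, scenario)
    out = base_per_afe.merge(adds, on="household_id", how="left",
                             suffixes=("", "_add"))
    for col in adds.columns:
        if col == "household_id":
            continue
        out[col] = out[col] + out[col + "_add"].fillna(0.0)
        out = out.drop(columns=[col + "_add"])
    out.insert(1, "scenario", scenario)
    return out


def all_scenarios(base_per_afe: pd.DataFrame, vehicle_grams: pd.DataFrame,
                  afe: pd.DataFrame, spec: FortificationSpec) -> pd.DataFrame:
    """Stack per-AFE intakes for the four scenarios into one long table."""
    return pd.concat(
        [apply_scenario(base_per_afe, vehicle_grams, afe, spec, s) for s in SCENARIOS],
        ignore_index=True)
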