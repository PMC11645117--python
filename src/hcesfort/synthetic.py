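"""Synthetic household-survey generator with known ground truth.

Emulates the structure of a national panel survey's 7-day food-consumption
module so that the whole analysis pipeline is testable without the
registration-gated microdata: four analytical strata (Dar es Salaam,
Mainland other urban, Mainland rural, Zanzibar), clusters sampled within
strata with eight households each, household rosters with a young
age pyramid, right-skewed (lognormal) consumption quantities with
per-stratum coverage probabilities, inverse-sampling-fraction survey
weights with noise, and controlled injection of missing values and
log-scale outliers.

Log-quantities are drawn truncated at ``truncate_z`` standard deviations
(default 2.5), and a pull-in pass then nudges any value that would still
trip the >3 SD cleaning rule in the nationally pooled distribution (a
stratum-mixture effect) back inside the threshold. Injected artifacts are
therefore, by construction, the only replacements the cleaning stage
should make, which keeps the generator's bookkeeping exact.

Alongside every generated survey the module returns a
:class:`GroundTruth`: per-household per-scenario intakes and national
prevalences recomputed by an independent straight-line implementation
(:mod:`hcesfort.ground_truth`), never by the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .foods import (COMPONENT_FOODS, FOOD_INDEX, FOOD_LIST, NUTRIENTS, RECIPES,
                    SOURCES, VEHICLES)

DEFAULT_STRATA = ["Dar es Salaam", "Mainland other urban", "Mainland rural", "Zanzibar"]


class ConfigurationError(ValueError):
    """Invalid survey-design or consumption-model configuration."""


class SurveyDesignConfig(BaseModel):
    """Stratified two-stage design: clusters within strata, households within clusters."""

    strata: list[str] = Field(default_factory=lambda: list(DEFAULT_STRATA))
    clusters_per_stratum: dict[str, int] = Field(
        default_factory=lambda: {"Dar es Salaam": 69, "Mainland other urban": 67,
                                 "Mainland rural": 224, "Zanzibar": 59})
    households_per_cluster: int = 8
    # stratum -> base survey weight (inverse sampling fraction scale)
    base_weights: dict[str, float] = Field(
        default_factory=lambda: {"Dar es Salaam": 350.0, "Mainland other urban": 420.0,
                                 "Mainland rural": 780.0, "Zanzibar": 120.0})
    # probability that a household in the stratum is urban
    urban_prob: dict[str, float] = Field(
        default_factory=lambda: {"Dar es Salaam": 1.0, "Mainland other urban": 1.0,
                                 "Mainland rural": 0.0, "Zanzibar": 0.30})
    mean_household_size: float = 4.6

    @field_validator("households_per_cluster")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ConfigurationError("households_per_cluster must be positive")
        return v

    def model_post_init(self, __context):
        for s in self.strata:
            if self.clusters_per_stratum.get(s, 0) <= 0:
                raise ConfigurationError(f"stratum {s!r} needs a positive cluster count")
            if not 0 <= self.urban_prob.get(s, 0.0) <= 1:
                raise ConfigurationError(f"urban probability for {s!r} outside [0, 1]")
            if self.base_weights.get(s, 1.0) <= 0:
                raise ConfigurationError(f"base weight for {s!r} must be positive")

    @property
    def n_households(self) -> int:
        return sum(self.clusters_per_stratum[s] for s in self.strata) \
            * self.households_per_cluster


@dataclass(frozen=True)
class ItemModel:
    """Consumption model for one (stratum, food item) cell."""

    coverage: float
    meanlog: float  # of the 7-day household quantity in grams
    sdlog: float

    def __post_init__(self):
        if not 0 <= self.coverage <= 1:
            raise ConfigurationError("coverage probability outside [0, 1]")
        if self.sdlog <= 0:
            raise ConfigurationError("sdlog must be positive")


# per-stratum overrides for the fortification-relevant items: coverage and
# a shift applied to the national meanlog (urban households buy more oil
# and wheat products, rural households more maize flour)
STRATUM_ADJUST: dict[str, dict[str, tuple[float, float]]] = {
    "cooking_oil": {"Dar es Salaam": (0.99, 0.40), "Mainland other urban": (0.97, 0.15),
                    "Mainland rural": (0.88, -0.35), "Zanzibar": (0.86, 0.10)},
    "maize_flour": {"Dar es Salaam": (0.85, -0.30), "Mainland other urban": (0.93, -0.30),
                    "Mainland rural": (0.94, 0.20), "Zanzibar": (0.54, -1.40)},
    "wheat_flour": {"Dar es Salaam": (0.35, 0.50), "Mainland other urban": (0.25, 0.30),
                    "Mainland rural": (0.10, -0.40), "Zanzibar": (0.38, 0.60)},
    "bread": {"Dar es Salaam": (0.68, 0.40), "Mainland other urban": (0.50, 0.20),
              "Mainland rural": (0.22, -0.30), "Zanzibar": (0.62, 0.50)},
    "buns_cakes_biscuits": {"Dar es Salaam": (0.22, 0.20),
                            "Mainland other urban": (0.20, 0.10),
                            "Mainland rural": (0.10, -0.20), "Zanzibar": (0.16, 0.20)},
    "sweets": {"Dar es Salaam": (0.12, 0.0), "Mainland other urban": (0.10, 0.0),
               "Mainland rural": (0.06, 0.0), "Zanzibar": (0.10, 0.0)},
}


@dataclass
class ConsumptionModel:
    """Per-(stratum, item) coverage and lognormal quantity parameters."""

    items: dict  # (stratum, food_code) -> ItemModel
    missing_rate: float = 0.002  # share of consumption cells blanked
    outlier_rate: float = 0.001  # share of cells turned into >3 SD outliers
    truncate_z: float = 2.5      # natural draws bounded at +/- this many SD
    zero_consumption_rate: float = 0.019  # households reporting no food

    def __post_init__(self):
        for rate in (self.missing_rate, self.outlier_rate, self.zero_consumption_rate):
            if not 0 <= rate < 1:
                raise ConfigurationError("rates must lie in [0, 1)")
        if self.truncate_z <= 0:
            raise ConfigurationError("truncate_z must be positive")


#: AFE of a typical household, used to translate the food list's per-AFE
#: per-day medians into 7-day household draw medians
TYPICAL_AFE = 4.5


def default_model(design: Optional[SurveyDesignConfig] = None) -> ConsumptionModel:
    """The study-condition consumption model for the default food list."""
    design = design or SurveyDesignConfig()
    items = {}
    for f in FOOD_LIST:
        med_7d = f.median_g_afe_day * 7.0 * TYPICAL_AFE
        national_meanlog = np.log(med_7d) if med_7d > 0 else 0.0
        for s in design.strata:
            cov, dlog = f.coverage, 0.0
            adj = STRATUM_ADJUST.get(f.code, {}).get(s)
            if adj is not None:
                cov, dlog = adj
            items[(s, f.code)] = ItemModel(cov, national_meanlog + dlog, f.sdlog)
    return ConsumptionModel(items=items)


@dataclass
class GroundTruth:
    """By-construction truth for a generated survey.

    Everything here is recomputed with straight-line loops in
    :mod:`hcesfort.ground_truth`, independently of the pipeline operations.
    """

    true_daily: pd.DataFrame       # household_id, food_code, edible grams/day (pre-injection)
    afe: pd.DataFrame              # household_id, afe
    intakes: pd.DataFrame          # household_id, scenario, nutrient columns per AFE
    prevalence: pd.DataFrame       # scenario, nutrient, prevalence_pct (national, weighted)
    excess: pd.DataFrame           # scenario, nutrient, authority, prevalence_pct
    coverage: pd.DataFrame         # vehicle, coverage_pct (national, weighted)
    injected_missing: list = field(default_factory=list)   # (household_id, food_code)
    injected_outliers: list = field(default_factory=list)  # (household_id, food_code)
    n_zero_consumption: int = 0


# age pyramid approximating a young LMIC population: (lo, hi) years, probability
AGE_PYRAMID = [((0, 2), 0.075), ((2, 5), 0.105), ((5, 10), 0.145), ((10, 15), 0.125),
               ((15, 18), 0.065), ((18, 30), 0.20), ((30, 50), 0.175),
               ((50, 65), 0.07), ((65, 85), 0.04)]

# weight-for-age reference used to simulate measured anthropometry;
# mirrors the fallback anchors in hcesfort.afe
from .afe import _DEFAULT_WEIGHT_ANCHORS  # noqa: E402


def _draw_age(rng: np.random.Generator) -> tuple[float, Optional[int]]:
    probs = np.array([p for _, p in AGE_PYRAMID])
    lo, hi = AGE_PYRAMID[rng.choice(len(AGE_PYRAMID), p=probs / probs.sum())][0]
    if lo == 0 and hi == 2:
        months = int(rng.integers(0, 24))
        return months / 12.0, months
    return float(rng.uniform(lo, hi)), None


def _ref_weight(age: float, sex: str) -> float:
    anchors = _DEFAULT_WEIGHT_ANCHORS[sex]
    return float(np.interp(age, [a for a, _ in anchors], [w for _, w in anchors]))


def _generate_roster(design: SurveyDesignConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    hh_counter = 0
    for stratum in design.strata:
        for cluster_i in range(design.clusters_per_stratum[stratum]):
            cluster = f"{stratum[:3].upper()}-{cluster_i:03d}"
            for _ in range(design.households_per_cluster):
                hh_counter += 1
                hid = f"hh{hh_counter:05d}"
                urban = int(rng.random() < design.urban_prob[stratum])
                weight = design.base_weights[stratum] * rng.uniform(0.8, 1.2)
                size = 1 + min(int(rng.poisson(design.mean_household_size - 1)), 13)
                members = []
                for m in range(size):
                    if m == 0:  # household head: an adult
                        age, months = float(rng.uniform(18, 65)), None
                    else:
                        age, months = _draw_age(rng)
                    sex = "M" if rng.random() < 0.5 else "F"
                    # anthropometry mimics the survey: measured for females
                    # to 50 y and males to 15 y only
                    measured = (sex == "F" and age <= 50) or (sex == "M" and age <= 15)
                    wkg = (_ref_weight(age, sex) * rng.lognormal(0.0, 0.12)
                           if measured else np.nan)
                    members.append({
                        "household_id": hid, "member_id": f"{hid}m{m + 1}",
                        "sex": sex, "age_years": age,
                        "age_months": months if months is not None else pd.NA,
                        "weight_kg": wkg, "mother_member_id": pd.NA,
                        "stratum": stratum, "cluster": cluster, "urban": urban,
                        "survey_weight": weight,
                    })
                # mother links for under-2s: a woman aged 15-49 in the household
                candidates = [m["member_id"] for m in members
                              if m["sex"] == "F" and 15 <= m["age_years"] <= 49]
                for m in members:
                    if m["age_months"] is not pd.NA and candidates:
                        m["mother_member_id"] = candidates[int(rng.integers(len(candidates)))]
                rows.extend(members)
    roster = pd.DataFrame(rows)
    roster["age_months"] = roster["age_months"].astype("Int64")
    return roster


def _express_quantity(grams: float, item, rng: np.random.Generator):
    """Pick a reporting unit and return (quantity, unit, true reported grams)."""
    units = list(item.unit_probs)
    probs = np.array([item.unit_probs[u] for u in units], dtype=float)
    unit = units[rng.choice(len(units), p=probs / probs.sum())]
    if unit == "pieces":
        count = max(1, int(round(grams / item.portion_g)))
        return float(count), unit, count * item.portion_g
    if unit == "kg":
        return grams / 1000.0, unit, grams
    if unit == "g":
        return grams, unit, grams
    if unit == "L":
        return grams / (item.density * 1000.0), unit, grams
    return grams / item.density, "mL", grams  # mL


def _would_flag(log_values: np.ndarray, idx: int, z_limit: float = 3.0) -> bool:
    """Replicates the cleaning rule's flag test for one value (by index):
    deviation from the median of logs against the leave-one-out SD."""
    med = np.median(log_values)
    rest = np.delete(log_values, idx)
    sd = np.std(rest, ddof=1)
    return sd > 0 and abs(log_values[idx] - med) > z_limit * sd


_UNIT_TO_G = {"kg": 1000.0, "g": 1.0}


def _unit_factor(item, u: str) -> float:
    """Grams per reported unit for one item."""
    if u in _UNIT_TO_G:
        return _UNIT_TO_G[u]
    if u == "pieces":
        return item.portion_g
    return item.density * (1000.0 if u == "L" else 1.0)


def _grams_vector(sub: pd.DataFrame, item) -> np.ndarray:
    """Reported quantities of one item expressed in grams."""
    factors = sub["unit"].map(lambda u: _unit_factor(item, u))
    return (sub["quantity"].to_numpy(dtype=float) * factors.to_numpy(dtype=float))


def _loo_sd(logs: np.ndarray) -> np.ndarray:
    """Leave-one-out SD per element, matching the cleaning rule's yardstick."""
    n = len(logs)
    s1, s2 = logs.sum(), (logs ** 2).sum()
    mean_loo = (s1 - logs) / (n - 1)
    var = np.maximum((s2 - logs ** 2 - (n - 1) * mean_loo ** 2) / (n - 2), 0.0)
    return np.sqrt(var)


def _pull_in_naturals(consumption: pd.DataFrame, z_limit: float = 3.0,
                      margin: float = 0.85, max_iter: int = 50) -> None:
    """Enforce the generator's no-natural-outlier contract in place.

    Per-item truncation bounds individual log draws, but nationally pooled
    distributions mix stratum-shifted components whose tails can still
    exceed the >3 SD rule. This pass pulls any such value toward the item
    median (to ``margin`` x the flag threshold) so that, by construction,
    the only quantities the cleaning stage replaces are the artifacts
    injected afterwards.
    """
    for code, idx in consumption.groupby("food_code").groups.items():
        if len(idx) < 3:
            continue
        item = FOOD_INDEX[code]
        idx = np.asarray(idx)
        for _ in range(max_iter):
            sub = consumption.loc[idx]
            logs = np.log(_grams_vector(sub, item))
            med = np.median(logs)
            sd = _loo_sd(logs)
            dev = logs - med
            flagged = np.flatnonzero((sd > 0) & (np.abs(dev) > z_limit * sd))
            if not len(flagged):
                break
            for j in flagged:
                target = med + np.sign(dev[j]) * margin * z_limit * sd[j]
                pos = idx[j]
                factor = _unit_factor(item, consumption.at[pos, "unit"])
                if consumption.at[pos, "unit"] == "pieces":
                    count = max(1, int(round(np.exp(target) / factor)))
                    consumption.at[pos, "quantity"] = float(count)
                else:
                    consumption.at[pos, "quantity"] = float(np.exp(target) / factor)


def _inject_artifacts(consumption: pd.DataFrame, model: ConsumptionModel,
                      rng: np.random.Generator):
    """Blank a share of cells and turn a share into guaranteed outliers."""
    n = len(consumption)
    injected_missing, injected_outliers = [], []

    n_missing = int(np.floor(model.missing_rate * n))
    if n_missing:
        miss_idx = rng.choice(n, size=n_missing, replace=False)
        for i in miss_idx:
            row = consumption.iloc[i]
            injected_missing.append((row["household_id"], row["food_code"]))
        consumption.iloc[miss_idx, consumption.columns.get_loc("quantity")] = np.nan

    n_out = int(np.floor(model.outlier_rate * n))
    if n_out:
        # one injection per item, mass-unit items with enough consumers only
        counts = consumption["food_code"].value_counts()
        eligible = [c for c in counts.index
                    if counts[c] >= 20 and "pieces" not in FOOD_INDEX[c].unit_probs]
        eligible = [str(c) for c in rng.permutation(eligible)]
        for code in eligible[:n_out]:
            sub = consumption[(consumption["food_code"] == code)
                              & consumption["quantity"].notna()]
            if len(sub) < 20:
                continue
            pos = sub.index[int(rng.integers(len(sub)))]
            logs = np.log(_grams_vector(sub, FOOD_INDEX[code]))
            local = int(np.flatnonzero(sub.index == pos)[0])
            base_sd = max(np.std(logs, ddof=1), 0.1)
            k = 4.0
            while True:  # raise the multiplier until the >3 SD rule fires
                trial = logs.copy()
                trial[local] += k * base_sd
                if _would_flag(trial, local):
                    break
                k += 1.0
            consumption.loc[pos, "quantity"] *= float(np.exp(k * base_sd))
            row = consumption.loc[pos]
            injected_outliers.append((row["household_id"], row["food_code"]))
    return injected_missing, injected_outliers


def generate_survey(design: Optional[SurveyDesignConfig] = None,
                    model: Optional[ConsumptionModel] = None,
                    seed: int = 0):
    """Generate (roster, consumption, ground truth) for one synthetic survey.

    Deterministic given ``seed``. Consumption rows exist only for items a
    household consumes; a small configured share of households reports no
    food at all (they are the pipeline's exclusion set and carry no ground
    truth). Ground truth reflects the *pre-injection* quantities.
    """
    design = design or SurveyDesignConfig()
    model = model or default_model(design)
    rng = np.random.default_rng(seed)

    roster = _generate_roster(design, rng)
    households = roster.drop_duplicates("household_id")[
        ["household_id", "stratum", "cluster", "urban", "survey_weight"]]

    rows = []
    n_zero = 0
    for hh in households.itertuples(index=False):
        if rng.random() < model.zero_consumption_rate:
            n_zero += 1
            continue
        for item in FOOD_LIST:
            im = model.items.get((hh.stratum, item.code))
            if im is None or rng.random() >= im.coverage:
                continue
            z = rng.normal()
            while abs(z) > model.truncate_z:
                z = rng.normal()
            grams = float(np.exp(im.meanlog + im.sdlog * z))
            qty, unit, true_grams = _express_quantity(grams, item, rng)
            src = SOURCES[rng.choice(3, p=np.array(item.source_probs)
                                     / sum(item.source_probs))]
            rows.append({"household_id": hh.household_id, "food_code": item.code,
                         "quantity": qty, "unit": unit, "source": src,
                         "recall_days": 7, "_true_grams": true_grams})
    consumption = pd.DataFrame(rows)
    # enforce the no-natural-outlier contract on the pooled distributions,
    # then refresh the true gram amounts from the (possibly adjusted) rows
    _pull_in_naturals(consumption)
    for code, idx in consumption.groupby("food_code").groups.items():
        grams = _grams_vector(consumption.loc[idx], FOOD_INDEX[code])
        consumption.loc[idx, "_true_grams"] = grams
    true_grams = consumption[["household_id", "food_code", "_true_grams"]].rename(
        columns={"_true_grams": "true_grams_7d"})
    consumption = consumption.drop(columns=["_true_grams"])

    injected_missing, injected_outliers = _inject_artifacts(consumption, model, rng)

    from . import ground_truth  # deferred: straight-line reimplementation
    gt = ground_truth.compute(roster, true_grams, generate_fixtures(seed))
    gt.injected_missing = injected_missing
    gt.injected_outliers = injected_outliers
    gt.n_zero_consumption = n_zero
    return roster, consumption, gt


def generate_fixtures(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Deterministic reference tables for the 60-item food list.

    Returns ``fct`` (per-100 g compositions, concatenated items left to be
    resolved via ``weights``), ``recipes`` (wheat-flour and oil mass
    fractions of the processed products), ``portions`` (gram masses for
    pieces items), ``refuse_density`` and ``weights``
    (household-budget-survey consumption-frequency weights for composite
    components). The tables are fixed study conditions; ``seed`` is
    accepted for interface symmetry.
    """
    fct_rows, rd_rows, portion_rows, weight_rows = [], [], [], []
    for f in FOOD_LIST + COMPONENT_FOODS:
        fct_rows.append({"food_code": f.code, "food_name": f.name,
                         **dict(zip(NUTRIENTS, f.comp)), "source_fct": f.source_fct})
        rd_rows.append({"food_code": f.code, "refuse_fraction": f.refuse,
                        "density_g_ml": f.density if f.density else np.nan})
        if f.portion_g:
            portion_rows.append({"food_code": f.code, "portion_g": f.portion_g})
        if f.components:
            total = sum(f.components.values())
            for comp, w in f.components.items():
                weight_rows.append({"composite_code": f.code, "component_code": comp,
                                    "frequency_weight": w / total})
    recipes = pd.DataFrame(RECIPES, columns=["product_code", "ingredient_code",
                                             "mass_fraction"])
    return {
        "fct": pd.DataFrame(fct_rows),
        "recipes": recipes,
        "portions": pd.DataFrame(portion_rows),
        "refuse_density": pd.DataFrame(rd_rows),
        "weights": pd.DataFrame(weight_rows),
    }
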