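"""Adult female equivalent (AFE) standardisation of household nutrient supplies.

Household surveys record food at the household level, so apparent intakes
must be standardised before they can be compared against requirement
thresholds defined for individuals. The AFE approach expresses a
household's total energy requirement as a multiple of the requirement of a
reference woman — non-pregnant, non-lactating, aged 18–29.9 years — and
divides household nutrient supplies by that multiple. It assumes food is
shared within the household in proportion to members' energy requirements.

Energy requirements are computed from an auditable, configurable table:

* adults and children from age 2 years use Schofield basal-metabolic-rate
  equations (kcal/d, weight in kg) multiplied by a physical activity level
  (default PAL 1.85, an active or moderately active lifestyle);
* children below 24 months contribute only the energy needed from
  non-breastmilk (complementary) foods: 0 kcal/d at 0–2 months, 76 at 3–5,
  269 at 6–8, 451 at 9–11 and 746 at 12–23 months;
* lactating women receive an additional 500 kcal/d. Lactation status is
  inferred: a woman linked as the biological mother of a child below
  24 months is assumed to be lactating;
* pregnancy is not modelled (household surveys rarely record it).

Measured body weights are used where the survey provides them; missing
weights are resolved by documented fallback rules (see
:func:`resolve_weight`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Schofield BMR equations, kcal/d with weight in kg: (slope, intercept) by
# sex and age band [lower, upper) in years.
SCHOFIELD = {
    "M": [(0.0, 3.0, 59.512, -30.4), (3.0, 10.0, 22.706, 504.3),
          (10.0, 18.0, 17.686, 658.2), (18.0, 30.0, 15.057, 692.2),
          (30.0, 60.0, 11.472, 873.1), (60.0, 200.0, 11.711, 587.7)],
    "F": [(0.0, 3.0, 58.317, -31.1), (3.0, 10.0, 20.315, 485.9),
          (10.0, 18.0, 13.384, 692.6), (18.0, 30.0, 14.818, 486.6),
          (30.0, 60.0, 8.126, 845.6), (60.0, 200.0, 9.082, 658.5)],
}

# Energy needed from complementary (non-breastmilk) foods, kcal/d, by age in
# months, for children below 24 months in a low/middle-income context.
COMPLEMENTARY_KCAL = [(0, 3, 0.0), (3, 6, 76.0), (6, 9, 269.0),
                      (9, 12, 451.0), (12, 24, 746.0)]

LACTATION_KCAL = 500.0

# Reference body-weight anchors (kg) for members whose weight the survey did
# not measure; linearly interpolated between ages.
_DEFAULT_WEIGHT_ANCHORS = {
    "M": [(0, 3.3), (1, 9.6), (2, 12.2), (5, 18.3), (10, 31.2), (15, 52.1),
          (18, 63.0), (30, 65.0), (60, 62.0)],
    "F": [(0, 3.2), (1, 8.9), (2, 11.5), (5, 17.9), (10, 31.9), (15, 51.5),
          (18, 55.0), (30, 57.0), (60, 55.0)],
}


@dataclass(frozen=True)
class MemberProfile:
    """One household member as needed for energy-requirement calculation."""

    member_id: str
    sex: str  # 'M' or 'F'
    age_years: float  # for children <2 y, months/12
    age_months: Optional[int] = None  # set only when below 24 months
    weight_kg: Optional[float] = None
    is_lactating: bool = False
    mother_member_id: Optional[str] = None  # this member's mother, if a child

    def __post_init__(self):
        if self.age_years < 0:
            raise ValueError(f"negative age for member {self.member_id}")
        if self.is_lactating and self.sex != "F":
            raise ValueError(f"lactating male member {self.member_id}")


@dataclass
class EnergyRequirementTable:
    """Configurable energy-requirement model at a fixed activity level.

    The defaults implement Schofield BMR x PAL with the complementary-food
    energies and lactation bonus documented in the module docstring.
    ``reference_weight_kg`` defines the reference woman (18–29.9 y); her EER
    is the AFE denominator.
    """

    pal: float = 1.85
    reference_weight_kg: float = 55.0
    lactation_kcal: float = LACTATION_KCAL
    complementary_kcal: list = field(default_factory=lambda: list(COMPLEMENTARY_KCAL))
    schofield: dict = field(default_factory=lambda: {s: list(v) for s, v in SCHOFIELD.items()})
    global_adult_male_weight_kg: float = 65.0
    default_weight_anchors: dict = field(
        default_factory=lambda: {s: list(v) for s, v in _DEFAULT_WEIGHT_ANCHORS.items()})

    @property
    def reference_eer(self) -> float:
        """EER (kcal/d) of the non-pregnant, non-lactating 18–29.9 y woman."""
        return self._bmr("F", 25.0, self.reference_weight_kg) * self.pal

    def _bmr(self, sex: str, age_years: float, weight_kg: float) -> float:
        for lo, hi, slope, intercept in self.schofield[sex]:
            if lo <= age_years < hi:
                return slope * weight_kg + intercept
        raise KeyError(f"no energy-requirement band covers age {age_years} ({sex})")

    def default_weight(self, age_years: float, sex: str) -> float:
        anchors = self.default_weight_anchors[sex]
        ages = [a for a, _ in anchors]
        wts = [w for _, w in anchors]
        return float(np.interp(age_years, ages, wts))


def resolve_weight(member: MemberProfile, table: EnergyRequirementTable,
                   roster: Optional[pd.DataFrame] = None) -> float:
    """Body weight (kg) for EER calculation, applying survey fallback rules.

    Measured weight wins. Otherwise: adult males take the global-database
    adult male weight; males aged 16–17 are interpolated at the two
    midpoints between the survey mean weight at 15 and the adult-male
    weight at 18; females above 50 take the mean measured weight of females
    aged 19–49 in the same survey file. Any remaining gap falls back to a
    weight-for-age reference table.

    ``roster`` is the full survey roster DataFrame (columns ``sex``,
    ``age_years``, ``weight_kg``) used for the survey-mean rules; without
    it those rules degrade to the reference table.
    """
    if member.weight_kg is not None and not (isinstance(member.weight_kg, float)
                                             and math.isnan(member.weight_kg)):
        return float(member.weight_kg)

    age, sex = member.age_years, member.sex

    def _survey_mean(sel_sex: str, lo: float, hi: float) -> Optional[float]:
        if roster is None:
            return None
        m = roster[(roster["sex"] == sel_sex)
                   & (roster["age_years"] >= lo) & (roster["age_years"] <= hi)]
        w = pd.to_numeric(m["weight_kg"], errors="coerce").dropna()
        return float(w.mean()) if len(w) else None

    if sex == "M" and age >= 18:
        return table.global_adult_male_weight_kg
    if sex == "M" and 16 <= age < 18:
        w15 = _survey_mean("M", 14.5, 15.5) or table.default_weight(15, "M")
        w18 = table.global_adult_male_weight_kg
        # two midpoints between the weights at 15 and 18 years of age
        frac = 1.0 / 3.0 if age < 17 else 2.0 / 3.0
        return w15 + frac * (w18 - w15)
    if sex == "F" and age > 50:
        w = _survey_mean("F", 19, 49)
        if w is not None:
            return w
    return table.default_weight(age, sex)


def member_eer(member: MemberProfile, table: EnergyRequirementTable,
               roster: Optional[pd.DataFrame] = None) -> float:
    """Estimated energy requirement (kcal/d) of one household member.

    Children below 24 months contribute only complementary-food energy
    (floored at zero); everyone else gets Schofield BMR x PAL at their
    resolved body weight; lactating women receive the lactation bonus.
    """
    months = member.age_months
    if months is None and member.age_years < 2:
        months = int(round(member.age_years * 12))
    if months is not None and months < 24:
        for lo, hi, kcal in table.complementary_kcal:
            if lo <= months < hi:
                return max(kcal, 0.0)
        raise KeyError(f"no complementary-energy band for age {months} months")
    weight = resolve_weight(member, table, roster)
    eer = table._bmr(member.sex, member.age_years, weight) * table.pal
    if member.is_lactating:
        eer += table.lactation_kcal
    return eer


def identify_lactating(roster: pd.DataFrame) -> pd.Series:
    """Flag assumed-lactating women: mothers of a child below 24 months.

    ``roster`` needs columns ``household_id``, ``member_id``, ``sex``,
    ``age_months`` (nullable; set for under-2s) and ``mother_member_id``
    (nullable; the child's link to its mother). Returns a boolean Series
    aligned to ``roster``. Each mother is flagged once however many young
    children she has; absent links produce no flags.
    """
    flags = pd.Series(False, index=roster.index)
    months = pd.to_numeric(roster.get("age_months"), errors="coerce")
    young = roster[(months.notna()) & (months < 24) & roster["mother_member_id"].notna()]
    mothers = set(zip(young["household_id"], young["mother_member_id"]))
    if mothers:
        keys = list(zip(roster["household_id"], roster["member_id"]))
        is_mother = pd.Series([k in mothers for k in keys], index=roster.index)
        flags = is_mother & (roster["sex"] == "F")
    return flags


def household_afe(roster: pd.DataFrame,
                  table: Optional[EnergyRequirementTable] = None) -> pd.DataFrame:
    """Number of adult female equivalents per household.

    AFE = sum of member EERs / EER of the reference woman. Households whose
    members all contribute zero energy requirement (e.g. a lone 1-month-old,
    a data artefact) are dropped with a warning.

    Returns a DataFrame with ``household_id`` and ``afe``.
    """
    if table is None:
        table = EnergyRequirementTable()
    if roster.empty:
        raise ValueError("empty roster")
    work = roster.copy()
    if "is_lactating" not in work.columns:
        work["is_lactating"] = identify_lactating(work)

    ref = table.reference_eer
    eers = np.empty(len(work))
    for i, row in enumerate(work.itertuples(index=False)):
        m = MemberProfile(
            member_id=str(row.member_id), sex=row.sex,
            age_years=float(row.age_years),
            age_months=None if pd.isna(getattr(row, "age_months", None))
            else int(row.age_months),
            weight_kg=None if pd.isna(getattr(row, "weight_kg", None))
            else float(row.weight_kg),
            is_lactating=bool(row.is_lactating),
        )
        eers[i] = member_eer(m, table, roster=work)
    work["_eer"] = eers
    afe = (work.groupby("household_id")["_eer"].sum() / ref).rename("afe").reset_index()
    zero = afe["afe"] <= 0
    if zero.any():
        logger.warning("dropping %d household(s) with AFE = 0", int(zero.sum()))
        afe = afe[~zero]
    return afe


def intake_per_afe(supply: pd.DataFrame, afe: pd.DataFrame) -> pd.DataFrame:
    """Divide per-household daily nutrient supplies by household AFE.

    ``supply`` has ``household_id`` plus nutrient columns (per day);
    households without a positive AFE are excluded. Units are preserved
    (a mg/d supply becomes mg/d per AFE).
    """
    merged = supply.merge(afe[afe["afe"] > 0], on="household_id", how="inner")
    nutrients = [c for c in supply.columns if c != "household_id"]
    out = merged[["household_id"]].copy()
    for c in nutrients:
        out[c] = merged[c] / merged["afe"]
    return out
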