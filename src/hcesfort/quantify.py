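"""Turn raw 7-day consumption records into edible grams/day and nutrients.

Steps, in pipeline order:

1. unit conversion to grams (:func:`to_grams`) — kg/g directly, volume
   units via item density, pieces via portion mass;
2. refuse subtraction (:func:`edible_grams`) to edible portion;
3. division by the recall period to grams per day;
4. outlier and missing-value cleaning (:func:`clean_quantities`) — log
   quantities more than 3 SD from the median of logs, and missing
   quantities, are replaced by the per-item median among consumers;
5. nutrient attachment (:func:`household_nutrient_supply`) against a food
   composition table, plus fortification-vehicle disaggregation of
   processed foods via recipes (:func:`vehicle_equivalents`).

Concatenated survey items (one line covering several foods) get their
composition as a consumption-frequency-weighted mean of the component
foods (:func:`composite_composition`).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .foods import NUTRIENTS, UNITS, VEHICLES, WHEAT_PRODUCTS

logger = logging.getLogger(__name__)


class UnresolvableUnitError(ValueError):
    """A record's unit cannot be converted to grams for its food."""


def to_grams(quantity: float, unit: str, food_code: str,
             portion_g: Optional[float] = None,
             density_g_ml: Optional[float] = None) -> float:
    """Convert a reported quantity to grams (as-purchased, refuse included).

    Volume units require the item's density (g/mL); ``pieces`` requires a
    portion mass (g/piece). A missing conversion factor raises
    :class:`UnresolvableUnitError` naming the food code.
    """
    if unit not in UNITS:
        raise UnresolvableUnitError(f"unknown unit {unit!r} for {food_code}")
    if unit == "kg":
        return quantity * 1000.0
    if unit == "g":
        return quantity
    if unit in ("L", "mL"):
        if density_g_ml is None or not density_g_ml > 0:
            raise UnresolvableUnitError(
                f"{food_code}: volume unit {unit!r} but no density available")
        return quantity * density_g_ml * (1000.0 if unit == "L" else 1.0)
    # pieces
    if portion_g is None or not portion_g > 0:
        raise UnresolvableUnitError(
            f"{food_code}: unit 'pieces' but no portion mass available")
    return quantity * portion_g


def edible_grams(grams: float, refuse_fraction: float) -> float:
    """Remove the non-edible portion (peels, bones, shells)."""
    if not 0 <= refuse_fraction < 1:
        raise ValueError(f"refuse fraction {refuse_fraction} outside [0, 1)")
    return grams * (1.0 - refuse_fraction)


def records_to_daily_grams(consumption: pd.DataFrame,
                           refuse_density: pd.DataFrame,
                           portions: pd.DataFrame) -> pd.DataFrame:
    """Vectorised conversion of raw records to edible grams per day.

    ``consumption`` columns: household_id, food_code, quantity (NaN =
    missing), unit, source, recall_days. Returns household_id, food_code,
    source, grams_per_day (NaN where quantity was missing).
    """
    rd = refuse_density.set_index("food_code")
    pt = portions.set_index("food_code")["portion_g"]
    out = consumption[["household_id", "food_code", "source"]].copy()
    grams = np.empty(len(consumption))
    for i, row in enumerate(consumption.itertuples(index=False)):
        if pd.isna(row.quantity):
            grams[i] = np.nan
            continue
        code = row.food_code
        density = rd["density_g_ml"].get(code) if code in rd.index else None
        density = None if pd.isna(density) else float(density)
        portion = float(pt[code]) if code in pt.index else None
        g = to_grams(float(row.quantity), row.unit, code, portion, density)
        refuse = float(rd.loc[code, "refuse_fraction"]) if code in rd.index else 0.0
        grams[i] = edible_grams(g, refuse) / float(row.recall_days)
    out["grams_per_day"] = grams
    return out


def clean_quantities(daily: pd.DataFrame, z_limit: float = 3.0) -> pd.DataFrame:
    """Replace outlying and missing quantities with per-item consumer medians.

    Quantities are log-transformed (they are right-skewed); within each
    food item, values whose log deviates from the median of logs by more
    than ``z_limit`` standard deviations (of the logs) are treated as
    outliers. The yardstick SD for each value excludes that value
    (leave-one-out): a gross recording error would otherwise inflate its
    own spread estimate and mask itself in small samples. Outliers and
    missing values are replaced by the median untransformed quantity among
    consuming households of that item.

    Items with fewer than two non-missing consumers cannot define a spread
    and pass through unflagged; items with no non-missing values at all are
    dropped with a warning.

    Returns the input plus boolean ``was_outlier`` and ``was_imputed``
    columns, with ``grams_per_day`` replaced where flagged.
    """
    parts = []
    for code, grp in daily.groupby("food_code", sort=False):
        grp = grp.copy()
        vals = grp["grams_per_day"]
        obs = vals[vals.notna() & (vals > 0)]
        grp["was_outlier"] = False
        grp["was_imputed"] = vals.isna()
        if len(obs) == 0:
            logger.warning("food %s: all quantities missing; item dropped", code)
            continue
        median = float(obs.median())
        if len(obs) >= 3:
            logs = np.log(obs.to_numpy(dtype=float))
            med_log = float(np.median(logs))
            n = len(logs)
            # leave-one-out SD of the logs, vectorised via sums
            s1, s2 = logs.sum(), (logs ** 2).sum()
            mean_loo = (s1 - logs) / (n - 1)
            var_loo = np.maximum(
                (s2 - logs ** 2 - (n - 1) * mean_loo ** 2) / (n - 2), 0.0)
            sd_loo = pd.Series(np.sqrt(var_loo), index=obs.index)
            dev = np.abs(np.log(vals.where(vals > 0)) - med_log)
            flag = ((dev > z_limit * sd_loo.reindex(vals.index))
                    & (sd_loo.reindex(vals.index) > 0)).fillna(False)
            grp["was_outlier"] = flag
        replace = grp["was_outlier"] | grp["was_imputed"]
        grp.loc[replace, "grams_per_day"] = median
        parts.append(grp)
    if not parts:
        raise ValueError("no usable consumption records")
    return pd.concat(parts, ignore_index=True)


def composite_composition(components: Iterable[tuple[pd.Series, float]],
                          code: str, name: str = "") -> pd.Series:
    """Weighted-mean composition for a concatenated survey item.

    ``components`` yields (composition row, frequency weight) pairs; the
    result's nutrient values are sum(w_i v_i)/sum(w_i) and its provenance
    label records the component codes.
    """
    components = list(components)
    if not components:
        raise ValueError(f"composite {code}: empty component list")
    total = sum(w for _, w in components)
    if any(w < 0 for _, w in components) or total <= 0:
        raise ValueError(f"composite {code}: weights must be >= 0 with positive sum")
    out = pd.Series(0.0, index=NUTRIENTS)
    for comp, w in components:
        out = out + comp[NUTRIENTS].astype(float) * (w / total)
    out["food_code"] = code
    out["food_name"] = name
    out["source_fct"] = "composite:" + "+".join(str(c.get("food_code", "?"))
                                                for c, _ in components)
    return out


def resolve_composites(fct: pd.DataFrame, component_weights: pd.DataFrame) -> pd.DataFrame:
    """Fill in concatenated items' rows from their components.

    ``component_weights`` columns: composite_code, component_code,
    frequency_weight. Component rows must exist in ``fct``; the returned
    table has one row per food code with composites resolved.
    """
    fct = fct.set_index("food_code", drop=False)
    rows = []
    for comp_code, grp in component_weights.groupby("composite_code"):
        pairs = []
        for r in grp.itertuples(index=False):
            if r.component_code not in fct.index:
                raise KeyError(f"composite {comp_code}: missing component "
                               f"{r.component_code} in composition table")
            pairs.append((fct.loc[r.component_code], float(r.frequency_weight)))
        name = (fct.loc[comp_code, "food_name"] if comp_code in fct.index else comp_code)
        rows.append(composite_composition(pairs, comp_code, name))
    resolved = pd.DataFrame(rows)
    keep = fct[~fct["food_code"].isin(resolved["food_code"])]
    merged = pd.concat([keep, resolved], ignore_index=True)
    return merged.reset_index(drop=True)


def vehicle_equivalents(cleaned: pd.DataFrame, recipes: pd.DataFrame) -> pd.DataFrame:
    """Per-household fortifiable-vehicle grams/day, recipes included.

    Wheat flour and cooking oil count both direct consumption and their
    share of processed products (bread; buns, cakes and biscuits; sweets)
    via recipe mass fractions. Macaroni/spaghetti is excluded by design:
    the provenance of its flour is unknown. Maize flour is direct-only.
    Products for which the recipe table has no entry are skipped with a
    warning.
    """
    rec = {(r.product_code, r.ingredient_code): float(r.mass_fraction)
           for r in recipes.itertuples(index=False)}
    known_products = {p for p, _ in rec}
    missing = (set(WHEAT_PRODUCTS) - known_products)
    for p in missing:
        logger.warning("recipe table lacks product %s; excluded from equivalents", p)

    hh = cleaned.groupby(["household_id", "food_code"])["grams_per_day"].sum().unstack(
        fill_value=0.0)

    out = pd.DataFrame(index=hh.index)
    for vehicle in VEHICLES:
        total = hh[vehicle].copy() if vehicle in hh.columns else pd.Series(0.0, index=hh.index)
        if vehicle != "maize_flour":  # maize flour has no recipe products
            for (product, ingredient), frac in rec.items():
                if ingredient == vehicle and product in hh.columns:
                    total = total + hh[product] * frac
        out[vehicle] = total
    return out.reset_index()


def household_nutrient_supply(cleaned: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Daily household nutrient totals from cleaned quantities and an FCT.

    supply(nutrient) = sum over items of grams/day / 100 x per-100 g value.
    Every consumed food code must have a composition row; unmatched codes
    are a hard error listing the offenders.
    """
    unmatched = sorted(set(cleaned["food_code"]) - set(fct["food_code"]))
    if unmatched:
        raise KeyError(f"no composition match for food codes: {', '.join(unmatched)}")
    merged = cleaned.merge(fct[["food_code"] + NUTRIENTS], on="food_code", how="left")
    for n in NUTRIENTS:
        merged[n] = merged["grams_per_day"] / 100.0 * merged[n].astype(float)
    supply = merged.groupby("household_id")[NUTRIENTS].sum().reset_index()
    return supply


def exclude_zero_consumption(households: pd.DataFrame,
                             consumption: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop households that reported no food in the recall period.

    Returns the retained household table and the number excluded.
    """
    reporting = set(consumption["household_id"])
    keep = households["household_id"].isin(reporting)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d household(s) with no reported food consumption",
                    n_excluded)
    return households[keep].reset_index(drop=True), n_excluded
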