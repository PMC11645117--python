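"""CSV/YAML interchange with schema validation.

All tables travel as UTF-8 CSV with documented headers. Reads are
validated immediately: column presence, types, closed vocabularies (units,
sources, sexes) and positivity constraints, with errors naming the column
and offending row. Fortification parameters, thresholds and the iron risk
curve load from small structured config files so that country-specific
values can be dropped in without code changes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adequacy import IronRiskCurve, ThresholdSet
from .foods import NUTRIENTS, SOURCES, UNITS
from .fortification import FortificationSpec


class SchemaError(ValueError):
    """A table failed validation; message names column and row."""


def _require(df: pd.DataFrame, table: str, columns: list[str]):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {', '.join(missing)}")


def _check_vocab(df, table, column, allowed):
    bad = df[~df[column].isin(allowed) & df[column].notna()]
    if len(bad):
        row = bad.index[0]
        raise SchemaError(f"{table}: column {column!r} row {row}: "
                          f"value {bad[column].iloc[0]!r} not in {sorted(allowed)}")


def _check_positive(df, table, column, allow_nan=False, strict=True):
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() & df[column].notna()  # non-numeric entries
    if not allow_nan:
        bad = bad | df[column].isna()
    bad = bad | ((vals <= 0) if strict else (vals < 0))
    if bad.any():
        row = bad.idxmax()
        raise SchemaError(f"{table}: column {column!r} row {row}: "
                          f"value {df[column].loc[row]!r} fails positivity check")


def validate_roster(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, "roster", ["household_id", "member_id", "sex", "age_years",
                            "stratum", "cluster", "urban", "survey_weight"])
    _check_vocab(df, "roster", "sex", {"M", "F"})
    _check_positive(df, "roster", "age_years", strict=False)
    _check_positive(df, "roster", "survey_weight")
    return df


def validate_consumption(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, "consumption", ["household_id", "food_code", "quantity",
                                 "unit", "source", "recall_days"])
    _check_vocab(df, "consumption", "unit", set(UNITS))
    _check_vocab(df, "consumption", "source", set(SOURCES))
    _check_positive(df, "consumption", "quantity", allow_nan=True)
    _check_positive(df, "consumption", "recall_days")
    return df


def validate_fct(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, "fct", ["food_code"] + NUTRIENTS)
    for n in NUTRIENTS:
        _check_positive(df, "fct", n, strict=False)
    return df


def validate_refuse_density(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, "refuse_density", ["food_code", "refuse_fraction", "density_g_ml"])
    bad = (pd.to_numeric(df["refuse_fraction"], errors="coerce") >= 1) \
        | (pd.to_numeric(df["refuse_fraction"], errors="coerce") < 0)
    if bad.any():
        row = bad.idxmax()
        raise SchemaError(f"refuse_density: refuse_fraction row {row} outside [0, 1)")
    _check_positive(df, "refuse_density", "density_g_ml", allow_nan=True)
    return df


def validate_recipes(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, "recipes", ["product_code", "ingredient_code", "mass_fraction"])
    frac = pd.to_numeric(df["mass_fraction"], errors="coerce")
    bad = frac.isna() | (frac <= 0) | (frac > 1)
    if bad.any():
        row = bad.idxmax()
        raise SchemaError(f"recipes: mass_fraction row {row} outside (0, 1]")
    sums = df.groupby("product_code")["mass_fraction"].sum()
    over = sums[sums > 1 + 1e-9]
    if len(over):
        raise SchemaError(f"recipes: ingredient fractions of {over.index[0]!r} exceed 1")
    return df


def validate_portions(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, "portions", ["food_code", "portion_g"])
    _check_positive(df, "portions", "portion_g")
    return df


def validate_weights(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, "weights", ["composite_code", "component_code", "frequency_weight"])
    _check_positive(df, "weights", "frequency_weight", strict=False)
    return df


_VALIDATORS = {
    "roster": validate_roster,
    "consumption": validate_consumption,
    "fct": validate_fct,
    "refuse_density": validate_refuse_density,
    "recipes": validate_recipes,
    "portions": validate_portions,
    "weights": validate_weights,
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one known table kind from CSV."""
    df = pd.read_csv(path)
    if kind == "roster" and "age_months" in df.columns:
        df["age_months"] = df["age_months"].astype("Int64")
    return _VALIDATORS[kind](df)


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write a dict of DataFrames as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def load_fortification_spec(path: str | Path) -> FortificationSpec:
    """Fortification parameters from a YAML file mirroring the A/B/C columns.

    Format: a list of mappings with keys ``vehicle``, ``nutrient``,
    ``standard_mg_kg`` (A), ``compliance`` (B) and ``loss`` (C).
    """
    with open(path, encoding="utf-8") as fh:
        rows = yaml.safe_load(fh)
    return FortificationSpec.from_rows(rows)


def load_thresholds(path: str | Path) -> ThresholdSet:
    """H-AR/H-UL thresholds from YAML with ``har`` and ``hul`` mappings."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ThresholdSet(har=data.get("har", {}), hul=data.get("hul", {}),
                        zinc_ul_authority=data.get("zinc_ul_authority", "efsa"))


def load_iron_curve(path: str | Path) -> IronRiskCurve:
    """Iron risk curve from a two-column CSV (intake_mg_d, risk)."""
    df = pd.read_csv(path)
    return IronRiskCurve(np.asarray(df["intake_mg_d"], dtype=float),
                         np.asarray(df["risk"], dtype=float))
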