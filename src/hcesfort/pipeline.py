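"""End-to-end pipeline driver: simulate -> quantify -> AFE -> scenarios -> adequacy."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__, adequacy, afe, fortification, io, quantify, synthetic

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


class PipelineConfig(BaseModel):
    """Driver configuration.

    Leave the table paths unset to run on a synthetic survey generated
    with ``seed``; point them at CSV files (schema per :mod:`hcesfort.io`)
    to analyse real or externally prepared data.
    """

    roster: Optional[str] = None
    consumption: Optional[str] = None
    fct: Optional[str] = None
    recipes: Optional[str] = None
    portions: Optional[str] = None
    refuse_density: Optional[str] = None
    weights: Optional[str] = None  # composite-component frequency weights
    fortification_spec: Optional[str] = None  # YAML, defaults to built-in
    thresholds: Optional[str] = None          # YAML, defaults to built-in
    iron_curve: Optional[str] = None          # CSV, defaults to built-in
    scenarios: list[str] = Field(default_factory=lambda: list(fortification.SCENARIOS))
    design: Optional[dict] = None  # synthetic survey-design overrides
    seed: int = 0
    outdir: str = "hcesfort_out"
    purchased_only: bool = False  # fortify only purchased vehicle quantities
    unweighted: bool = False      # ignore survey weights in summaries


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("load")
def _load_inputs(config: PipelineConfig):
    table_keys = ["roster", "consumption", "fct", "recipes", "portions",
                  "refuse_density", "weights"]
    paths = {k: getattr(config, k) for k in table_keys}
    set_paths = [k for k, v in paths.items() if v]
    if set_paths and len(set_paths) != len(table_keys):
        missing = sorted(set(table_keys) - set(set_paths))
        raise FileNotFoundError(f"partial input set; missing table path(s): {missing}")
    if set_paths:
        for k, v in paths.items():
            if not Path(v).exists():
                raise FileNotFoundError(f"{k} table not found at {v}")
        tables = {k: io.read_table(v, k) for k, v in paths.items()}
    else:
        design = (synthetic.SurveyDesignConfig(**config.design)
                  if config.design else None)
        roster, consumption, _gt = synthetic.generate_survey(design=design,
                                                             seed=config.seed)
        tables = {"roster": roster, "consumption": consumption,
                  **synthetic.generate_fixtures(config.seed)}
    spec = (io.load_fortification_spec(config.fortification_spec)
            if config.fortification_spec else fortification.default_spec())
    thresholds = (io.load_thresholds(config.thresholds)
                  if config.thresholds else adequacy.ThresholdSet())
    curve = (io.load_iron_curve(config.iron_curve)
             if config.iron_curve else adequacy.DEFAULT_IRON_CURVE)
    return tables, spec, thresholds, curve


@_stage("quantify")
def _quantify(tables, purchased_only: bool):
    fct = quantify.resolve_composites(tables["fct"], tables["weights"])
    daily = quantify.records_to_daily_grams(tables["consumption"],
                                            tables["refuse_density"],
                                            tables["portions"])
    cleaned = quantify.clean_quantities(daily)
    fortifiable = (cleaned[cleaned["source"] == "purchase"] if purchased_only
                   else cleaned)
    veh = quantify.vehicle_equivalents(fortifiable, tables["recipes"])
    supply = quantify.household_nutrient_supply(cleaned, fct)
    return cleaned, veh, supply


@_stage("afe")
def _afe(roster: pd.DataFrame, kept_ids) -> pd.DataFrame:
    return afe.household_afe(roster[roster["household_id"].isin(kept_ids)])


@_stage("scenarios")
def _scenarios(supply, afe_df, veh, spec, scenario_names):
    base = afe.intake_per_afe(supply, afe_df)
    frames = [fortification.apply_scenario(base, veh, afe_df, spec, s)
              for s in scenario_names]
    return pd.concat(frames, ignore_index=True)


@_stage("adequacy")
def _adequacy(intakes_long, veh, meta, afe_df, thresholds, curve, weighted):
    return adequacy.stratified_summaries(intakes_long, veh, meta, afe_df,
                                         thresholds, curve, weighted=weighted)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the output CSV families plus a run log.

    Outputs land in ``config.outdir``: cleaned_quantities, vehicle
    equivalents, household supply and AFE, per-scenario intakes, and the
    five summary families (coverage, intake summaries, inadequacy, excess,
    gaps). Deterministic given the seed. Nothing is written until every
    stage has succeeded.
    """
    tables, spec, thresholds, curve = _load_inputs(config)

    households = tables["roster"].drop_duplicates("household_id")[
        ["household_id", "stratum", "cluster", "urban", "survey_weight"]]
    households, n_excluded = quantify.exclude_zero_consumption(
        households, tables["consumption"])

    cleaned, veh, supply = _quantify(tables, config.purchased_only)
    afe_df = _afe(tables["roster"], set(households["household_id"]))
    intakes = _scenarios(supply, afe_df, veh, spec, config.scenarios)
    summaries = _adequacy(intakes, veh, households, afe_df, thresholds, curve,
                          not config.unweighted)

    outdir = Path(config.outdir)
    io.write_tables({
        "cleaned_quantities": cleaned,
        "vehicle_equivalents": veh,
        "household_supply": supply,
        "household_afe": afe_df,
        "scenario_intakes": intakes,
        **summaries,
    }, outdir)

    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    log = {
        "hcesfort_version": __version__,
        "python": platform.python_version(),
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_households_analysed": int(households["household_id"].nunique()),
        "n_households_excluded_zero_consumption": n_excluded,
        "scenarios": config.scenarios,
        "weighted": not config.unweighted,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
    logger.info("pipeline complete: %s", outdir)
    return outdir
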