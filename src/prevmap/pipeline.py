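"""End-to-end orchestration: simulate -> select -> fit -> predict -> aggregate -> validate.

A single declarative configuration drives the run; every stage has its own
named seed, all outputs land under one directory, and a JSON manifest records
stage order, input checksums, outputs, seeds and durations so a run can be
verified and reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .aggregate import estimates_table, format_headline, population_weighted_aggregate
from .grids import CovariateStack, PopulationRaster
from .mapping import DEFAULT_THRESHOLDS, exceedance_probability, predict_grid
from .model import FittedModel, ModelSpec, fit
from .selection import build_design, empirical_variogram, fit_nonspatial_glm, \
    select_covariates
from .synthetic import AdminUnits
from .validation import kfold_cv, scatter_report

log = logging.getLogger("prevmap")

ALL_STAGES = ("simulate", "select", "fit", "predict", "aggregate", "validate")


class ConfigError(ValueError):
    """Raised when a pipeline configuration does not validate."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; earlier outputs are kept."""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "prevmap_run"
    stages: list[str] = dc_field(default_factory=lambda: list(ALL_STAGES))
    seeds: dict = dc_field(default_factory=dict)      # per-stage overrides
    base_seed: int = 0
    scenario: dict = dc_field(default_factory=dict)   # synthetic_data overrides
    model: dict = dc_field(default_factory=dict)      # ModelSpec overrides
    thresholds: list[float] = dc_field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    n_prediction_samples: int = 1000
    cv_folds: int = 10
    config_version: int = 1

    def stage_seed(self, stage: str) -> int:
        if stage in self.seeds:
            return int(self.seeds[stage])
        return int((self.base_seed * 1009 + ALL_STAGES.index(stage)) % 2**31)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        for t in cfg.thresholds:
            if not 0 <= t <= 1:
                raise ConfigError(f"threshold {t} outside [0, 1]")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksum_tree(paths: list[Path]) -> dict:
    out = {}
    for p in paths:
        if p.is_file():
            out[str(p)] = _sha256(p)
        elif p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _sha256(f)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_version": config.config_version, "stages": []}
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        seed = config.stage_seed(stage)
        t0 = time.perf_counter()
        log.info("stage %s starting (seed %d)", stage, seed)
        record = {"stage": stage, "seed": seed}
        try:
            inputs, outputs = _STAGE_FNS[stage](config, state, out, seed)
            record["inputs"] = _checksum_tree(inputs)
            record["outputs"] = _checksum_tree(outputs)
            record["status"] = "ok"
        except Exception as exc:
            record["status"] = "failed"
            record["error"] = f"{type(exc).__name__}: {exc}"
            manifest["stages"].append(record)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        record["duration_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(record)
        log.info("stage %s done in %.2fs", stage, record["duration_s"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config, state, out: Path, seed):
    scen = synthetic.make_scenario(seed=seed, **config.scenario)
    synthetic.save_scenario(scen, out / "inputs")
    state["scenario"] = scen
    return [], [out / "inputs"]


def _load_inputs(config, state, out: Path):
    src = out / "inputs"
    if "scenario" in state:
        scen = state["scenario"]
        return scen.survey, scen.truth.covariates, scen.population, scen.admin
    survey = pd.read_csv(src / "survey.csv")
    stack = CovariateStack.load(src / "covariates")
    pop = PopulationRaster.load(src / "population.asc")
    admin = AdminUnits.load(src / "admin.geojson")
    return survey, stack, pop, admin


def _stage_select(config, state, out: Path, seed):
    survey, stack, _, _ = _load_inputs(config, state, out)
    design = build_design(survey, stack)
    report = select_covariates(design)
    _, resid, _ = fit_nonspatial_glm(design, report.retained)
    vario = empirical_variogram(resid, design.coords,
                                max_dist=0.5 * stack.grid.diameter)
    sel_dir = out / "selection"
    sel_dir.mkdir(exist_ok=True)
    report.save(sel_dir / "selection.json")
    vario.to_csv(sel_dir / "variogram.csv", index=False)
    state["design"], state["report"] = design, report
    return [out / "inputs"], [sel_dir]


def _stage_fit(config, state, out: Path, seed):
    survey, stack, _, _ = _load_inputs(config, state, out)
    if "report" not in state:
        raise StageError("fit requires the select stage (no retained covariates found)")
    design, report = state["design"], state["report"]
    spec = ModelSpec.from_dict({
        "covariates": report.retained, "seed": seed, **config.model})
    model = fit(design, spec)
    model.save(out / "model")
    model.summary().to_csv(out / "model" / "summary.csv", index=False)
    state["model"], state["spec"] = model, spec
    return [out / "selection"], [out / "model"]


def _stage_predict(config, state, out: Path, seed):
    _, stack, _, _ = _load_inputs(config, state, out)
    model = state.get("model") or FittedModel.load(out / "model")
    n = min(config.n_prediction_samples, model.n_draws)
    pg = predict_grid(model, stack, n_samples=n, seed=seed)
    pred_dir = out / "predictions"
    pg.save(pred_dir)
    for surf in exceedance_probability(pg, tuple(config.thresholds)):
        surf.save(pred_dir / f"exceed_{int(round(100 * surf.threshold)):02d}pct.asc")
    state["prediction"] = pg
    return [out / "model"], [pred_dir]


def _stage_aggregate(config, state, out: Path, seed):
    _, _, pop, admin = _load_inputs(config, state, out)
    pg = state["prediction"]
    estimates = population_weighted_aggregate(pg, pop, admin)
    agg_dir = out / "aggregates"
    agg_dir.mkdir(exist_ok=True)
    estimates_table(estimates).to_csv(agg_dir / "admin_estimates.csv", index=False,
                                      float_format="%.10g")
    format_headline(estimates).to_csv(agg_dir / "headline.csv", index=False)
    gj = admin.to_geojson()
    for feat, e in zip(gj["features"], estimates):
        feat["properties"].update({
            "prev_mean": e.prev_mean, "prev_lo": e.prev_lo, "prev_hi": e.prev_hi,
            "count_mean": e.count_mean, "count_lo": e.count_lo,
            "count_hi": e.count_hi, "population": e.population,
        })
    (agg_dir / "admin_estimates.geojson").write_text(json.dumps(gj))
    return [out / "predictions"], [agg_dir]


def _stage_validate(config, state, out: Path, seed):
    design = state["design"]
    spec = state["spec"]
    cv = kfold_cv(design, spec, k=config.cv_folds, seed=seed,
                  full_model=state.get("model"))
    val_dir = out / "validation"
    val_dir.mkdir(exist_ok=True)
    scatter_report(cv).to_csv(val_dir / "observed_vs_predicted.csv", index=False)
    (val_dir / "metrics.json").write_text(json.dumps(cv.metrics(), indent=2))
    state["cv"] = cv
    return [out / "model"], [val_dir]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "select": _stage_select,
    "fit": _stage_fit,
    "predict": _stage_predict,
    "aggregate": _stage_aggregate,
    "validate": _stage_validate,
}
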