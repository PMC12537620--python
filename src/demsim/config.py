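"""Layered run configuration, seed management, and the full pipeline.

A single YAML file (all keys optional, validated against a known-key
schema) drives ``run_all``: generate inputs, calibrate per sex, simulate
all scenarios, write the outcome reports, and run the sensitivity sweep.
All randomness flows from one master seed through named substreams, and a
manifest records the config hash, seeds and every output path so a rerun
with the same config reproduces byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibrate import CalibrationTargets, GAOptions, calibrate
from .cohort import StageParams
from .inputs import (
    IncidenceSchedule,
    LifeTable,
    default_synthetic_inputs,
    load_risk_config,
)
from .model import DementiaModel
from .outcomes import by_age_tables, outcome_table
from .risk import ScenarioSpec, default_scenarios, load_scenarios
from .sensitivity import run_sensitivity, tornado_table
from .simulate import SimulationConfig, simulate_batch


class ConfigError(ValueError):
    """Unknown or invalid configuration key."""


_SCHEMA: dict[str, dict | None] = {
    "sexes": None,
    "n_individuals": None,
    "master_seed": None,
    "max_age": None,
    "output_dir": None,
    "engine": None,
    "incidence_event": None,
    "inputs": {
        "kind": None,  # synthetic | reference_matched
        "rate_at_65": None,
        "doubling_time": None,
        "trend_decline_per_decade": None,
        "life_expectancy_female": None,
        "life_expectancy_male": None,
    },
    "calibration": {
        "method": None,
        "rtol": None,
        "max_iter": None,
        "ga": {
            "population_size": None,
            "n_generations": None,
            "tournament_size": None,
            "crossover_prob": None,
            "blend_alpha": None,
            "mutation_prob": None,
            "mutation_sigma": None,
            "sigma_decay": None,
            "objective_tol": None,
        },
    },
    "stages": {
        "p_mci_to_mild": None,
        "p_mild_to_moderate": None,
        "p_moderate_to_severe": None,
        "excess_mortality_mci": None,
        "excess_mortality_mild": None,
        "excess_mortality_moderate": None,
        "excess_mortality_severe": None,
        "collapsed": None,
    },
    "scenarios_file": None,
    "sensitivity": {"enabled": None, "engine": None},
}

DEFAULT_CONFIG: dict = {
    "sexes": ["female", "male"],
    "n_individuals": 200_000,
    "master_seed": 1,
    "max_age": 100,
    "output_dir": "demsim_output",
    "engine": "micro",
    "incidence_event": "dementia_entry",
    "inputs": {
        "kind": "synthetic",
        "rate_at_65": 0.002,
        "doubling_time": 5.5,
        "trend_decline_per_decade": 0.0,
    },
    "calibration": {"method": "analytic", "rtol": 1e-6, "max_iter": 200},
    "stages": {},
    "scenarios_file": None,
    "sensitivity": {"enabled": True, "engine": "oracle"},
}


def _validate(cfg: dict, schema: dict, prefix: str = "") -> None:
    for key, value in cfg.items():
        if key not in schema:
            raise ConfigError(f"unknown configuration key: {prefix}{key}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, dict):
            _validate(value, sub, prefix=f"{prefix}{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally layered with a YAML file and explicit overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _validate(user, _SCHEMA)
        cfg = _merge(cfg, user)
    if overrides:
        _validate(overrides, _SCHEMA)
        cfg = _merge(cfg, overrides)
    _validate(cfg, _SCHEMA)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Named substreams from one master seed (all below 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    names = ("calibration", "simulation", "sensitivity")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seeds, outputs."""

    config_hash: str
    master_seed: int
    seeds: dict[str, int]
    started: str
    outputs: dict[str, str] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _build_model(cfg: dict, sex: str) -> DementiaModel:
    stage = StageParams(**cfg["stages"])
    inp = cfg["inputs"]
    if inp.get("kind", "synthetic") == "reference_matched":
        return DementiaModel.from_reference_matched(
            sex,
            max_age=cfg["max_age"],
            stage=stage,
            incidence_event=cfg["incidence_event"],
        )
    e0 = inp.get(f"life_expectancy_{sex}")
    table, inc = default_synthetic_inputs(
        sex,
        max_age=cfg["max_age"],
        rate_at_65=inp.get("rate_at_65", 0.002),
        doubling_time=inp.get("doubling_time", 5.5),
        trend_decline_per_decade=inp.get("trend_decline_per_decade", 0.0),
        life_expectancy=e0,
    )
    return DementiaModel(
        table, inc, load_risk_config(sex), stage, cfg["incidence_event"]
    )


def run_all(cfg: dict, output_dir: str | Path | None = None) -> RunManifest:
    """Execute the full pipeline and return the manifest.

    Stages: generate-inputs, calibrate (per sex), simulate (all scenarios,
    shared CRN), report, sensitivity.  Deterministic under a fixed master
    seed; output CSV/JSON files carry no timestamps, so reruns are
    byte-identical.
    """
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(cfg["master_seed"])
    manifest = RunManifest(
        config_hash=config_hash(cfg),
        master_seed=cfg["master_seed"],
        seeds=seeds,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest_path = out / "manifest.json"
    try:
        scenarios = (
            load_scenarios(cfg["scenarios_file"])
            if cfg["scenarios_file"]
            else default_scenarios()
        )
        models = {}
        all_tables = []
        for sex in cfg["sexes"]:
            model = _build_model(cfg, sex)
            model.life_table.to_csv(out / f"life_table_{sex}.csv")
            model.incidence.to_csv(out / f"incidence_{sex}.csv")
            manifest.outputs[f"life_table_{sex}"] = str(out / f"life_table_{sex}.csv")
            manifest.outputs[f"incidence_{sex}"] = str(out / f"incidence_{sex}.csv")
            if "generate-inputs" not in manifest.completed_stages:
                manifest.completed_stages.append("generate-inputs")

            cal = cfg["calibration"]
            ga = GAOptions(**cal.get("ga", {})) if cal.get("ga") else None
            fit = model.fit(
                method=cal["method"],
                seed=seeds["calibration"],
                rtol=cal["rtol"],
                max_iter=cal["max_iter"],
                ga_options=ga,
            )
            fit.to_json(out / f"model_{sex}.json")
            manifest.outputs[f"model_{sex}"] = str(out / f"model_{sex}.json")
            models[sex] = fit
            if "calibrate" not in manifest.completed_stages:
                manifest.completed_stages.append("calibrate")

            if cfg["engine"] == "micro":
                sim = SimulationConfig(
                    n_individuals=cfg["n_individuals"],
                    master_seed=seeds["simulation"],
                    sex=sex,
                    max_age=cfg["max_age"],
                )
                results = simulate_batch(fit, scenarios, sim)
            else:
                results = {s.label: fit.run_cohort(s) for s in scenarios}
                if "reference" not in results:
                    results["reference"] = fit.run_cohort()
            for label, res in results.items():
                p = out / f"cohort_{sex}_{label}.csv"
                res.to_csv(p)
                manifest.outputs[f"cohort_{sex}_{label}"] = str(p)
            if "simulate" not in manifest.completed_stages:
                manifest.completed_stages.append("simulate")

            table = outcome_table(results)
            all_tables.append(table)
            for name, frame in by_age_tables(results).items():
                p = out / f"{name}_{sex}.csv"
                frame.to_csv(p, index=False)
                manifest.outputs[f"{name}_{sex}"] = str(p)
        combined = __import__("pandas").concat(all_tables, ignore_index=True)
        combined.to_csv(out / "table2.csv", index=False)
        manifest.outputs["table2"] = str(out / "table2.csv")
        if "report" not in manifest.completed_stages:
            manifest.completed_stages.append("report")

        if cfg["sensitivity"]["enabled"]:
            records = run_sensitivity(
                models,
                engine=cfg["sensitivity"].get("engine", "oracle"),
                n=cfg["n_individuals"],
                seed=seeds["sensitivity"],
                calibration_method=cfg["calibration"]["method"],
            )
            records.to_csv(out / "sensitivity.csv", index=False)
            tornado_table(records).to_csv(out / "tornado.csv", index=False)
            manifest.outputs["sensitivity"] = str(out / "sensitivity.csv")
            manifest.outputs["tornado"] = str(out / "tornado.csv")
            manifest.completed_stages.append("sensitivity")
    finally:
        manifest.write(manifest_path)
        manifest.outputs["manifest"] = str(manifest_path)
    return manifest
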