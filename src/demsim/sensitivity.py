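"""Univariate sensitivity analysis over the risk-factor parameter CIs.

Each of the six uncertain parameters (two prevalences, two dementia RRs,
two mortality RRs) is set to its lower and upper 95%-CI bound in turn, the
model is re-calibrated, and the percentage of potentially avoidable
dementia cases under complete elimination of each factor is recomputed.
Sign reversals -- cases *increasing* under a reduction, which happens when
the mortality benefit of removing an exposure outweighs its dementia
benefit -- are flagged explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import CalibratedModel, CalibrationError, build_sensitivity_models
from .cohort import StageParams
from .outcomes import compare, summarize
from .risk import ScenarioSpec
from .simulate import SimulationConfig, simulate

DEFAULT_SENSITIVITY_SCENARIOS = (
    ScenarioSpec("smoking_100", 1.0, 0.0),
    ScenarioSpec("hypertension_100", 0.0, 1.0),
)


def _avoidable_cases_pct(
    model: CalibratedModel,
    scenario: ScenarioSpec,
    engine: str,
    n: int,
    seed: int,
) -> float:
    """Percent of dementia cases avoided by a scenario (positive = fewer)."""
    if engine == "oracle":
        ref = model.run_cohort()
        alt = model.run_cohort(scenario)
    elif engine == "micro":
        cfg = SimulationConfig(n_individuals=n, master_seed=seed, sex=model.sex)
        ref = simulate(model, None, cfg)
        alt = simulate(model, scenario, cfg)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    cmp = compare(summarize(ref), summarize(alt, standard=ref))
    return -cmp.pct_change["total_cases"]


def run_sensitivity(
    models_by_sex: dict[str, CalibratedModel],
    scenarios: tuple[ScenarioSpec, ...] = DEFAULT_SENSITIVITY_SCENARIOS,
    engine: str = "oracle",
    n: int = 200_000,
    seed: int = 0,
    stage: StageParams | None = None,
    calibration_method: str = "analytic",
) -> pd.DataFrame:
    """The full univariate sweep: 12 re-calibrated models per sex plus base.

    ``models_by_sex`` maps sex to the base-case calibrated model; its inputs
    and risk configuration are reused for the re-calibrations.  Returns one
    record per model x scenario with the percent of potentially avoidable
    cases and a sign flag (``increase`` marks a reversal: more cases under
    the reduction).  Calibration failures are reported per-record, not
    raised.
    """
    records = []
    for sex, base in models_by_sex.items():
        variants: dict[tuple[str, str], CalibratedModel | None] = {
            ("point", "point"): base
        }
        try:
            variants.update(
                build_sensitivity_models(
                    base.risk_config,
                    base.life_table,
                    base.incidence,
                    stage=stage or base.rates.stage,
                    method=calibration_method,
                    seed=base.seed or 0,
                )
            )
        except CalibrationError as err:
            records.append(
                {"sex": sex, "parameter": "all", "bound": "n/a", "scenario": "n/a",
                 "avoidable_cases_pct": np.nan, "sign": "calibration_failure",
                 "note": str(err)}
            )
            continue
        for (param, bound), model in variants.items():
            for scenario in scenarios:
                if model is None:
                    continue
                try:
                    pct = _avoidable_cases_pct(model, scenario, engine, n, seed)
                    note = ""
                except CalibrationError as err:  # pragma: no cover - defensive
                    pct, note = np.nan, str(err)
                records.append(
                    {
                        "sex": sex,
                        "parameter": param,
                        "bound": bound,
                        "scenario": scenario.label,
                        "avoidable_cases_pct": pct,
                        "sign": (
                            "decrease" if pct > 0 else "increase" if pct < 0 else "reference"
                        ),
                        "note": note,
                    }
                )
    return pd.DataFrame.from_records(records)


def tornado_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per parameter x scenario x sex: lower / point / upper avoidable %."""
    point = records[records["parameter"] == "point"]
    rows = []
    for (sex, scenario), grp in records.groupby(["sex", "scenario"]):
        base = point[(point["sex"] == sex) & (point["scenario"] == scenario)]
        base_pct = float(base["avoidable_cases_pct"].iloc[0]) if len(base) else np.nan
        for param, pgrp in grp[grp["parameter"] != "point"].groupby("parameter"):
            lo = pgrp[pgrp["bound"] == "lower"]["avoidable_cases_pct"]
            hi = pgrp[pgrp["bound"] == "upper"]["avoidable_cases_pct"]
            rows.append(
                {
                    "sex": sex,
                    "scenario": scenario,
                    "parameter": param,
                    "lower": float(lo.iloc[0]) if len(lo) else np.nan,
                    "point": base_pct,
                    "upper": float(hi.iloc[0]) if len(hi) else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["spread"] = (out["upper"] - out["lower"]).abs()
    return out.sort_values(["sex", "scenario", "spread"], ascending=[True, True, False]).reset_index(
        drop=True
    )
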