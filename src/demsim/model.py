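"""Top-level modelling interface.

``DementiaModel`` bundles the inputs of one sex-specific analysis -- an
other-cause life table, a dementia-onset incidence schedule, and the
risk-factor parameter set -- and ``fit()`` calibrates it, returning a
:class:`~demsim.calibrate.CalibratedModel` results object from which cohort
runs, microsimulations, scenario outcomes and summaries are obtained::

    model = DementiaModel.from_synthetic("female")
    res = model.fit()
    print(res.summary())
    ref = res.run_cohort()

Two constructors build synthetic stand-in inputs: ``from_synthetic`` uses
the package defaults, while ``from_reference_matched`` additionally tunes
the mortality level to a target cohort life expectancy and the incidence
level so the *reference* scenario reproduces a published lifetime risk of
dementia at age 65 (54.5% for women, 35.5% for men).  Scenario effects are
never tuned; they are genuine model outputs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .calibrate import CalibratedModel, CalibrationTargets, GAOptions, calibrate
from .cohort import StageParams
from .inputs import (
    DEFAULT_DOUBLING_TIME,
    DEFAULT_LIFE_EXPECTANCY,
    DEFAULT_MAX_AGE,
    DEFAULT_TREND_DECLINE,
    IncidenceSchedule,
    LifeTable,
    default_synthetic_inputs,
    fit_gompertz_to_life_expectancy,
    load_risk_config,
    make_incidence_schedule,
    make_life_table,
)
from .risk import RiskGroupConfig

#: published reference lifetime risk (%) of dementia at age 65, by sex,
#: used only as a calibration target for the reference-matched inputs
REFERENCE_LIFETIME_RISK_65 = {"female": 54.5, "male": 35.5}


class DementiaModel:
    """Multistate dementia natural-history model for one sex.

    Parameters
    ----------
    life_table : LifeTable
        Annual other-cause death probabilities of the simulated cohort.
    incidence : IncidenceSchedule
        Population-average dementia-onset hazard by age.
    risk_config : RiskGroupConfig
        Exposure prevalence targets, relative risks and age windows.
    stage : StageParams, optional
        Dementia stage dwell-time and mortality parameters.
    incidence_event : {"dementia_entry", "mci_entry"}
        Which transition is counted as a dementia onset in the outcomes.
    """

    def __init__(
        self,
        life_table: LifeTable,
        incidence: IncidenceSchedule,
        risk_config: RiskGroupConfig,
        stage: StageParams | None = None,
        incidence_event: str = "dementia_entry",
    ):
        if life_table.sex != risk_config.sex:
            raise ValueError("life table and risk config are for different sexes")
        self.life_table = life_table
        self.incidence = incidence
        self.risk_config = risk_config
        self.stage = stage if stage is not None else StageParams()
        self.incidence_event = incidence_event

    @property
    def sex(self) -> str:
        return self.risk_config.sex

    @classmethod
    def from_synthetic(
        cls,
        sex: str,
        max_age: int = DEFAULT_MAX_AGE,
        stage: StageParams | None = None,
        incidence_event: str = "dementia_entry",
        **input_kw,
    ) -> "DementiaModel":
        """Model on the default synthetic stand-in inputs for one sex."""
        table, inc = default_synthetic_inputs(sex, max_age=max_age, **input_kw)
        return cls(table, inc, load_risk_config(sex), stage, incidence_event)

    @classmethod
    def from_reference_matched(
        cls,
        sex: str,
        lifetime_risk_target: float | None = None,
        life_expectancy_target: float | None = None,
        doubling_time: float = DEFAULT_DOUBLING_TIME,
        trend_decline_per_decade: float | None = None,
        max_age: int = DEFAULT_MAX_AGE,
        stage: StageParams | None = None,
        incidence_event: str = "dementia_entry",
    ) -> "DementiaModel":
        """Synthetic inputs tuned to reference-scenario targets.

        The Gompertz level is adjusted so the calibrated reference cohort's
        all-cause life expectancy (dementia mortality included) matches the
        target, and the incidence level so the reference lifetime risk of
        dementia at 65 matches the target.  Both are properties of the
        *reference* scenario only.
        """
        lr_target = (
            lifetime_risk_target
            if lifetime_risk_target is not None
            else REFERENCE_LIFETIME_RISK_65[sex]
        )
        e0_target = (
            life_expectancy_target
            if life_expectancy_target is not None
            else DEFAULT_LIFE_EXPECTANCY[sex]
        )
        cfg = load_risk_config(sex)
        stage = stage if stage is not None else StageParams()
        trend = (
            trend_decline_per_decade
            if trend_decline_per_decade is not None
            else DEFAULT_TREND_DECLINE
        )

        def build(e0_table: float, rate: float):
            params = fit_gompertz_to_life_expectancy(e0_table, sex, max_age=max_age)
            table = make_life_table(params, sex, max_age)
            inc = make_incidence_schedule(
                rate, doubling_time, trend, sex=sex, max_age=max_age
            )
            fit = calibrate(
                CalibrationTargets.from_config(cfg, table, inc),
                cfg,
                stage=stage,
                incidence_event=incidence_event,
            )
            return table, inc, fit

        e0_table = e0_target
        rate = 0.002
        for _ in range(4):

            def lr_gap(log_rate: float) -> float:
                _, _, fit = build(e0_table, float(np.exp(log_rate)))
                return fit.lifetime_risk(65) - lr_target

            log_rate = brentq(lr_gap, np.log(1e-4), np.log(0.5), xtol=2e-4)
            rate = float(np.exp(log_rate))
            table, inc, fit = build(e0_table, rate)
            cohort_e0 = float(fit.run_cohort().person_years.sum())
            gap = e0_target - cohort_e0
            if abs(gap) < 0.02:
                break
            e0_table += gap
        return cls(table, inc, cfg, stage, incidence_event)

    def fit(
        self,
        method: str = "analytic",
        seed: int | None = 0,
        rtol: float = 1e-6,
        max_iter: int = 200,
        ga_options: GAOptions | None = None,
    ) -> CalibratedModel:
        """Calibrate the model; returns the fitted results object."""
        targets = CalibrationTargets.from_config(
            self.risk_config, self.life_table, self.incidence
        )
        return calibrate(
            targets,
            self.risk_config,
            stage=self.stage,
            method=method,
            seed=seed,
            rtol=rtol,
            max_iter=max_iter,
            ga_options=ga_options,
            incidence_event=self.incidence_event,
        )


@lru_cache(maxsize=8)
def fit_reference_model(sex: str, matched: bool = True) -> CalibratedModel:
    """Cached calibrated model on synthetic inputs (reference-matched by
    default); convenience for scripts and tests."""
    if matched:
        model = DementiaModel.from_reference_matched(sex)
    else:
        model = DementiaModel.from_synthetic(sex)
    return model.fit()
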