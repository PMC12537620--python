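"""Model calibration: fit birth group fractions and baseline hazards.

Three target families are matched, sex-stratified throughout:

* survivor prevalence of smoking among those alive at 65-100, of
  hypertension at 40-59, and of the joint exposure at 65-100 -- matched by
  adjusting the *birth* assignment fractions of the four risk groups
  (because exposed groups carry excess mortality, more carriers must be
  seeded at birth than are observed among survivors);
* the population incidence schedule -- matched by the baseline onset hazard
  of the unexposed group;
* the life table -- matched by the baseline other-cause mortality hazard.

The hazard targets are closed in a single forward sweep of the
expected-value cohort model (see :mod:`demsim.cohort`); only the birth
fractions require iteration.  Two optimizers are provided: a fixed-point
``analytic`` method and a seeded real-coded genetic algorithm (``ga``) with
tournament selection, blend crossover and Gaussian mutation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .cohort import (
    BaselineRates,
    CohortResult,
    StageParams,
    lifetime_risk,
    run_cohort,
    survivor_prevalence,
)
from .inputs import IncidenceSchedule, LifeTable
from .risk import GroupFractions, RiskGroupConfig, ScenarioSpec, allocate_groups

_SMOKING_GROUPS = (1, 3)
_HTN_GROUPS = (2, 3)
_BOTH_GROUPS = (3,)


class CalibrationError(RuntimeError):
    """Calibration failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class GAOptions:
    """Genetic-algorithm settings (conventional defaults, all overridable)."""

    population_size: int = 100
    n_generations: int = 200
    tournament_size: int = 3
    crossover_prob: float = 0.7
    blend_alpha: float = 0.5
    mutation_prob: float = 0.2
    mutation_sigma: float = 0.10
    sigma_decay: float = 0.97
    objective_tol: float = 1e-12


@dataclass
class CalibrationTargets:
    """Observed quantities the fitted model must reproduce."""

    prev_smoking: float  # % among alive, smoking window
    prev_hypertension: float  # % among alive, hypertension window
    prev_both: float  # % among alive, smoking window
    life_table: LifeTable
    incidence: IncidenceSchedule

    @classmethod
    def from_config(
        cls,
        risk_config: RiskGroupConfig,
        life_table: LifeTable,
        incidence: IncidenceSchedule,
    ) -> "CalibrationTargets":
        return cls(
            prev_smoking=risk_config.prev_smoking,
            prev_hypertension=risk_config.prev_hypertension,
            prev_both=risk_config.prev_both,
            life_table=life_table,
            incidence=incidence,
        )

    def as_vector(self) -> np.ndarray:
        return np.array([self.prev_smoking, self.prev_hypertension, self.prev_both])


@dataclass
class CalibratedModel:
    """Fitted model: birth fractions, baseline hazards, and diagnostics.

    The results object of :meth:`demsim.model.DementiaModel.fit`.  Holds
    everything needed to evaluate scenarios: the calibrated birth group
    fractions, the baseline hazard schedules of the unexposed group, the
    stage parameters, and the inputs the fit was conditioned on.
    """

    sex: str
    fractions: GroupFractions
    rates: BaselineRates
    risk_config: RiskGroupConfig
    life_table: LifeTable
    incidence: IncidenceSchedule
    method: str
    seed: int | None
    diagnostics: dict = field(default_factory=dict)

    # -- evaluation ------------------------------------------------------
    def run_cohort(self, scenario: ScenarioSpec | None = None) -> CohortResult:
        """Expected-value cohort trajectory under a scenario (frozen rates)."""
        result, _ = run_cohort(
            self.fractions,
            self.life_table,
            self.incidence,
            self.risk_config,
            rates=self.rates,
            scenario=scenario,
        )
        return result

    def simulate(self, scenario=None, n: int = 200_000, seed: int = 0, **kw):
        """Stochastic microsimulation under a scenario (see demsim.simulate)."""
        from .simulate import SimulationConfig, simulate

        sim = SimulationConfig(n_individuals=n, master_seed=seed, sex=self.sex, **kw)
        return simulate(self, scenario, sim)

    def lifetime_risk(
        self, from_age: int = 65, scenario: ScenarioSpec | None = None
    ) -> float:
        return lifetime_risk(self.run_cohort(scenario), from_age)

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        d = self.diagnostics
        f = self.fractions
        lines = [
            "Calibrated dementia risk-factor model",
            "=" * 53,
            f"sex: {self.sex}    method: {self.method}    seed: {self.seed}",
            f"objective: {d.get('objective', float('nan')):.3e}    "
            f"iterations: {d.get('n_iter', '-')}",
            "",
            "Birth group fractions (calibrated parameters)",
            f"  none          {f.f_none:10.6f}",
            f"  smoking       {f.f_smoking:10.6f}",
            f"  hypertension  {f.f_hypertension:10.6f}",
            f"  both          {f.f_both:10.6f}",
            "",
            "Survivor-prevalence targets (% | fitted %)",
        ]
        for name, tgt, fit in zip(
            ("smoking 65-100", "hypertension 40-59", "both 65-100"),
            d.get("targets", [np.nan] * 3),
            d.get("fitted", [np.nan] * 3),
        ):
            lines.append(f"  {name:<20} {tgt:8.3f} | {fit:8.3f}")
        lines += [
            "",
            f"baseline onset hazard at 65: {self.rates.h_none[65]:.3e} /yr",
            f"baseline other-cause hazard at 65: {self.rates.m_none[65]:.3e} /yr",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "sex": self.sex,
            "method": self.method,
            "seed": self.seed,
            "fractions": list(self.fractions.as_array()),
            "m_none": list(self.rates.m_none),
            "h_none": list(self.rates.h_none),
            "stage": asdict(self.rates.stage),
            "incidence_event": self.rates.incidence_event,
            "risk_config": _config_to_dict(self.risk_config),
            "life_table": {
                "sex": self.life_table.sex,
                "qx": list(self.life_table.qx),
                "max_age": self.life_table.max_age,
            },
            "incidence": {
                "sex": self.incidence.sex,
                "h_pop": list(self.incidence.h_pop),
                "trend_decline_per_decade": self.incidence.trend_decline_per_decade,
                "reference_year": self.incidence.reference_year,
                "birth_year": self.incidence.birth_year,
                "onset_floor_age": self.incidence.onset_floor_age,
                "max_age": self.incidence.max_age,
            },
            "diagnostics": _jsonable(self.diagnostics),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibratedModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            sex=p["sex"],
            fractions=GroupFractions.from_array(p["fractions"]),
            rates=BaselineRates(
                np.array(p["m_none"]),
                np.array(p["h_none"]),
                StageParams(**p["stage"]),
                p["incidence_event"],
            ),
            risk_config=RiskGroupConfig(**_tuplify(p["risk_config"])),
            life_table=LifeTable(**p["life_table"]),
            incidence=IncidenceSchedule(
                sex=p["incidence"]["sex"],
                h_pop=np.array(p["incidence"]["h_pop"]),
                trend_decline_per_decade=p["incidence"]["trend_decline_per_decade"],
                reference_year=p["incidence"]["reference_year"],
                birth_year=p["incidence"]["birth_year"],
                onset_floor_age=p["incidence"]["onset_floor_age"],
                max_age=p["incidence"]["max_age"],
            ),
            method=p["method"],
            seed=p["seed"],
            diagnostics=p["diagnostics"],
        )


def _config_to_dict(cfg: RiskGroupConfig) -> dict:
    d = asdict(cfg)
    return d


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _fitted_prevalences(result: CohortResult, cfg: RiskGroupConfig) -> np.ndarray:
    return np.array(
        [
            survivor_prevalence(result, cfg.smoking_target_window, _SMOKING_GROUPS),
            survivor_prevalence(result, cfg.hypertension_target_window, _HTN_GROUPS),
            survivor_prevalence(result, cfg.smoking_target_window, _BOTH_GROUPS),
        ]
    )


def _fractions_from_marginals(m_s: float, m_h: float, b: float) -> GroupFractions:
    f_s = m_s - b
    f_h = m_h - b
    f_none = 1.0 - f_s - f_h - b
    return GroupFractions(f_none, f_s, f_h, b)


def _relative_residuals(fitted: np.ndarray, targets: np.ndarray) -> np.ndarray:
    denom = np.where(targets > 0, targets, 1.0)
    return (fitted - targets) / denom


def calibrate(
    targets: CalibrationTargets,
    risk_config: RiskGroupConfig,
    stage: StageParams | None = None,
    method: str = "analytic",
    seed: int | None = 0,
    rtol: float = 1e-6,
    max_iter: int = 200,
    ga_options: GAOptions | None = None,
    incidence_event: str = "dementia_entry",
) -> CalibratedModel:
    """Fit birth fractions and baseline hazards to the calibration targets.

    ``method='analytic'`` runs a fixed-point loop (sweep, compare survivor
    prevalences to targets, rescale marginals) until every prevalence target
    is matched within relative tolerance ``rtol``; ``method='ga'`` minimizes
    the sum of squared relative residuals with a seeded genetic algorithm.
    Both close the hazard targets exactly inside each cohort sweep.
    """
    stage = stage if stage is not None else StageParams()
    tvec = targets.as_vector() / 100.0  # work on the fraction scale

    def sweep(fracs: GroupFractions):
        result, rates = run_cohort(
            fracs,
            targets.life_table,
            targets.incidence,
            risk_config,
            stage=stage,
            incidence_event=incidence_event,
        )
        return result, rates, _fitted_prevalences(result, risk_config) / 100.0

    naive = allocate_groups(
        replace(
            risk_config,
            prev_smoking=targets.prev_smoking,
            prev_hypertension=targets.prev_hypertension,
            prev_both=targets.prev_both,
        )
    )

    if method == "analytic":
        fracs = naive
        history = []
        for it in range(max_iter):
            result, rates, fitted = sweep(fracs)
            res = _relative_residuals(fitted, tvec)
            history.append(float(np.abs(res).max()))
            if np.abs(res).max() < rtol:
                break
            m_s = fracs.f_smoking + fracs.f_both
            m_h = fracs.f_hypertension + fracs.f_both
            scale = np.where(fitted > 0, tvec / np.where(fitted > 0, fitted, 1.0), 1.0)
            m_s *= scale[0]
            m_h *= scale[1]
            b = fracs.f_both * scale[2]
            b = min(b, m_s, m_h)
            fracs = _fractions_from_marginals(m_s, m_h, b)
        else:
            raise CalibrationError(
                f"analytic calibration did not converge in {max_iter} iterations",
                {"residual_history": history, "fractions": list(fracs.as_array())},
            )
        objective = float(np.sum(res**2))
        n_iter = it + 1
    elif method == "ga":
        opts = ga_options or GAOptions()
        m_s0 = naive.f_smoking + naive.f_both
        m_h0 = naive.f_hypertension + naive.f_both
        b0 = naive.f_both
        lo = np.array([0.2 * m_s0, 0.2 * m_h0, 0.2 * b0])
        hi = np.array(
            [min(3 * m_s0, 0.9), min(3 * m_h0, 0.9), min(3 * max(b0, 1e-6), 0.9)]
        )

        def objective_fn(x: np.ndarray) -> float:
            m_s, m_h, b = x
            if b > min(m_s, m_h) or m_s + m_h - b > 1.0:
                return 1e6 + float(abs(b - min(m_s, m_h)))
            try:
                fr = _fractions_from_marginals(m_s, m_h, b)
            except Exception:
                return 1e6
            _, _, fitted = sweep(fr)
            return float(np.sum(_relative_residuals(fitted, tvec) ** 2))

        best_x, best_f, gens = _ga_minimize(
            objective_fn,
            lo,
            hi,
            seed=seed if seed is not None else 0,
            opts=opts,
            initial=[np.array([m_s0, m_h0, b0])],
        )
        if best_f > 1e-4:
            raise CalibrationError(
                f"GA calibration objective {best_f:.3e} above 1e-4",
                {"best": list(best_x), "objective": best_f},
            )
        fracs = _fractions_from_marginals(*best_x)
        result, rates, fitted = sweep(fracs)
        res = _relative_residuals(fitted, tvec)
        objective = best_f
        n_iter = gens
    else:
        raise ValueError(f"unknown calibration method {method!r}")

    return CalibratedModel(
        sex=targets.life_table.sex,
        fractions=fracs,
        rates=rates,
        risk_config=risk_config,
        life_table=targets.life_table,
        incidence=targets.incidence,
        method=method,
        seed=seed,
        diagnostics={
            "objective": objective,
            "n_iter": n_iter,
            "targets": list(tvec * 100.0),
            "fitted": list(fitted * 100.0),
            "residuals": list(res),
        },
    )


def _ga_minimize(fun, lo, hi, seed, opts: GAOptions, initial=None):
    """Minimal seeded real-coded GA: tournament, blend crossover, Gaussian
    mutation, one-elite survival, early stop at ``objective_tol``."""
    rng = np.random.default_rng(seed)
    d = len(lo)
    pop = lo + rng.random((opts.population_size, d)) * (hi - lo)
    for i, x in enumerate(initial or []):
        pop[i] = np.clip(x, lo, hi)
    fit = np.array([fun(x) for x in pop])
    best_i = int(np.argmin(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    sigma = opts.mutation_sigma * (hi - lo)
    gens = 0
    for gen in range(opts.n_generations):
        gens = gen + 1
        # tournament selection
        idx = rng.integers(0, opts.population_size, (opts.population_size, opts.tournament_size))
        winners = idx[np.arange(opts.population_size), np.argmin(fit[idx], axis=1)]
        parents = pop[winners]
        children = parents.copy()
        # blend (BLX-alpha) crossover on consecutive pairs
        for i in range(0, opts.population_size - 1, 2):
            if rng.random() < opts.crossover_prob:
                a, b = parents[i], parents[i + 1]
                lo_g = np.minimum(a, b) - opts.blend_alpha * np.abs(a - b)
                hi_g = np.maximum(a, b) + opts.blend_alpha * np.abs(a - b)
                children[i] = lo_g + rng.random(d) * (hi_g - lo_g)
                children[i + 1] = lo_g + rng.random(d) * (hi_g - lo_g)
        # Gaussian mutation
        mask = rng.random((opts.population_size, d)) < opts.mutation_prob
        children = children + mask * rng.normal(0.0, 1.0, (opts.population_size, d)) * sigma
        children = np.clip(children, lo, hi)
        children[0] = best_x  # elitism
        pop = children
        fit = np.array([fun(x) for x in pop])
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_x, best_f = pop[i].copy(), float(fit[i])
        sigma = sigma * opts.sigma_decay
        if best_f <= opts.objective_tol:
            break
    return best_x, best_f, gens


_SENSITIVITY_PARAMS = (
    ("prev_smoking", "ci_prev_smoking"),
    ("prev_hypertension", "ci_prev_hypertension"),
    ("rr_dementia_smoking", "ci_rr_dementia_smoking"),
    ("rr_dementia_hypertension", "ci_rr_dementia_hypertension"),
    ("rr_mortality_smoking", "ci_rr_mortality_smoking"),
    ("rr_mortality_hypertension", "ci_rr_mortality_hypertension"),
)


def build_sensitivity_models(
    risk_config: RiskGroupConfig,
    life_table: LifeTable,
    incidence: IncidenceSchedule,
    stage: StageParams | None = None,
    method: str = "analytic",
    seed: int | None = 0,
    **calibrate_kw,
) -> dict[tuple[str, str], CalibratedModel]:
    """Re-calibrate once per 95%-CI bound of each uncertain parameter.

    Six parameters (two prevalences, two dementia RRs, two mortality RRs) x
    two bounds = twelve models, each calibrated with all other parameters at
    their point estimates.
    """
    models: dict[tuple[str, str], CalibratedModel] = {}
    for param, ci_attr in _SENSITIVITY_PARAMS:
        ci = getattr(risk_config, ci_attr)
        if ci is None:
            raise ValueError(f"missing confidence interval for {param}")
        for bound, value in zip(("lower", "upper"), ci):
            cfg = risk_config.with_param(param, float(value))
            targets = CalibrationTargets.from_config(cfg, life_table, incidence)
            models[(param, bound)] = calibrate(
                targets, cfg, stage=stage, method=method, seed=seed, **calibrate_kw
            )
    return models
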