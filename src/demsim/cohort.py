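"""Deterministic expected-value cohort model (the analytic oracle).

The same natural history as the stochastic microsimulation -- unidirectional
transitions between cognitively normal, MCI, mild, moderate and severe
dementia, with death from dementia or from other causes possible in any
stage -- computed as a forward recursion of expected occupancies over
age x risk group x state.  It serves three purposes:

* calibration: during the forward sweep the baseline other-cause mortality
  hazard ``m_none(a)`` and baseline onset hazard ``h_none(a)`` of the
  unexposed group are solved per age so that the population-average death
  and onset probabilities reproduce the life table and the incidence
  schedule exactly (composition drift from differential survival of the
  high-risk groups is accounted for automatically, because the composition
  entering each age is known before that age is solved);
* scenario evaluation without Monte-Carlo noise;
* an independent equivalence oracle for the microsimulation.

Within each annual cycle events are applied in a fixed sequence: other-cause
death, then dementia onset or a single stage progression, then stage-specific
dementia death; each hazard h is converted to a probability 1 - exp(-h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inputs import IncidenceSchedule, LifeTable
from .risk import (
    GROUPS,
    GroupFractions,
    RiskGroupConfig,
    ScenarioSpec,
    apply_scenario,
    rr_matrix,
)

# state indices
NORMAL, MCI, MILD, MODERATE, SEVERE, DEAD_DEMENTIA, DEAD_OTHER = range(7)
STATES = ("normal", "mci", "mild", "moderate", "severe", "dead_dementia", "dead_other")
ALIVE_STATES = slice(0, 5)
DEMENTIA_STATES = (MILD, MODERATE, SEVERE)
N_GROUPS, N_STATES = 4, 7

_MASS_EPS = 1e-14


class InvariantError(RuntimeError):
    """An internal conservation or positivity invariant was violated."""


@dataclass(frozen=True)
class StageParams:
    """Dementia stage dwell-time and mortality parameters.

    Annual transition probabilities between consecutive stages and
    stage-specific excess mortality hazards (1/year).  These are
    natural-history defaults, configurable because the source analysis does
    not print them.  ``collapsed=True`` replaces the staged pathway with a
    single dementia state entered directly at onset (used for analytic
    closed-form tests).
    """

    p_mci_to_mild: float = 0.25
    p_mild_to_moderate: float = 0.30
    p_moderate_to_severe: float = 0.35
    excess_mortality_mci: float = 0.0
    excess_mortality_mild: float = 0.05
    excess_mortality_moderate: float = 0.10
    excess_mortality_severe: float = 0.20
    collapsed: bool = False

    def __post_init__(self) -> None:
        for name in (
            "p_mci_to_mild",
            "p_mild_to_moderate",
            "p_moderate_to_severe",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for name in (
            "excess_mortality_mci",
            "excess_mortality_mild",
            "excess_mortality_moderate",
            "excess_mortality_severe",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    def excess_hazards(self) -> np.ndarray:
        """Per alive-state dementia-death hazards (normal has none)."""
        return np.array(
            [
                0.0,
                self.excess_mortality_mci,
                self.excess_mortality_mild,
                self.excess_mortality_moderate,
                self.excess_mortality_severe,
            ]
        )


@dataclass
class BaselineRates:
    """Calibrated baseline hazards of the unexposed ('none') group.

    ``m_none[a]`` is the other-cause mortality hazard and ``h_none[a]`` the
    dementia-onset hazard at age ``a``; exposed groups multiply these by
    their age-dependent relative risks.  ``m_none`` is ``inf`` at the
    closing age of the life table.
    """

    m_none: np.ndarray
    h_none: np.ndarray
    stage: StageParams = field(default_factory=StageParams)
    incidence_event: str = "dementia_entry"

    def __post_init__(self) -> None:
        self.m_none = np.asarray(self.m_none, dtype=float)
        self.h_none = np.asarray(self.h_none, dtype=float)
        if np.any(self.h_none < 0) or np.any(self.m_none < 0):
            raise ValueError("negative baseline hazard")
        if self.incidence_event not in ("mci_entry", "dementia_entry"):
            raise ValueError(f"unknown incidence_event {self.incidence_event!r}")


@dataclass
class CohortResult:
    """Person-years and event counts by age x group x state for one run.

    For the deterministic oracle the cohort has total mass ``n = 1`` and all
    quantities are expected fractions; for the microsimulation they are
    counts of individuals.  ``occupancy[a]`` is the start-of-age-``a``
    distribution over groups and states (all seven, so it sums to ``n``).
    """

    sex: str
    scenario: str
    n: float
    max_age: int
    incidence_event: str
    occupancy: np.ndarray  # (A+1, G, 7)
    person_years: np.ndarray  # (A+1, G, 5) alive states only
    onsets_mci: np.ndarray  # (A+1, G)
    onsets_dementia: np.ndarray  # (A+1, G)
    deaths_other: np.ndarray  # (A+1, G)
    deaths_dementia: np.ndarray  # (A+1, G)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.max_age + 1)

    def onsets(self, event: str | None = None) -> np.ndarray:
        """(A+1, G) counted incidence events (configured event by default)."""
        event = event or self.incidence_event
        if event == "mci_entry":
            return self.onsets_mci
        if event == "dementia_entry":
            return self.onsets_dementia
        raise ValueError(f"unknown incidence event {event!r}")

    def py_alive_by_age(self) -> np.ndarray:
        return self.person_years.sum(axis=(1, 2))

    def py_dementia_by_age(self) -> np.ndarray:
        return self.person_years[:, :, list(DEMENTIA_STATES)].sum(axis=(1, 2))

    def py_dementia_free_by_age(self) -> np.ndarray:
        return self.person_years[:, :, (NORMAL, MCI)].sum(axis=(1, 2))

    def py_at_risk_by_age(self, event: str | None = None) -> np.ndarray:
        """Person-years at risk of the counted incidence event."""
        event = event or self.incidence_event
        if event == "mci_entry":
            return self.person_years[:, :, NORMAL].sum(axis=1)
        return self.py_dementia_free_by_age()

    def total_deaths(self) -> float:
        return float(self.deaths_other.sum() + self.deaths_dementia.sum())

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "occupancy": self.occupancy,
            "person_years": self.person_years,
            "onsets_mci": self.onsets_mci,
            "onsets_dementia": self.onsets_dementia,
            "deaths_other": self.deaths_other,
            "deaths_dementia": self.deaths_dementia,
        }

    def equals(self, other: "CohortResult") -> bool:
        """Bit-level equality of all aggregates (CRN identity checks)."""
        return all(
            np.array_equal(a, other.arrays()[k]) for k, a in self.arrays().items()
        )

    def add(self, other: "CohortResult") -> "CohortResult":
        """Pool two results of the same shape (chunked microsimulation)."""
        if other.max_age != self.max_age or other.sex != self.sex:
            raise ValueError("cannot pool results with different shapes")
        return CohortResult(
            sex=self.sex,
            scenario=self.scenario,
            n=self.n + other.n,
            max_age=self.max_age,
            incidence_event=self.incidence_event,
            **{k: a + other.arrays()[k] for k, a in self.arrays().items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(age, group, state) table with person-years and events.

        Events are attributed to the first alive state row of each
        (age, group) for compactness of the long format.
        """
        recs = []
        for a in range(self.max_age + 1):
            for g, gname in enumerate(GROUPS):
                for s in range(5):
                    recs.append(
                        {
                            "scenario": self.scenario,
                            "sex": self.sex,
                            "age": a,
                            "group": gname,
                            "state": STATES[s],
                            "person_years": self.person_years[a, g, s],
                            "onsets": self.onsets(None)[a, g] if s == 0 else 0.0,
                            "deaths_other": self.deaths_other[a, g] if s == 0 else 0.0,
                            "deaths_dementia": (
                                self.deaths_dementia[a, g] if s == 0 else 0.0
                            ),
                        }
                    )
        return pd.DataFrame.from_records(recs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def solve_annual_hazard(weights: np.ndarray, rrs: np.ndarray, q_target: float) -> float:
    """Solve ``sum_g w_g (1 - exp(-rr_g * m)) = q_target`` for the hazard m.

    ``weights`` is the composition of the population at risk (sums to 1) and
    ``rrs`` the group relative risks.  Newton iteration from the
    hazard-linear first guess ``-ln(1-q) / sum(w rr)``; exact to ~1e-15.
    Returns ``inf`` when the target probability is 1 (closing age).
    """
    if q_target <= 0.0:
        return 0.0
    if q_target >= 1.0 - 1e-12:
        return np.inf
    wr = float(weights @ rrs)
    if wr <= 0:
        raise InvariantError("weighted relative-risk sum is not positive")
    m = -np.log1p(-q_target) / wr
    for _ in range(60):
        em = np.exp(-rrs * m)
        f = float(weights @ (1.0 - em)) - q_target
        fp = float(weights @ (rrs * em))
        step = f / fp
        m -= step
        if abs(step) < 1e-16 + 1e-13 * m:
            break
    return float(max(m, 0.0))


def _prepare(fractions, scenario):
    if scenario is not None:
        fractions = apply_scenario(fractions, scenario)
    return fractions


def run_cohort(
    fractions: GroupFractions,
    life_table: LifeTable,
    incidence: IncidenceSchedule,
    risk_config: RiskGroupConfig,
    stage: StageParams | None = None,
    rates: BaselineRates | None = None,
    scenario: ScenarioSpec | None = None,
    incidence_event: str = "dementia_entry",
    label: str | None = None,
) -> tuple[CohortResult, BaselineRates]:
    """Forward expected-value recursion over one birth cohort.

    With ``rates=None`` the baseline hazards are *solved* during the sweep
    (calibration mode): at each age the other-cause hazard of the unexposed
    group is chosen so the realized population death probability equals the
    life-table ``qx``, and the onset hazard so the realized onset
    probability among the at-risk (cognitively normal) survivors equals the
    incidence schedule.  With frozen ``rates`` (scenario mode) the stored
    hazards are applied as-is.

    Returns the cohort trajectory and the baseline rates used.
    """
    stage = stage if stage is not None else StageParams()
    if rates is not None:
        stage = rates.stage
        incidence_event = rates.incidence_event
    fractions = _prepare(fractions, scenario)
    A = life_table.max_age
    if incidence.max_age != A:
        raise ValueError("life table and incidence schedule cover different ages")

    rr_mort = rr_matrix(risk_config, "mortality", A)
    rr_dem = rr_matrix(risk_config, "dementia", A)
    excess = stage.excess_hazards()
    p_dd = -np.expm1(-excess)  # per alive state

    occ = np.zeros((N_GROUPS, N_STATES))
    occ[:, NORMAL] = fractions.as_array()

    occupancy = np.zeros((A + 1, N_GROUPS, N_STATES))
    py = np.zeros((A + 1, N_GROUPS, 5))
    onsets_mci = np.zeros((A + 1, N_GROUPS))
    onsets_dem = np.zeros((A + 1, N_GROUPS))
    deaths_other = np.zeros((A + 1, N_GROUPS))
    deaths_dem = np.zeros((A + 1, N_GROUPS))
    m_out = np.zeros(A + 1)
    h_out = np.zeros(A + 1)

    for a in range(A + 1):
        occupancy[a] = occ
        start_alive = occ[:, ALIVE_STATES].copy()
        alive_g = start_alive.sum(axis=1)
        total_alive = alive_g.sum()
        if total_alive <= _MASS_EPS:
            m_out[a] = rates.m_none[a] if rates is not None else 0.0
            h_out[a] = rates.h_none[a] if rates is not None else 0.0
            continue

        # --- step 1: other-cause death ---------------------------------
        qx = life_table.qx[a]
        if rates is None:
            m = solve_annual_hazard(alive_g / total_alive, rr_mort[a], qx)
        else:
            m = rates.m_none[a]
        if np.isinf(m):
            p_death = np.ones(N_GROUPS)
        else:
            p_death = -np.expm1(-rr_mort[a] * m)
        flow = start_alive * p_death[:, None]
        occ[:, ALIVE_STATES] -= flow
        occ[:, DEAD_OTHER] += flow.sum(axis=1)
        deaths_other[a] = flow.sum(axis=1)

        # --- step 2: onset / one stage progression ----------------------
        at_risk = occ[:, NORMAL].copy()
        tr = at_risk.sum()
        target_h = incidence.hazard_at(a)
        if rates is None:
            if target_h > 0 and tr > _MASS_EPS:
                h = solve_annual_hazard(
                    at_risk / tr, rr_dem[a], -np.expm1(-target_h)
                )
            else:
                h = 0.0
        else:
            h = rates.h_none[a]
        p_onset = -np.expm1(-rr_dem[a] * h)
        onset_flow = occ[:, NORMAL] * p_onset
        onsets_mci[a] = onset_flow
        new = occ[:, ALIVE_STATES].copy()
        if stage.collapsed:
            new[:, NORMAL] -= onset_flow
            new[:, MILD] += onset_flow
            onsets_dem[a] = onset_flow
        else:
            f1 = occ[:, MCI] * stage.p_mci_to_mild
            f2 = occ[:, MILD] * stage.p_mild_to_moderate
            f3 = occ[:, MODERATE] * stage.p_moderate_to_severe
            new[:, NORMAL] -= onset_flow
            new[:, MCI] += onset_flow - f1
            new[:, MILD] += f1 - f2
            new[:, MODERATE] += f2 - f3
            new[:, SEVERE] += f3
            onsets_dem[a] = f1
        occ[:, ALIVE_STATES] = new

        # --- step 3: dementia death -------------------------------------
        flow = occ[:, ALIVE_STATES] * p_dd[None, :]
        occ[:, ALIVE_STATES] -= flow
        occ[:, DEAD_DEMENTIA] += flow.sum(axis=1)
        deaths_dem[a] = flow.sum(axis=1)

        py[a] = 0.5 * (start_alive + occ[:, ALIVE_STATES])
        m_out[a] = m
        h_out[a] = h

        if np.any(occ < -1e-12) or abs(occ.sum() - 1.0) > 1e-9:
            raise InvariantError(f"occupancy left the simplex at age {a}")

    used = (
        rates
        if rates is not None
        else BaselineRates(m_out, h_out, stage, incidence_event)
    )
    result = CohortResult(
        sex=life_table.sex,
        scenario=label or (scenario.label if scenario is not None else "reference"),
        n=1.0,
        max_age=A,
        incidence_event=incidence_event,
        occupancy=occupancy,
        person_years=py,
        onsets_mci=onsets_mci,
        onsets_dementia=onsets_dem,
        deaths_other=deaths_other,
        deaths_dementia=deaths_dem,
    )
    return result, used


def solve_baseline_mortality(
    life_table: LifeTable,
    fractions: GroupFractions,
    risk_config: RiskGroupConfig,
    incidence: IncidenceSchedule,
    stage: StageParams | None = None,
) -> np.ndarray:
    """Baseline other-cause mortality hazard ``m_none(a)`` of the unexposed.

    Solved age by age with the alive composition drifting as higher-risk
    groups die faster, so the population-average death probability
    reproduces the life table exactly.
    """
    _, rates = run_cohort(fractions, life_table, incidence, risk_config, stage)
    return rates.m_none


def solve_baseline_incidence(
    incidence: IncidenceSchedule,
    fractions: GroupFractions,
    life_table: LifeTable,
    risk_config: RiskGroupConfig,
    stage: StageParams | None = None,
) -> np.ndarray:
    """Baseline onset hazard ``h_none(a)`` reproducing population incidence."""
    _, rates = run_cohort(fractions, life_table, incidence, risk_config, stage)
    return rates.h_none


def lifetime_risk(result: CohortResult, from_age: int = 65) -> float:
    """Probability (%) of the incidence event after ``from_age``.

    Cumulative counted onsets at ages >= ``from_age`` divided by the
    dementia-free alive mass at that age (cognitively normal, plus MCI when
    onsets are counted at dementia entry).
    """
    if from_age > result.max_age:
        raise ValueError("from_age beyond the simulated age range")
    if result.incidence_event == "mci_entry":
        denom = result.occupancy[from_age, :, NORMAL].sum()
    else:
        denom = result.occupancy[from_age, :, (NORMAL, MCI)].sum()
    if denom <= 0:
        raise ZeroDivisionError("no dementia-free individuals alive at from_age")
    num = result.onsets()[from_age:].sum()
    return float(100.0 * num / denom)


def survivor_prevalence(
    result: CohortResult, window: tuple[int, int], groups: tuple[int, ...]
) -> float:
    """Person-year-weighted exposure prevalence (%) in an age window."""
    lo, hi = window
    py_g = result.person_years[lo : hi + 1].sum(axis=2)  # (ages, G)
    tot = py_g.sum()
    if tot <= 0:
        raise ZeroDivisionError("no person-years in the prevalence window")
    return float(100.0 * py_g[:, list(groups)].sum() / tot)


def mortality_closure_error(result: CohortResult, life_table: LifeTable) -> float:
    """Max |realized - target| other-cause death probability over ages.

    Meaningful for expected-value results; the realized probability is
    deaths among those alive at the start of the age divided by that alive
    mass.
    """
    err = 0.0
    for a in range(result.max_age + 1):
        alive = result.occupancy[a, :, ALIVE_STATES].sum()
        if alive < 1e-9:
            continue
        realized = result.deaths_other[a].sum() / alive
        err = max(err, abs(realized - life_table.qx[a]))
    return err


def incidence_closure_error(
    result: CohortResult, incidence: IncidenceSchedule
) -> float:
    """Max |realized - target| onset probability among the at-risk.

    The at-risk pool is the cognitively normal population surviving the
    within-year other-cause mortality step, recovered from the recorded
    occupancies and death counts.
    """
    err = 0.0
    for a in range(result.max_age + 1):
        alive_g = result.occupancy[a, :, ALIVE_STATES].sum(axis=1)
        if alive_g.sum() < 1e-9:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            p_death = np.where(alive_g > 0, result.deaths_other[a] / alive_g, 0.0)
        at_risk = (result.occupancy[a, :, NORMAL] * (1.0 - p_death)).sum()
        if at_risk < 1e-9:
            continue
        realized = result.onsets_mci[a].sum() / at_risk
        target = -np.expm1(-incidence.hazard_at(a))
        err = max(err, abs(realized - target))
    return err
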