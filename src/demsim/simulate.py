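"""Stochastic individual-level microsimulation of one birth cohort.

Each simulated individual draws a fixed stream of uniforms from a
counter-based generator (Philox) keyed by the master seed and their chunk,
*independently of the scenario*: a latent exposure pair sampled from the
calibrated reference birth fractions, two removal uniforms, and one triple
of uniforms per year of age (other-cause death, onset/stage progression,
dementia death -- drawn every year whether or not the individual is alive,
so the stream position never depends on simulated history).

A scenario maps the latent exposure deterministically: a reduction fraction
``r`` removes the factor from individuals whose removal uniform falls below
``r``.  Scenarios therefore share common random numbers (CRN): the null
scenario is bit-identical to the reference, and scenario differences are
free of between-individual sampling noise.  Memory is O(ages x states x
groups) through chunked streaming, so the cohort size is limited by time,
not memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import CalibratedModel
from .cohort import (
    DEAD_DEMENTIA,
    DEAD_OTHER,
    MCI,
    MILD,
    MODERATE,
    N_GROUPS,
    N_STATES,
    NORMAL,
    SEVERE,
    CohortResult,
)
from .risk import GROUPS, REFERENCE_SCENARIO, ScenarioSpec, rr_matrix

_SEX_CODE = {"female": 0, "male": 1}


@dataclass
class SimulationConfig:
    """Size, seeding and scope of a microsimulation run."""

    n_individuals: int
    master_seed: int
    sex: str
    birth_year: int = 1980
    max_age: int = 100
    chunk_size: int = 100_000
    keep_chunks: bool = False  # retain per-chunk results (variance estimation)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")

    def chunks(self) -> list[tuple[int, int]]:
        """(chunk index, size) pairs; boundaries depend only on n and size."""
        out = []
        remaining = self.n_individuals
        ci = 0
        while remaining > 0:
            m = min(self.chunk_size, remaining)
            out.append((ci, m))
            remaining -= m
            ci += 1
        return out


def _chunk_rng(config: SimulationConfig, chunk_index: int) -> np.random.Generator:
    # 128-bit counter-based key: (seed, sex, chunk) uniquely and
    # scenario-independently identify each individual's stream
    key = (
        (int(config.master_seed) & 0xFFFFFFFFFFFFFFFF) << 33
        | _SEX_CODE[config.sex] << 32
        | int(chunk_index)
    )
    return np.random.Generator(np.random.Philox(key=key))


def _probability_tables(model: CalibratedModel, max_age: int):
    """Annual event probabilities by (age, group) and by stage."""
    rr_mort = rr_matrix(model.risk_config, "mortality", max_age)
    rr_dem = rr_matrix(model.risk_config, "dementia", max_age)
    m = model.rates.m_none[:, None]
    h = model.rates.h_none[:, None]
    with np.errstate(invalid="ignore"):
        q_death = np.where(np.isinf(m), 1.0, -np.expm1(-rr_mort * np.where(np.isinf(m), 0.0, m)))
    q_onset = -np.expm1(-rr_dem * h)
    stage = model.rates.stage
    if stage.collapsed:
        p_prog = np.zeros(5)
    else:
        p_prog = np.array(
            [0.0, stage.p_mci_to_mild, stage.p_mild_to_moderate, stage.p_moderate_to_severe, 0.0]
        )
    p_dd = -np.expm1(-stage.excess_hazards())
    return q_death, q_onset, p_prog, p_dd


def _empty_result(model: CalibratedModel, label: str, max_age: int) -> CohortResult:
    shape = (max_age + 1, N_GROUPS)
    return CohortResult(
        sex=model.sex,
        scenario=label,
        n=0.0,
        max_age=max_age,
        incidence_event=model.rates.incidence_event,
        occupancy=np.zeros((max_age + 1, N_GROUPS, N_STATES)),
        person_years=np.zeros((max_age + 1, N_GROUPS, 5)),
        onsets_mci=np.zeros(shape),
        onsets_dementia=np.zeros(shape),
        deaths_other=np.zeros(shape),
        deaths_dementia=np.zeros(shape),
    )


def _bincount_gs(group: np.ndarray, state: np.ndarray, n_states: int) -> np.ndarray:
    flat = np.bincount(group * n_states + state, minlength=N_GROUPS * n_states)
    return flat.reshape(N_GROUPS, n_states)


def simulate(
    model: CalibratedModel,
    scenario: ScenarioSpec | None,
    config: SimulationConfig,
) -> CohortResult:
    """Simulate one scenario; aggregates to the oracle's result schema."""
    scenario = scenario or REFERENCE_SCENARIO
    if config.sex != model.sex:
        raise ValueError("simulation sex does not match the calibrated model")
    if config.max_age != model.life_table.max_age:
        raise ValueError("max_age does not match the calibrated model")
    max_age = config.max_age
    q_death, q_onset, p_prog, p_dd = _probability_tables(model, max_age)
    ref_cum = np.cumsum(model.fractions.as_array())
    collapsed = model.rates.stage.collapsed
    rs, rh = scenario.reduce_smoking, scenario.reduce_hypertension

    total = _empty_result(model, scenario.label, max_age)
    chunks: list[CohortResult] = []
    for ci, m in config.chunks():
        rng = _chunk_rng(config, ci)
        u_group = rng.random(m)
        u_rs = rng.random(m)
        u_rh = rng.random(m)
        latent = np.searchsorted(ref_cum, u_group, side="right").clip(0, 3)
        smokes = (latent == 1) | (latent == 3)
        htn = (latent == 2) | (latent == 3)
        # deterministic counterfactual mapping (common random numbers)
        smokes = smokes & (u_rs >= rs)
        htn = htn & (u_rh >= rh)
        group = (smokes.astype(np.int8) + 2 * htn.astype(np.int8)).astype(np.intp)

        res = _empty_result(model, scenario.label, max_age)
        res.n = float(m)
        states = np.zeros(m, dtype=np.intp)  # all start cognitively normal
        for a in range(max_age + 1):
            u = rng.random((3, m))
            res.occupancy[a] = _bincount_gs(group, states, N_STATES)
            start_gs = res.occupancy[a][:, :5].copy()
            alive = states < DEAD_DEMENTIA
            if not alive.any():
                # stream position is already advanced; occupancy recorded
                continue
            # step 1: other-cause death
            dies = alive & (u[0] < q_death[a, group])
            states[dies] = DEAD_OTHER
            res.deaths_other[a] = np.bincount(group[dies], minlength=N_GROUPS)
            # step 2: onset or single stage progression
            s0 = states.copy()
            onset = (s0 == NORMAL) & (u[1] < q_onset[a, group])
            states[onset] = MILD if collapsed else MCI
            res.onsets_mci[a] = np.bincount(group[onset], minlength=N_GROUPS)
            if collapsed:
                res.onsets_dementia[a] = res.onsets_mci[a]
            else:
                prog1 = (s0 == MCI) & (u[1] < p_prog[MCI])
                prog2 = (s0 == MILD) & (u[1] < p_prog[MILD])
                prog3 = (s0 == MODERATE) & (u[1] < p_prog[MODERATE])
                states[prog1] = MILD
                states[prog2] = MODERATE
                states[prog3] = SEVERE
                res.onsets_dementia[a] = np.bincount(group[prog1], minlength=N_GROUPS)
            # step 3: dementia death
            in_dem = (states >= MCI) & (states <= SEVERE)
            dd = in_dem & (u[2] < p_dd[states.clip(0, 4)])
            states[dd] = DEAD_DEMENTIA
            res.deaths_dementia[a] = np.bincount(group[dd], minlength=N_GROUPS)
            end_gs = _bincount_gs(group, states, N_STATES)[:, :5]
            res.person_years[a] = 0.5 * (start_gs + end_gs)
        total = total.add(res)
        if config.keep_chunks:
            chunks.append(res)
    if config.keep_chunks:
        total.chunk_results = chunks  # type: ignore[attr-defined]
    return total


def simulate_batch(
    model: CalibratedModel,
    scenarios: list[ScenarioSpec],
    config: SimulationConfig,
) -> dict[str, CohortResult]:
    """Run the reference plus all scenarios with shared CRN streams.

    The reference is always included (computed once); scenarios with
    identical reduction fractions share one computation.  Duplicate labels
    are an error.
    """
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate scenario labels")
    all_specs = [REFERENCE_SCENARIO] + [
        s for s in scenarios if not s.is_reference
    ]
    cache: dict[tuple[float, float], CohortResult] = {}
    out: dict[str, CohortResult] = {}
    for spec in all_specs:
        key = (spec.reduce_smoking, spec.reduce_hypertension)
        if key not in cache:
            cache[key] = simulate(model, spec, config)
        out[spec.label] = cache[key]
    return out
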