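"""Deterministic cohort oracle: hazard solves, recursion, closures."""

from dataclasses import replace

import numpy as np
import pytest

from demsim.cohort import (
    MCI,
    NORMAL,
    BaselineRates,
    StageParams,
    incidence_closure_error,
    lifetime_risk,
    mortality_closure_error,
    run_cohort,
    solve_annual_hazard,
    solve_baseline_incidence,
    solve_baseline_mortality,
)
from demsim.inputs import (
    GompertzParams,
    LifeTable,
    make_incidence_schedule,
    make_life_table,
)
from demsim.risk import GroupFractions, ScenarioSpec, allocate_groups

FEMALE_FRACTIONS = GroupFractions(0.824, 0.076, 0.076, 0.024)


def _no_mortality_table(sex="female", max_age=100):
    qx = np.zeros(max_age + 1)
    qx[-1] = 1.0
    return LifeTable(sex=sex, qx=qx, max_age=max_age)


def _unit_rr_config(config):
    return replace(
        config,
        rr_dementia_smoking=1.0,
        rr_dementia_hypertension=1.0,
        rr_mortality_smoking=1.0,
        rr_mortality_hypertension=1.0,
    )


class TestSolveAnnualHazard:
    def test_all_rr_one_reduces_to_single_hazard(self):
        q = 0.02
        m = solve_annual_hazard(np.full(4, 0.25), np.ones(4), q)
        assert m == pytest.approx(-np.log1p(-q), rel=1e-12)

    def test_weighted_mixture_hand_value(self):
        # composition and mortality RRs of the female parameter table; the
        # weighted RR sum is .824 + .076*1.9 + .076*1.3 + .024*2.2 = 1.12,
        # so the hazard-linear value is 0.02/1.12 = 0.017857 and the exact
        # probability-scale root lies ~1.3e-5 above it
        w = np.array([0.824, 0.076, 0.076, 0.024])
        rr = np.array([1.0, 1.9, 1.3, 2.2])
        m = solve_annual_hazard(w, rr, -np.expm1(-0.02))
        assert m == pytest.approx(0.02 / 1.12, abs=5e-5)
        # the solve is exact on the probability scale
        assert w @ (1 - np.exp(-rr * m)) == pytest.approx(-np.expm1(-0.02), abs=1e-14)

    def test_certain_death_gives_infinite_hazard(self):
        assert np.isinf(solve_annual_hazard(np.ones(1), np.ones(1), 1.0))

    def test_zero_target_gives_zero(self):
        assert solve_annual_hazard(np.ones(1), np.ones(1), 0.0) == 0.0


class TestBaselineSolves:
    def test_unit_rrs_recover_life_table_hazard(self, female_config, synthetic_female):
        table, inc = synthetic_female
        cfg = _unit_rr_config(female_config)
        m_none = solve_baseline_mortality(table, FEMALE_FRACTIONS, cfg, inc)
        h = table.hazard()
        assert m_none[:-1] == pytest.approx(h[:-1], rel=1e-10)

    def test_unit_rrs_recover_incidence_hazard(self, female_config, synthetic_female):
        table, inc = synthetic_female
        cfg = _unit_rr_config(female_config)
        h_none = solve_baseline_incidence(inc, FEMALE_FRACTIONS, table, cfg)
        expected = np.array([inc.hazard_at(a) for a in range(101)])
        # below the closing age (where everyone is dead before onset)
        assert h_none[:-1] == pytest.approx(expected[:-1], rel=1e-10)

    def test_exposed_composition_drifts_with_differential_mortality(
        self, female_config, synthetic_female
    ):
        # with no dementia at all, per-group survival factorizes into a
        # product over ages, which is an independent check of the recursion
        table, _ = synthetic_female
        inc0 = make_incidence_schedule(0.0, 5.0, sex="female")
        stage = StageParams()
        result, rates = run_cohort(
            FEMALE_FRACTIONS, table, inc0, female_config, stage=stage
        )
        from demsim.risk import rr_matrix

        rrm = rr_matrix(female_config, "mortality", 100)
        surv = FEMALE_FRACTIONS.as_array().copy()
        for a in range(90):
            surv = surv * np.exp(-rrm[a] * rates.m_none[a])
        alive90 = result.occupancy[90, :, :5].sum(axis=1)
        assert alive90 == pytest.approx(surv, rel=1e-9)
        # smokers are under-represented among survivors at 90
        pi_smoke = alive90[1] / alive90.sum()
        assert pi_smoke < FEMALE_FRACTIONS.f_smoking

    def test_calibration_closure_within_1e8(self, female_config, synthetic_female):
        table, inc = synthetic_female
        result, _ = run_cohort(FEMALE_FRACTIONS, table, inc, female_config)
        assert mortality_closure_error(result, table) < 1e-8
        assert incidence_closure_error(result, inc) < 1e-8


class TestRunCohort:
    def test_conservation_without_mortality_or_dementia(self, female_config):
        table = _no_mortality_table()
        inc = make_incidence_schedule(0.0, 5.0, sex="female")
        result, _ = run_cohort(FEMALE_FRACTIONS, table, inc, female_config)
        # everyone alive and cognitively normal at the closing age
        assert result.occupancy[100, :, NORMAL].sum() == pytest.approx(1.0)
        # 100 full years plus the closing half-year of person-time
        assert result.person_years.sum() == pytest.approx(100.5)
        assert result.py_dementia_by_age().sum() == 0.0

    def test_whole_cohort_dies(self, fitted_female):
        result = fitted_female.run_cohort()
        assert result.total_deaths() == pytest.approx(1.0, abs=1e-9)

    def test_null_scenario_identical_to_reference(self, fitted_female):
        ref = fitted_female.run_cohort()
        null = fitted_female.run_cohort(ScenarioSpec("null", 0.0, 0.0))
        assert ref.equals(null)

    def test_occupancy_simplex_and_absorbing_states(self, fitted_female):
        res = fitted_female.run_cohort()
        sums = res.occupancy.sum(axis=(1, 2))
        assert sums == pytest.approx(np.ones(101), abs=1e-9)
        dead = res.occupancy[:, :, 5:].sum(axis=(1, 2))
        assert np.all(np.diff(dead) >= -1e-12)


class TestLifetimeRisk:
    def test_zero_incidence_gives_zero(self, female_config):
        table = _no_mortality_table()
        inc = make_incidence_schedule(0.0, 5.0, sex="female")
        result, _ = run_cohort(FEMALE_FRACTIONS, table, inc, female_config)
        assert lifetime_risk(result) == 0.0

    def test_flat_hazard_no_mortality_closed_form(self, female_config):
        # with no mortality and a flat onset hazard h from 65, the chance of
        # remaining onset-free over the 35 modelled years is exp(-35h)
        h = 0.02
        table = _no_mortality_table()
        inc = make_incidence_schedule(h, np.inf, sex="female", onset_floor_age=65)
        stage = StageParams(
            excess_mortality_mci=0.0,
            excess_mortality_mild=0.0,
            excess_mortality_moderate=0.0,
            excess_mortality_severe=0.0,
        )
        result, _ = run_cohort(
            FEMALE_FRACTIONS, table, inc, female_config, stage=stage,
            incidence_event="mci_entry",
        )
        expected = 100.0 * -np.expm1(-35 * h)
        assert lifetime_risk(result, 65) == pytest.approx(expected, rel=1e-10)

    def test_nonincreasing_under_dementia_rr_lowering_with_fixed_mortality(
        self, female_config, synthetic_female
    ):
        # mortality RRs forced to 1 so scenarios only lower dementia risk
        table, inc = synthetic_female
        cfg = replace(
            female_config, rr_mortality_smoking=1.0, rr_mortality_hypertension=1.0
        )
        _, rates = run_cohort(FEMALE_FRACTIONS, table, inc, cfg)
        risks = []
        for r in (0.0, 0.25, 0.5, 1.0):
            res, _ = run_cohort(
                FEMALE_FRACTIONS, table, inc, cfg, rates=rates,
                scenario=ScenarioSpec(f"r{r}", r, r),
            )
            risks.append(lifetime_risk(res))
        assert np.all(np.diff(risks) <= 1e-9)
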