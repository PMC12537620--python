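"""Outcome summaries, scenario comparisons, age restriction, crossover."""

import numpy as np
import pytest

from demsim.cohort import CohortResult
from demsim.outcomes import (
    compare,
    crossover_age,
    moving_average,
    outcome_table,
    restrict_to_age,
    summarize,
)
from demsim.risk import ScenarioSpec


def _toy_result(onsets, at_risk_py, dem_py, free_py, scenario="toy", n=1000.0):
    """Hand-buildable 3-age cohort result (single group, ages 0..2)."""
    A = len(onsets) - 1
    occ = np.zeros((A + 1, 4, 7))
    occ[:, 0, 0] = np.asarray(free_py)  # normal occupancy proxy
    py = np.zeros((A + 1, 4, 5))
    py[:, 0, 0] = np.asarray(at_risk_py)  # at-risk person-years in 'normal'
    py[:, 0, 2] = np.asarray(dem_py)  # dementia person-years in 'mild'
    ons = np.zeros((A + 1, 4))
    ons[:, 0] = np.asarray(onsets)
    zeros = np.zeros((A + 1, 4))
    return CohortResult(
        sex="female",
        scenario=scenario,
        n=n,
        max_age=A,
        incidence_event="mci_entry",
        occupancy=occ,
        person_years=py,
        onsets_mci=ons,
        onsets_dementia=zeros.copy(),
        deaths_other=zeros.copy(),
        deaths_dementia=zeros.copy(),
    )


class TestSummarize:
    def test_toy_table_weighted_mean_by_hand(self):
        # onsets/at-risk rates: 0.02, 0.05, 0.10; weights 100:80:20
        res = _toy_result(
            onsets=[2.0, 4.0, 2.0],
            at_risk_py=[100.0, 80.0, 20.0],
            dem_py=[0.0, 10.0, 10.0],
            free_py=[100.0, 80.0, 20.0],
        )
        rep = summarize(res, standard=np.array([0.5, 0.3, 0.2]))
        expected_inc = (0.5 * 0.02 + 0.3 * 0.05 + 0.2 * 0.10) * 100
        assert rep.age_adjusted_incidence == pytest.approx(expected_inc)
        # prevalence: dementia share of alive person-years per age
        prev = np.array([0.0, 10 / 90.0, 10 / 30.0])
        assert rep.age_adjusted_prevalence == pytest.approx(
            100 * (0.5 * prev[0] + 0.3 * prev[1] + 0.2 * prev[2])
        )
        assert rep.total_cases == 8.0
        assert rep.ly_with_dementia == 20.0

    def test_self_weighting_makes_adjusted_equal_crude(self, fitted_female):
        res = fitted_female.run_cohort()
        rep = summarize(res)
        crude_inc = res.onsets().sum() / res.py_at_risk_by_age().sum() * 100
        crude_prev = res.py_dementia_by_age().sum() / res.py_alive_by_age().sum() * 100
        assert rep.age_adjusted_incidence == pytest.approx(crude_inc, rel=1e-12)
        assert rep.age_adjusted_prevalence == pytest.approx(crude_prev, rel=1e-12)

    def test_no_dementia_cohort_is_all_dementia_free(self, fitted_female):
        res = fitted_female.run_cohort()
        res = _toy_result([0, 0, 0], [50, 30, 20], [0, 0, 0], [50, 30, 20])
        rep = summarize(res)
        assert rep.age_adjusted_prevalence == 0.0
        assert rep.ly_without_dementia == rep.by_age_py_alive.sum()

    def test_weight_length_mismatch_rejected(self, fitted_female):
        res = fitted_female.run_cohort()
        with pytest.raises(ValueError, match="weights length"):
            summarize(res, standard=np.ones(5))


class TestCompare:
    def test_identical_reports_give_zero_changes(self, fitted_female):
        res = fitted_female.run_cohort()
        rep = summarize(res)
        cmp = compare(rep, rep)
        assert all(v == 0.0 for v in cmp.pct_change.values())
        assert cmp.crossover_age_cases is None

    def test_toy_crossover_detected_at_older_age(self):
        ref = _toy_result([5.0, 5.0, 5.0], [100, 100, 100], [0, 0, 0], [100] * 3)
        alt = _toy_result([3.0, 4.0, 6.0], [100, 100, 100], [0, 0, 0], [100] * 3)
        cmp = compare(summarize(ref), summarize(alt, standard=ref))
        assert cmp.crossover_age_cases_raw == 2.0

    def test_mismatched_sex_rejected(self, fitted_female):
        rep = summarize(fitted_female.run_cohort())
        other = summarize(_toy_result([0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]))
        with pytest.raises(ValueError):
            compare(rep, other)


class TestCrossoverAge:
    def test_simple_sign_change(self):
        diff = np.array([-2.0, -1.0, 1.0, 2.0])
        assert crossover_age(diff, smooth_window=1) == 2.0

    def test_all_nonnegative_returns_none(self):
        assert crossover_age(np.array([0.0, 1.0, 2.0])) is None

    def test_never_settling_returns_none(self):
        assert crossover_age(np.array([1.0, 1.0, -1.0]), smooth_window=1) is None

    def test_smoothing_suppresses_flicker(self):
        # a single positive blip inside a negative run is not a crossover
        # once smoothed
        diff = np.array([-5.0, -5.0, 0.5, -5.0, -5.0, 3.0, 4.0, 5.0])
        assert crossover_age(diff, smooth_window=1) == 5.0
        assert crossover_age(diff, smooth_window=3) == 5.0

    def test_moving_average_preserves_length_and_mean_of_constant(self):
        x = np.full(10, 3.0)
        assert np.allclose(moving_average(x, 5), x)


class TestRestrictToAge:
    def test_cutoff_at_max_age_is_identity(self, fitted_female):
        res = fitted_female.run_cohort()
        assert restrict_to_age(res, res.max_age) is res

    def test_truncation_conserves_person_years(self, fitted_female):
        res = fitted_female.run_cohort()
        r85 = restrict_to_age(res, 85)
        assert r85.max_age == 84
        assert r85.person_years.sum() == pytest.approx(
            res.person_years[:85].sum()
        )
        assert (
            r85.py_dementia_by_age().sum() + r85.py_dementia_free_by_age().sum()
            == pytest.approx(r85.person_years.sum())
        )

    def test_low_cutoff_warns(self, fitted_female):
        res = fitted_female.run_cohort()
        with pytest.warns(UserWarning, match="onset floor"):
            restrict_to_age(res, 30)


class TestOutcomeTable:
    def test_reference_row_has_zero_changes(self, fitted_female):
        results = {
            "reference": fitted_female.run_cohort(),
            "elim": fitted_female.run_cohort(ScenarioSpec("elim", 1.0, 1.0)),
        }
        table = outcome_table(results)
        ref_row = table[table.scenario == "reference"].iloc[0]
        assert ref_row["total_cases_pct_change"] == 0.0
        assert set(table.scenario) == {"reference", "elim"}

    def test_missing_reference_rejected(self, fitted_female):
        with pytest.raises(ValueError, match="reference"):
            outcome_table({"elim": fitted_female.run_cohort()})
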