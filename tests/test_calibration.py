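"""Calibration: fixed-point and GA fits, recovery, sensitivity models."""

from dataclasses import replace

import numpy as np
import pytest

from demsim.calibrate import (
    CalibratedModel,
    CalibrationError,
    CalibrationTargets,
    GAOptions,
    build_sensitivity_models,
    calibrate,
    _fitted_prevalences,
)
from demsim.cohort import mortality_closure_error, run_cohort
from demsim.risk import GroupFractions, allocate_groups

SMALL_GA = GAOptions(population_size=40, n_generations=80, objective_tol=1e-12)


def _unit_rr_config(config):
    return replace(
        config,
        rr_dementia_smoking=1.0,
        rr_dementia_hypertension=1.0,
        rr_mortality_smoking=1.0,
        rr_mortality_hypertension=1.0,
    )


class TestAnalyticCalibration:
    def test_unit_rrs_give_naive_fractions_and_life_table_rates(
        self, female_config, synthetic_female
    ):
        # without differential risks, survivor prevalence equals birth
        # prevalence, so calibration must return the naive allocation and
        # the baseline mortality must equal the life-table hazard
        table, inc = synthetic_female
        cfg = _unit_rr_config(female_config)
        fit = calibrate(CalibrationTargets.from_config(cfg, table, inc), cfg)
        naive = allocate_groups(cfg)
        assert fit.fractions.as_array() == pytest.approx(
            naive.as_array(), abs=1e-7
        )
        assert fit.rates.m_none[:-1] == pytest.approx(table.hazard()[:-1], rel=1e-6)

    def test_excess_mortality_requires_seeding_more_smokers(
        self, female_config, fitted_female
    ):
        # smokers die faster, so hitting a 10% survivor prevalence at 65-100
        # requires a larger birth share than the naive window value
        naive = allocate_groups(female_config)
        assert (
            fitted_female.fractions.f_smoking + fitted_female.fractions.f_both
            > naive.f_smoking + naive.f_both
        )

    def test_prevalence_targets_hit_within_tolerance(self, fitted_female):
        fitted = np.array(fitted_female.diagnostics["fitted"])
        targets = np.array(fitted_female.diagnostics["targets"])
        assert np.abs(fitted - targets).max() < 0.1  # percentage points

    def test_self_recovery_of_known_fractions(self, female_config, synthetic_female):
        # generate survivor-prevalence targets FROM a known parameter set
        # via the oracle, re-calibrate, and recover the birth fractions
        table, inc = synthetic_female
        truth = GroupFractions(0.80, 0.09, 0.08, 0.03)
        result, _ = run_cohort(truth, table, inc, female_config)
        prevs = _fitted_prevalences(result, female_config)
        targets = CalibrationTargets(
            prev_smoking=prevs[0],
            prev_hypertension=prevs[1],
            prev_both=prevs[2],
            life_table=table,
            incidence=inc,
        )
        fit = calibrate(targets, female_config)
        assert fit.fractions.as_array() == pytest.approx(
            truth.as_array(), abs=1e-4
        )

    def test_nonconvergence_raises_with_diagnostics(
        self, female_config, synthetic_female
    ):
        table, inc = synthetic_female
        targets = CalibrationTargets.from_config(female_config, table, inc)
        with pytest.raises(CalibrationError) as exc:
            calibrate(targets, female_config, max_iter=1, rtol=1e-12)
        assert "residual_history" in exc.value.diagnostics


class TestGACalibration:
    def test_ga_agrees_with_analytic_within_1e3(
        self, female_config, synthetic_female, fitted_female
    ):
        table, inc = synthetic_female
        targets = CalibrationTargets.from_config(female_config, table, inc)
        ga = calibrate(
            targets, female_config, method="ga", seed=11, ga_options=SMALL_GA
        )
        assert ga.diagnostics["objective"] <= 1e-4
        assert ga.fractions.as_array() == pytest.approx(
            fitted_female.fractions.as_array(), abs=1e-3
        )

    def test_ga_deterministic_under_fixed_seed(self, female_config, synthetic_female):
        table, inc = synthetic_female
        targets = CalibrationTargets.from_config(female_config, table, inc)
        opts = GAOptions(population_size=20, n_generations=15, objective_tol=0.0)
        a = calibrate(targets, female_config, method="ga", seed=5, ga_options=opts)
        b = calibrate(targets, female_config, method="ga", seed=5, ga_options=opts)
        assert np.array_equal(a.fractions.as_array(), b.fractions.as_array())
        assert np.array_equal(a.rates.m_none, b.rates.m_none)


class TestSerialization:
    def test_json_roundtrip_preserves_model(self, fitted_female, tmp_path):
        path = tmp_path / "model.json"
        fitted_female.to_json(path)
        back = CalibratedModel.from_json(path)
        assert back.fractions.as_array() == pytest.approx(
            fitted_female.fractions.as_array(), abs=0
        )
        assert np.array_equal(
            np.asarray(back.rates.h_none), np.asarray(fitted_female.rates.h_none)
        )
        assert back.run_cohort().equals(fitted_female.run_cohort())

    def test_summary_mentions_fit_quality(self, fitted_female):
        text = fitted_female.summary()
        assert "objective" in text and "Birth group fractions" in text


@pytest.fixture(scope="module")
def models(female_config, synthetic_female):
    table, inc = synthetic_female
    return build_sensitivity_models(female_config, table, inc)


class TestSensitivityModels:
    def test_exactly_twelve_models(self, models):
        assert len(models) == 12
        assert all(b in ("lower", "upper") for _, b in models)

    def test_bound_values_applied(self, models):
        m = models[("rr_dementia_smoking", "lower")]
        assert m.risk_config.rr_dementia_smoking == 1.2
        m = models[("prev_smoking", "upper")]
        assert m.risk_config.prev_smoking == 11.7

    def test_every_model_satisfies_closure_contract(self, models, synthetic_female):
        table, _ = synthetic_female
        for m in models.values():
            assert mortality_closure_error(m.run_cohort(), table) < 1e-8
            fitted = np.array(m.diagnostics["fitted"])
            targets = np.array(m.diagnostics["targets"])
            assert np.abs(fitted - targets).max() < 0.1

    def test_missing_ci_rejected(self, female_config, synthetic_female):
        table, inc = synthetic_female
        cfg = replace(female_config, ci_rr_dementia_smoking=None)
        with pytest.raises(ValueError, match="confidence interval"):
            build_sensitivity_models(cfg, table, inc)
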