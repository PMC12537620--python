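"""Synthetic input generators and the packaged risk-factor fixture."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demsim.inputs import (
    GompertzParams,
    IncidenceSchedule,
    IntegrityError,
    LifeTable,
    load_risk_config,
    make_incidence_schedule,
    make_life_table,
    subtract_dementia_share,
    fit_gompertz_to_life_expectancy,
)


class TestLifeTable:
    def test_zero_hazard_gives_zero_qx_below_closing_age(self):
        table = make_life_table(GompertzParams(0.0, 0.0, 0.1), "female")
        assert np.all(table.qx[:-1] == 0.0)

    def test_table_closed_at_max_age(self):
        table = make_life_table(GompertzParams(1e-4, 1e-5, 0.1), "male")
        assert table.qx[-1] == 1.0

    def test_survival_matches_gompertz_closed_form(self):
        # pure Gompertz: S(a) = exp(-(b/c)(e^{ca}-1)); the table's product
        # of (1-qx) over integer ages must reproduce it because each annual
        # qx is built from the hazard at the start of the year
        b, c = 1e-5, 0.1
        params = GompertzParams(0.0, b, c)
        table = make_life_table(params, "female")
        prod = np.prod(1.0 - table.qx[:80])
        # discrete product of exp(-h(a)) equals exp(-sum h(a)); compare to
        # the same quantity computed from the closed-form hazard directly
        expected = np.exp(-np.sum(b * np.exp(c * np.arange(80))))
        assert prod == pytest.approx(expected, abs=1e-6)
        # and the closed-form integral is close to the discrete sum
        analytic = np.exp(-params.cumulative_hazard(80))
        assert prod == pytest.approx(analytic, rel=5e-2)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(0, 0.01),
        b=st.floats(1e-7, 1e-4),
        c=st.floats(0.05, 0.2),
    )
    def test_survival_curve_non_increasing_and_vanishes(self, a, b, c):
        table = make_life_table(GompertzParams(a, b, c), "female")
        lx = table.survival()
        assert np.all(np.diff(lx) <= 1e-15)
        assert lx[-1] == 0.0

    def test_roundtrip_csv_bit_exact(self, tmp_path):
        table = make_life_table(GompertzParams(3e-4, 2e-5, 0.11), "male")
        path = tmp_path / "lt.csv"
        table.to_csv(path)
        back = LifeTable.from_csv(path)
        assert back.sex == "male"
        assert np.array_equal(back.qx, table.qx)

    def test_subtract_dementia_share_reduces_hazard(self):
        table = make_life_table(GompertzParams(1e-4, 1e-5, 0.1), "female")
        adj = subtract_dementia_share(table, 0.2)
        assert np.all(adj.qx[:-1] <= table.qx[:-1])
        assert adj.qx[-1] == 1.0
        # hazard scales by exactly (1 - share)
        assert adj.hazard()[50] == pytest.approx(0.8 * table.hazard()[50])

    def test_life_expectancy_fit_hits_target(self):
        params = fit_gompertz_to_life_expectancy(82.0, "female")
        assert make_life_table(params, "female").life_expectancy() == pytest.approx(
            82.0, abs=1e-6
        )

    def test_non_finite_hazard_rejected(self):
        with pytest.raises(ValueError):
            make_life_table(GompertzParams(0.0, 1.0, 10.0), "female")


class TestIncidenceSchedule:
    def test_doubling_arithmetic(self):
        inc = make_incidence_schedule(0.01, 5.0, sex="female")
        assert inc.h_pop[75] == pytest.approx(0.04)

    def test_flat_limit_for_infinite_doubling_time(self):
        inc = make_incidence_schedule(0.01, np.inf, sex="female")
        assert np.all(inc.h_pop[65:] == pytest.approx(0.01))

    def test_zero_below_onset_floor(self):
        inc = make_incidence_schedule(0.01, 5.0, sex="female")
        assert np.all(inc.h_pop[:40] == 0.0)

    def test_monotone_when_no_trend(self):
        inc = make_incidence_schedule(0.005, 6.0, 0.0, sex="male")
        assert np.all(np.diff(inc.h_pop[40:]) >= 0)

    def test_no_trend_multiplier_is_identity(self):
        inc = make_incidence_schedule(0.01, 5.0, 0.0, sex="female")
        assert all(inc.trend_multiplier(a) == 1.0 for a in (0, 50, 100))

    def test_trend_multiplier_linear_and_clipped(self):
        inc = make_incidence_schedule(
            0.01, 5.0, 0.2, sex="female", reference_year=2015, birth_year=1980
        )
        # age 35 -> year 2015 -> multiplier 1
        assert inc.trend_multiplier(35) == pytest.approx(1.0)
        assert inc.trend_multiplier(45) == pytest.approx(0.8)
        assert inc.trend_multiplier(95) == 0.0  # clipped at zero

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            make_incidence_schedule(-0.01, 5.0, sex="female")

    def test_roundtrip_csv_bit_exact(self, tmp_path):
        inc = make_incidence_schedule(0.0021, 5.5, 0.13, sex="female")
        path = tmp_path / "inc.csv"
        inc.to_csv(path)
        back = IncidenceSchedule.from_csv(path)
        assert np.array_equal(back.h_pop, inc.h_pop)
        assert back.trend_decline_per_decade == inc.trend_decline_per_decade
        assert back.reference_year == inc.reference_year


class TestRiskFactorFixture:
    def test_female_point_estimates(self, female_config):
        assert female_config.prev_smoking == 10.0
        assert female_config.ci_prev_smoking == (8.6, 11.7)
        assert female_config.rr_dementia_hypertension == 1.6
        assert female_config.ci_rr_dementia_hypertension == (1.2, 2.2)
        assert female_config.rr_mortality_smoking == 1.9

    def test_male_point_estimates(self, male_config):
        assert male_config.prev_smoking == 13.8
        assert male_config.prev_hypertension == 9.3
        assert male_config.rr_mortality_smoking == 1.8

    def test_checksum_guard(self, monkeypatch):
        import demsim.inputs as di

        monkeypatch.setattr(di, "_FIXTURE_SHA256", "0" * 64)
        with pytest.raises(IntegrityError):
            load_risk_config("female")
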