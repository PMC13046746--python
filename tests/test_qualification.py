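"""Aging arithmetic, zero-point drift analysis and accuracy grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icplab.qualification import (
    CM_FLUID_TO_MMHG,
    AgingProtocol,
    DriftLog,
    DriftModel,
    GridCoverageError,
    ToleranceSpec,
    acceleration_factor,
    accuracy_evaluate,
    drift_qualify,
    equivalent_duration,
    real_duration_for,
    zero_point_error,
    zero_point_series,
)
from icplab.synthetic import DriftSimSpec, gen_accuracy_grid, gen_drift_log


class TestAging:
    def test_default_acceleration_factor(self):
        af = acceleration_factor(AgingProtocol())
        assert af == pytest.approx(2 ** 4.6 * 162 / 168, rel=1e-12)
        assert round(af, 1) == 23.4

    def test_identity_when_no_elevation(self):
        assert acceleration_factor(AgingProtocol(elevated_temp=39.0, duty=1.0)) == 1.0

    def test_full_duty(self):
        assert acceleration_factor(AgingProtocol(duty=1.0)) == pytest.approx(2**4.6, rel=1e-12)

    def test_22_weeks_is_about_ten_years(self):
        years = equivalent_duration(22.0)
        assert years == pytest.approx(9.86, abs=0.005)

    def test_one_real_year_maps_to_af_years(self):
        assert equivalent_duration(52.18) == pytest.approx(acceleration_factor(AgingProtocol()), abs=0.01)

    def test_duration_round_trip(self):
        protocol = AgingProtocol()
        assert real_duration_for(equivalent_duration(22.0, protocol), protocol) == pytest.approx(22.0, rel=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        q10=st.floats(1.1, 4.0),
        elevated=st.floats(40.0, 120.0),
        duty=st.floats(0.1, 1.0),
    )
    def test_monotone_in_each_parameter(self, q10, elevated, duty):
        base = acceleration_factor(AgingProtocol(q10=q10, elevated_temp=elevated, duty=duty))
        assert acceleration_factor(AgingProtocol(q10=q10 + 0.2, elevated_temp=elevated, duty=duty)) >= base
        assert acceleration_factor(AgingProtocol(q10=q10, elevated_temp=elevated + 5, duty=duty)) >= base
        assert acceleration_factor(AgingProtocol(q10=q10, elevated_temp=elevated, duty=min(1.0, duty + 0.05))) >= base

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            AgingProtocol(q10=1.0)
        with pytest.raises(ValueError):
            AgingProtocol(duty=0.0)
        with pytest.raises(ValueError):
            AgingProtocol(elevated_temp=20.0)


class TestZeroPoint:
    def test_exact_balance(self):
        assert zero_point_error(760.0 + CM_FLUID_TO_MMHG, 760.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_printed_constant_arithmetic(self):
        assert zero_point_error(761.0, 760.0, 1.0) == pytest.approx(0.26441, abs=1e-9)

    def test_no_head_no_offset(self):
        assert zero_point_error(758.0, 758.0, 0.0) == 0.0

    def test_missing_barometer_is_an_error(self):
        with pytest.raises(ValueError, match="barometer"):
            zero_point_error(760.0, np.nan, 1.0)

    def test_series_starts_at_zero_and_constant_log_is_flat(self):
        log = DriftLog(gen_drift_log(DriftSimSpec(n_implants=3, duration_weeks=6, noise_sd=0.0, seed=2)))
        s = zero_point_series(log, "imp02")
        assert s.iloc[0] == 0.0
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_unknown_implant(self):
        log = DriftLog(gen_drift_log(DriftSimSpec(n_implants=1, duration_weeks=2, seed=0)))
        with pytest.raises(KeyError):
            zero_point_series(log, "imp99")

    def test_invariant_to_common_mode_offsets(self):
        df = gen_drift_log(DriftSimSpec(n_implants=1, duration_weeks=8, noise_sd=0.3, seed=4))
        s1 = zero_point_series(DriftLog(df), "imp01")
        shifted = df.copy()
        shifted["implant_abs_pressure_mmhg"] += 7.5
        shifted["barometer_mmhg"] += 7.5
        s2 = zero_point_series(DriftLog(shifted), "imp01")
        assert np.allclose(s1, s2, atol=1e-10)


class TestDriftQualify:
    def test_all_zero_series_passes(self):
        s = pd.Series(np.zeros(10), index=pd.date_range("2024-01-01", periods=10))
        q = drift_qualify(s, limit_mmhg=2.0)
        assert q.passed and q.max_excursion_mmhg == 0.0

    def test_excursion_located_and_failed(self):
        idx = pd.date_range("2024-01-01", periods=10)
        vals = np.zeros(10)
        vals[6] = 2.5
        q = drift_qualify(pd.Series(vals, index=idx), limit_mmhg=2.0)
        assert not q.passed
        assert q.max_excursion_mmhg == 2.5
        assert q.excursion_time == idx[6]

    def test_sub_limit_cohort_all_pass(self):
        spec = DriftSimSpec(n_implants=16, duration_weeks=52, true_drift_rate=0.5, noise_sd=0.1, seed=8)
        results = DriftModel(DriftLog(gen_drift_log(spec))).fit()
        table = results.qualify(limit_mmhg=2.0)
        assert table["passed"].all() and len(table) == 16


class TestAccuracy:
    def test_zero_error_grid_passes_with_zero_mean(self):
        report = accuracy_evaluate(gen_accuracy_grid(seed=0))
        assert report.passed
        assert report.pressure_error_mean == 0.0
        assert report.n_measurements == 462

    def test_single_bias_cell_flagged(self):
        def biased(set_p, set_t, rng):
            dp = np.zeros_like(set_p)
            dp[100] = 2.5
            return dp, np.zeros_like(set_t)

        report = accuracy_evaluate(gen_accuracy_grid(error_model=biased, seed=0))
        assert not report.passed
        assert int((~report.cells["pressure_ok"]).sum()) == 1
        assert not report.cells["pressure_ok"].iloc[100]

    def test_bounded_uniform_error_passes(self, rng):
        def uniform(set_p, set_t, r):
            return r.uniform(-1, 1, len(set_p)), r.uniform(-1, 1, len(set_t))

        report = accuracy_evaluate(gen_accuracy_grid(error_model=uniform, seed=3))
        assert report.passed

    def test_non_spanning_grid_is_a_coverage_failure(self):
        g = gen_accuracy_grid(pressure_range=(500.0, 900.0), seed=0)
        with pytest.raises(GridCoverageError):
            accuracy_evaluate(g)

    def test_temperature_channel_mirrors_pressure(self):
        def t_biased(set_p, set_t, rng):
            return np.zeros_like(set_p), np.full_like(set_t, 2.5)

        report = accuracy_evaluate(gen_accuracy_grid(error_model=t_biased, seed=0))
        assert not report.passed
        assert (~report.cells["temp_ok"]).all()
        assert report.cells["pressure_ok"].all()
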