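"""ICP pulse metrics and longitudinal diary analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icplab.icp import IcpRecording, excursion_flags, longitudinal_summary, pulse_metrics, reading_summary
from icplab.synthetic import IcpSimSpec, gen_icp


def sinusoid_recording(f=1.2, p2t=2.0, offset=10.0, duration=20.0, fs=50.0, posture="unspecified"):
    t = np.arange(int(duration * fs)) / fs
    return IcpRecording(samples=offset + 0.5 * p2t * np.sin(2 * np.pi * f * t), fs=fs, posture=posture)


class TestPulseMetrics:
    def test_pure_sinusoid(self):
        m = pulse_metrics(sinusoid_recording(f=1.2, p2t=2.0, offset=10.0))
        assert m.mean_icp == pytest.approx(10.0, abs=0.01)
        assert m.pulse_amplitude == pytest.approx(2.0, rel=0.02)
        assert m.heart_rate_est == pytest.approx(72.0, abs=0.5)
        assert m.quality_flag == "ok"

    def test_offset_invariance(self):
        a = pulse_metrics(sinusoid_recording(offset=0.0)).pulse_amplitude
        b = pulse_metrics(sinusoid_recording(offset=-15.0)).pulse_amplitude
        assert a == pytest.approx(b, rel=1e-9)

    def test_linear_scaling(self):
        a = pulse_metrics(sinusoid_recording(p2t=2.0)).pulse_amplitude
        b = pulse_metrics(sinusoid_recording(p2t=6.0)).pulse_amplitude
        assert b == pytest.approx(3.0 * a, rel=1e-9)

    @pytest.mark.parametrize("hr", [50, 70, 90, 110])
    def test_heart_rate_recovery_noiseless(self, hr):
        rec = gen_icp(IcpSimSpec(duration_s=30, pulse_amp=2.0, heart_rate=hr, resp_amp=0.0, noise_sd=0.0, seed=0))
        assert pulse_metrics(rec).heart_rate_est == pytest.approx(hr, abs=1.0)

    def test_generator_recovery_with_noise(self):
        rec = gen_icp(IcpSimSpec(duration_s=30, pulse_amp=2.0, heart_rate=70, resp_amp=0.5, noise_sd=0.2, seed=7))
        m = pulse_metrics(rec)
        assert m.pulse_amplitude == pytest.approx(2.0, rel=0.10)
        assert m.quality_flag == "ok"

    def test_zero_variance_low_beats(self):
        rec = IcpRecording(samples=np.full(500, 12.0))
        m = pulse_metrics(rec)
        assert m.pulse_amplitude == 0.0
        assert m.n_beats == 0
        assert m.quality_flag == "low_beats"

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            pulse_metrics(IcpRecording(samples=np.zeros(100)))

    def test_band_validated(self):
        rec = sinusoid_recording()
        with pytest.raises(ValueError, match="band"):
            pulse_metrics(rec, band=(0.67, 30.0))

    def test_spectral_mode_agrees_on_sinusoid(self):
        rec = sinusoid_recording(f=1.2, p2t=2.0)
        beat = pulse_metrics(rec, method="beat").pulse_amplitude
        spectral = pulse_metrics(rec, method="spectral").pulse_amplitude
        assert spectral == pytest.approx(beat, rel=0.05)
        assert spectral == pytest.approx(2.0, rel=0.05)

    def test_band_edge_flagged_aliased(self):
        rec = sinusoid_recording(f=0.69, p2t=2.0)
        assert pulse_metrics(rec).quality_flag == "aliased"

    def test_beat_count_consistent_with_duration(self):
        rec = sinusoid_recording(f=1.2, duration=20.0)
        m = pulse_metrics(rec)
        assert m.n_beats == pytest.approx(20.0 * m.heart_rate_est / 60.0, rel=0.2)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(offset=st.floats(-25, 30), scale=st.floats(0.5, 5.0))
    def test_amplitude_offset_and_scale_properties(self, offset, scale):
        base = sinusoid_recording(p2t=2.0, offset=0.0)
        rec = IcpRecording(samples=offset + scale * base.samples, fs=base.fs)
        m = pulse_metrics(rec)
        assert m.pulse_amplitude == pytest.approx(scale * 2.0, rel=0.03)
        assert m.mean_icp == pytest.approx(offset, abs=0.01)


class TestReadingSummary:
    def test_negative_mean_and_posture_carried(self):
        row = reading_summary(sinusoid_recording(offset=-15.0, posture="standing"))
        assert row["posture"] == "standing"
        assert row["mean_icp_mmhg"] == pytest.approx(-15.0, abs=0.01)

    def test_empty_posture_defaults_to_unspecified(self):
        row = reading_summary(sinusoid_recording(posture=""))
        assert row["posture"] == "unspecified"

    def test_rows_order_preserving(self):
        rows = [reading_summary(sinusoid_recording(offset=o)) for o in (5.0, 7.0)]
        assert rows[0]["mean_icp_mmhg"] < rows[1]["mean_icp_mmhg"]


def make_diary(n=40, postures=("lying", "standing"), offsets=(5.0, -10.0), noise=0.0, seed=0, step=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        posture = postures[i % len(postures)]
        mean = offsets[i % len(offsets)] + (rng.normal(0, noise) if noise else 0.0)
        if step is not None and i >= step[0]:
            mean += step[1]
        rows.append(
            {
                "timestamp": pd.Timestamp("2024-01-01") + pd.Timedelta(days=i),
                "posture": posture,
                "mean_icp_mmhg": mean,
                "pulse_amplitude_mmhg": 2.0,
            }
        )
    return pd.DataFrame(rows)


class TestLongitudinal:
    def test_constant_diary_is_perfectly_stable(self):
        summary, stability = longitudinal_summary(make_diary(), window_days=14)
        assert all(v == 0.0 for v in stability.values())

    def test_posture_medians_separated_by_offsets(self):
        diary = make_diary(n=60, noise=0.5, seed=3)
        summary, _ = longitudinal_summary(diary, window_days=14)
        med = summary.groupby("posture")["mean_icp_mmhg"].median()
        assert med["lying"] - med["standing"] == pytest.approx(15.0, abs=1.0)

    def test_single_row(self):
        diary = make_diary(n=1)
        summary, stability = longitudinal_summary(diary, window_days=7)
        assert len(summary) == 1
        assert summary["mean_icp_mmhg_median"].iloc[0] == diary["mean_icp_mmhg"].iloc[0]


class TestExcursionFlags:
    def test_constant_diary_no_flags(self):
        flags = excursion_flags(make_diary(n=40), baseline_window_days=14, k=3.0)
        assert not flags["flagged"].any()

    def test_step_change_flags_post_step_readings(self):
        # one posture only; +15 mmHg step late in the diary (shunt-blockage scenario)
        diary = make_diary(n=30, postures=("lying",), offsets=(8.0,), noise=0.2, seed=5, step=(24, 15.0))
        flags = excursion_flags(diary, baseline_window_days=24, k=3.0).sort_values("timestamp")
        evaluated = flags["status"] == "evaluated"
        assert flags.loc[evaluated & (flags.index >= 24), "flagged"].all()
        assert not flags.loc[flags.index < 24, "flagged"].any()

    def test_large_k_never_flags(self):
        diary = make_diary(n=30, postures=("lying",), offsets=(8.0,), noise=1.0, seed=6)
        flags = excursion_flags(diary, baseline_window_days=10, k=1e9)
        assert not flags["flagged"].any()

    def test_window_longer_than_span_rejected(self):
        with pytest.raises(ValueError, match="diary span"):
            excursion_flags(make_diary(n=10), baseline_window_days=30)

    def test_insufficient_baseline_not_evaluable(self):
        flags = excursion_flags(make_diary(n=20, postures=("lying",), offsets=(8.0,)), baseline_window_days=10)
        assert (flags["status"].iloc[:3] == "not_evaluable").all()
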