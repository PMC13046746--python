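"""Intracranial-pressure waveform analytics.

A home telemetry reading is a short (>= 5 s) uniformly sampled pressure
series at 50 Hz.  The clinically reported quantities are the mean ICP of
the reading and the amplitude of the cardiac-related pulse wave — the
heartbeat-synchronous oscillation riding on the mean.  The cardiac
component is isolated with a zero-phase band-pass (default 0.67-3.0 Hz,
i.e. 40-180 bpm), beats are segmented by peak detection on the filtered
signal, and the amplitude is the *median* over beats of the per-beat
peak-to-trough excursion.  A single-bin spectral amplitude is available
as a cross-checking alternative (``method="spectral"``).

Longitudinal summaries group per-reading rows by posture (ICP is strongly
posture dependent and may be negative upright) and compute rolling
medians; excursion flagging against the per-posture baseline is purely
descriptive and not a clinical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "DEFAULT_CARDIAC_BAND_HZ",
    "IcpRecording",
    "PulseMetrics",
    "pulse_metrics",
    "reading_summary",
    "longitudinal_summary",
    "excursion_flags",
]

DEFAULT_CARDIAC_BAND_HZ = (0.67, 3.0)
MIN_DURATION_S = 5.0
MIN_BEATS = 5


@dataclass
class IcpRecording:
    """One uniformly sampled ICP reading.

    samples in mmHg (gauge; negative values are physiological when
    upright), fs in Hz, posture a free-text label ("unspecified" when
    empty).  Recordings with gaps are split upstream; no missing samples.
    """

    samples: np.ndarray
    fs: float = 50.0
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2024-01-01T00:00:00"))
    posture: str = "unspecified"
    patient_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D sequence")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains missing samples; split gaps upstream")
        if not self.posture:
            self.posture = "unspecified"
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class PulseMetrics:
    """Per-reading cardiac pulse metrics."""

    mean_icp: float  # mmHg
    pulse_amplitude: float  # mmHg, median per-beat peak-to-trough
    heart_rate_est: float  # beats/min (nan if no beats)
    n_beats: int
    quality_flag: str  # ok | low_beats | aliased


def _band_passed(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x - x.mean())


def pulse_metrics(
    rec: IcpRecording,
    band: tuple[float, float] = DEFAULT_CARDIAC_BAND_HZ,
    method: str = "beat",
) -> PulseMetrics:
    """Mean ICP and cardiac pulse amplitude of one reading.

    ``method="beat"`` (canonical): median per-beat peak-to-trough on the
    band-passed signal.  ``method="spectral"``: peak-to-trough implied by
    the largest periodogram bin inside the band; heart rate and beat
    count still come from peak detection.
    """
    if rec.duration_s < MIN_DURATION_S:
        raise ValueError(
            f"recording too short for amplitude estimation: "
            f"{rec.duration_s:.2f} s < {MIN_DURATION_S} s"
        )
    lo, hi = band
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"band {band} must lie within (0, fs/2) = (0, {rec.fs / 2})")

    x = rec.samples
    mean_icp = float(x.mean())

    if np.ptp(x) < 1e-12:
        return PulseMetrics(mean_icp, 0.0, float("nan"), 0, "low_beats")

    y = _band_passed(x, rec.fs, band)
    min_distance = max(1, int(round(rec.fs / hi * 0.7)))
    prominence = 0.25 * (np.percentile(y, 95) - np.percentile(y, 5))
    peaks, _ = signal.find_peaks(y, distance=min_distance, prominence=max(prominence, 1e-12))

    n_beats = max(0, len(peaks) - 1)
    if n_beats == 0:
        return PulseMetrics(mean_icp, 0.0, float("nan"), 0, "low_beats")

    # sub-sample peak positions (parabolic interpolation) de-quantize the rate
    pk = peaks.astype(float)
    interior = (peaks > 0) & (peaks < len(y) - 1)
    ym, y0, yp = y[peaks[interior] - 1], y[peaks[interior]], y[peaks[interior] + 1]
    denom = ym - 2 * y0 + yp
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (ym - yp) / np.where(denom == 0, 1, denom), 0.0)
    pk[interior] += np.clip(shift, -0.5, 0.5)
    intervals_s = np.diff(pk) / rec.fs
    heart_rate = 60.0 / float(np.median(intervals_s))
    f_cardiac = heart_rate / 60.0

    if method == "beat":
        beat_amps = [
            float(y[peaks[i]] - y[peaks[i] : peaks[i + 1] + 1].min())
            for i in range(n_beats)
        ]
        amplitude = float(np.median(beat_amps))
    elif method == "spectral":
        n = len(x)
        spec = np.abs(np.fft.rfft(x - x.mean())) * 2.0 / n
        freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
        in_band = (freqs >= lo) & (freqs <= hi)
        amplitude = 2.0 * float(spec[in_band].max())  # peak-to-trough of the dominant tone
    else:
        raise ValueError(f"unknown method {method!r}; use 'beat' or 'spectral'")

    flag = "ok"
    if n_beats < MIN_BEATS:
        flag = "low_beats"
    elif f_cardiac <= lo * 1.05 or f_cardiac >= hi * 0.95:
        flag = "aliased"
    return PulseMetrics(mean_icp, amplitude, heart_rate, n_beats, flag)


def reading_summary(rec: IcpRecording, band: tuple[float, float] = DEFAULT_CARDIAC_BAND_HZ) -> dict:
    """One longitudinal-table row for a recording."""
    m = pulse_metrics(rec, band=band)
    return {
        "timestamp": rec.start_time,
        "patient_id": rec.patient_id,
        "posture": rec.posture or "unspecified",
        "mean_icp_mmhg": m.mean_icp,
        "pulse_amplitude_mmhg": m.pulse_amplitude,
        "heart_rate_bpm": m.heart_rate_est,
        "quality_flag": m.quality_flag,
    }


def _check_rows(rows: pd.DataFrame) -> pd.DataFrame:
    required = ["timestamp", "posture", "mean_icp_mmhg", "pulse_amplitude_mmhg"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"diary rows missing column(s): {missing}")
    if rows.empty:
        raise ValueError("need at least one diary row")
    rows = rows.copy()
    rows["timestamp"] = pd.to_datetime(rows["timestamp"])
    rows["posture"] = rows["posture"].fillna("unspecified").replace("", "unspecified")
    return rows.sort_values("timestamp")


def longitudinal_summary(
    rows: pd.DataFrame, group_by: str = "posture", window_days: float = 30.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Rolling per-group medians and IQRs of a reading diary.

    Returns (summary table, stability statistic per group).  The
    stability statistic is the largest absolute deviation of any rolling
    window median from that group's whole-diary median — 0 for a
    perfectly stable diary.
    """
    rows = _check_rows(rows)
    window = pd.Timedelta(days=window_days)
    out = []
    stability: dict[str, float] = {}
    for label, grp in rows.groupby(group_by):
        g = grp.set_index("timestamp").sort_index()
        for col in ("mean_icp_mmhg", "pulse_amplitude_mmhg"):
            roll = g[col].rolling(window, min_periods=1)
            g[f"{col}_median"] = roll.median()
            g[f"{col}_iqr"] = roll.quantile(0.75) - roll.quantile(0.25)
        stability[label] = float(
            (g["mean_icp_mmhg_median"] - g["mean_icp_mmhg"].median()).abs().max()
        )
        g[group_by] = label
        out.append(g.reset_index())
    return pd.concat(out, ignore_index=True), stability


def excursion_flags(
    rows: pd.DataFrame,
    baseline_window_days: float = 30.0,
    k: float = 3.0,
) -> pd.DataFrame:
    """Flag readings far from their per-posture rolling baseline.

    A reading is flagged when |mean ICP - trailing median| > k x trailing
    IQR, computed per posture over the preceding ``baseline_window_days``
    (the reading itself excluded).  Readings with fewer than
    ``MIN_BEATS`` baseline points get status ``not_evaluable``.  Purely
    descriptive — not a diagnostic claim.
    """
    rows = _check_rows(rows)
    span = rows["timestamp"].max() - rows["timestamp"].min()
    if span <= pd.Timedelta(days=baseline_window_days):
        raise ValueError(
            f"baseline window ({baseline_window_days} d) must be shorter than the diary span "
            f"({span / pd.Timedelta(days=1):.1f} d)"
        )
    window = pd.Timedelta(days=baseline_window_days)
    min_baseline = 5
    out = []
    for label, grp in rows.groupby("posture"):
        g = grp.set_index("timestamp").sort_index()
        x = g["mean_icp_mmhg"]
        roll = x.rolling(window, closed="left")
        med = roll.median()
        iqr = roll.quantile(0.75) - roll.quantile(0.25)
        count = roll.count()
        dev = (x - med).abs()
        g["baseline_median_mmhg"] = med
        g["baseline_iqr_mmhg"] = iqr
        g["deviation_mmhg"] = dev
        g["status"] = np.where(count >= min_baseline, "evaluated", "not_evaluable")
        g["flagged"] = (count >= min_baseline) & (dev > k * iqr)
        g["posture"] = label
        out.append(g.reset_index())
    return pd.concat(out, ignore_index=True).sort_values("timestamp").reset_index(drop=True)
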