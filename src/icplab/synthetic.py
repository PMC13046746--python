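"""Synthetic inputs for every stage of the pipeline.

Nothing downstream requires external data: head surfaces are emulated by
watertight sphere/ellipsoid meshes of head-like dimensions, the drift
rig by an absolute-pressure + barometer + fluid-head model with injected
linear drift, the accuracy rig by a full-factorial pressure/temperature
grid, and home ICP readings by mean level + cardiac sinusoid +
respiratory component + noise with a posture schedule.

Every generator is a pure function of its spec, including the seed; no
global random state is touched.  The cardiac component is a single
sinusoid (optional small harmonics, off by default): waveform morphology
is deliberately simplistic because amplitude recovery — not shape — is
what the analytics are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .icp import IcpRecording
from .qualification import CM_FLUID_TO_MMHG, DAYS_PER_YEAR, DRIFT_LOG_COLUMNS

__all__ = [
    "HeadMeshSpec",
    "DriftSimSpec",
    "IcpSimSpec",
    "gen_head_mesh",
    "gen_drift_log",
    "gen_icp",
    "gen_accuracy_grid",
]

_EPOCH = pd.Timestamp("2024-01-01T00:00:00")
_BARO_CLIP_MMHG = (730.0, 790.0)


@dataclass(frozen=True)
class HeadMeshSpec:
    """A sphere or ellipsoid standing in for a head surface.

    semi_axes in mm; the default 70 x 90 x 80 mm emulates an adult head
    (left-right, front-back, up-down half-extents).  mesh_resolution is
    the target edge length in mm.
    """

    shape: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (70.0, 90.0, 80.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mesh_resolution: float = 5.0

    def __post_init__(self):
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"shape must be 'sphere' or 'ellipsoid', got {self.shape!r}")
        axes = tuple(float(a) for a in self.semi_axes)
        if any(a <= 0 for a in axes):
            raise ValueError(f"semi_axes must all be > 0, got {axes}")
        if self.shape == "sphere" and len(set(axes)) != 1:
            raise ValueError("sphere requires equal semi_axes")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be > 0")
        object.__setattr__(self, "semi_axes", axes)
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


def gen_head_mesh(spec: HeadMeshSpec) -> trimesh.Trimesh:
    """Watertight, outward-oriented triangulated head stand-in.

    An icosphere is subdivided until its edge length (after anisotropic
    scaling) is at or below ``mesh_resolution``, then scaled to the
    semi-axes.  The construction is fully deterministic.
    """
    # unit icosahedron edge ~ 1.0515, halved per subdivision
    worst = max(spec.semi_axes)
    subdiv = int(np.clip(np.ceil(np.log2(1.0515 * worst / spec.mesh_resolution)), 1, 7))
    mesh = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    verts = mesh.vertices * np.asarray(spec.semi_axes) + np.asarray(spec.center)
    out = trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
    if not out.is_watertight:  # construction guarantees this; fail loudly if not
        raise RuntimeError("generated head mesh is not watertight")
    if out.volume < 0:
        out.invert()
    return out


@dataclass(frozen=True)
class DriftSimSpec:
    """Drift-rig simulation: a cohort of implants read at fixed intervals.

    true_drift_rate in mmHg/year (linear), noise_sd per-reading mmHg,
    head_height_cm the fixed fluid head above the implants, barometer a
    bounded Gaussian random walk (baro_walk_sd mmHg per sqrt-day) shared
    by all implants on the rig.
    """

    n_implants: int = 16
    duration_weeks: float = 52.0
    read_interval: float = 1.0  # days
    true_drift_rate: float = 0.0  # mmHg/year
    noise_sd: float = 0.1  # mmHg
    head_height_cm: float = 1.0
    baro_mean: float = 760.0
    baro_walk_sd: float = 2.0  # mmHg/day
    temperature_c: float = 38.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_weeks <= 0:
            raise ValueError("duration_weeks must be > 0")
        if self.read_interval <= 0:
            raise ValueError("read_interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_implants < 1:
            raise ValueError("n_implants must be >= 1")


def gen_drift_log(spec: DriftSimSpec) -> pd.DataFrame:
    """Simulated drift-rig log, one record per implant per read interval.

    implant absolute pressure = barometer + fluid head + drift(t) + noise.
    """
    rng = np.random.default_rng(spec.seed)
    t_days = np.arange(0.0, spec.duration_weeks * 7.0 + 1e-9, spec.read_interval)
    n_t = len(t_days)

    steps = rng.normal(0.0, spec.baro_walk_sd * np.sqrt(spec.read_interval), size=n_t)
    steps[0] = 0.0
    baro = np.clip(spec.baro_mean + np.cumsum(steps), *_BARO_CLIP_MMHG)

    head_mmhg = spec.head_height_cm * CM_FLUID_TO_MMHG
    drift = spec.true_drift_rate * t_days / DAYS_PER_YEAR

    frames = []
    for i in range(spec.n_implants):
        noise = rng.normal(0.0, spec.noise_sd, size=n_t) if spec.noise_sd > 0 else np.zeros(n_t)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": _EPOCH + pd.to_timedelta(t_days, unit="D"),
                    "implant_id": f"imp{i + 1:02d}",
                    "implant_abs_pressure_mmhg": baro + head_mmhg + drift + noise,
                    "barometer_mmhg": baro,
                    "head_cm": spec.head_height_cm,
                    "temperature_c": spec.temperature_c,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[list(DRIFT_LOG_COLUMNS)]


@dataclass(frozen=True)
class IcpSimSpec:
    """Synthetic home ICP reading.

    pulse_amp is the *peak-to-trough* cardiac amplitude in mmHg;
    resp_amp likewise for the respiratory component.  posture_schedule
    is a list of (start_s, posture_label, mean_offset_mmHg) step changes
    with no transient.  harmonics adds the given relative amplitudes at
    2f, 3f, ... of the cardiac tone (off by default).
    """

    duration_s: float = 30.0
    fs: float = 50.0
    mean_icp: float = 10.0
    pulse_amp: float = 2.0  # mmHg peak-to-trough
    heart_rate: float = 70.0  # beats/min
    resp_amp: float = 0.5  # mmHg peak-to-trough
    resp_rate: float = 15.0  # breaths/min
    noise_sd: float = 0.2  # mmHg
    posture_schedule: tuple = ()
    harmonics: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.pulse_amp < 0 or self.resp_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be >= 0")
        f_cardiac = self.heart_rate / 60.0
        if self.fs <= 2.0 * f_cardiac:
            raise ValueError(
                f"fs = {self.fs} Hz cannot resolve a {self.heart_rate} bpm cardiac tone "
                f"({f_cardiac:.2f} Hz): need fs > {2 * f_cardiac:.2f} Hz"
            )


def gen_icp(spec: IcpSimSpec) -> IcpRecording:
    """Synthetic ICP recording with known cardiac amplitude.

    With zero noise and zero respiration the peak-to-trough excursion of
    any whole beat is exactly ``pulse_amp``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    f_c = spec.heart_rate / 60.0
    cardiac = 0.5 * spec.pulse_amp * np.sin(2 * np.pi * f_c * t)
    for k, rel in enumerate(spec.harmonics, start=2):
        cardiac += 0.5 * spec.pulse_amp * rel * np.sin(2 * np.pi * k * f_c * t)
    resp = 0.5 * spec.resp_amp * np.sin(2 * np.pi * spec.resp_rate / 60.0 * t)

    offset = np.zeros(n)
    label = "unspecified"
    for start_s, posture, off in sorted(spec.posture_schedule, key=lambda e: e[0]):
        offset[t >= start_s] = off
        label = posture if label in ("unspecified", posture) else "mixed"

    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    samples = spec.mean_icp + offset + cardiac + resp + noise
    return IcpRecording(samples=samples, fs=spec.fs, posture=label)


def gen_accuracy_grid(
    pressure_range: tuple[float, float] = (475.0, 950.0),
    temp_range: tuple[float, float] = (35.0, 45.0),
    n_pressure: int = 22,
    n_temp: int = 21,
    error_model=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full-factorial accuracy grid with an injected error model.

    Default 22 x 21 = 462 cells spanning 475-950 mmHg absolute and
    35-45 degC.  ``error_model(set_p, set_t, rng) -> (dp, dt)`` returns the
    injected pressure/temperature reading errors (arrays); ``None``
    injects none.
    """
    if pressure_range[0] >= pressure_range[1] or temp_range[0] >= temp_range[1]:
        raise ValueError("ranges must be ordered (lo, hi)")
    if n_pressure < 2 or n_temp < 2:
        raise ValueError("need at least 2 points per condition axis")
    rng = np.random.default_rng(seed)
    p = np.linspace(*pressure_range, n_pressure)
    tc = np.linspace(*temp_range, n_temp)
    P, T = np.meshgrid(p, tc, indexing="ij")
    set_p, set_t = P.ravel(), T.ravel()
    if error_model is None:
        dp = np.zeros_like(set_p)
        dt = np.zeros_like(set_t)
    else:
        dp, dt = error_model(set_p, set_t, rng)
    return pd.DataFrame(
        {
            "set_pressure_mmhg": set_p,
            "set_temp_c": set_t,
            "implant_pressure_mmhg": set_p + dp,
            "implant_temp_c": set_t + dt,
        }
    )
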