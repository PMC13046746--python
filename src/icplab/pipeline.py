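"""End-to-end reproducible runs: config, staging, provenance.

A run executes the requested stages (simulate -> coverage -> sar ->
qualification -> icp) into a self-describing output directory: every run
writes the resolved configuration, a provenance manifest (parameters,
seed, library versions, SHA-256 of every output) and a log file.  Given
the same config and seed, the CSV/JSON outputs are byte-identical.

Configuration is TOML; units are encoded in key names (``spacing_mm``,
``threshold_ut``) to keep unit errors out of the config layer.  Unknown
keys are rejected before any computation.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coverage as cov, icp as icpmod, io as io_mod, qualification as qual, sar as sarmod, synthetic as syn
from .magnetics import CoilSpec

__all__ = ["DEFAULT_CONFIG", "RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "coverage", "sar", "qualification", "icp")

DEFAULT_CONFIG: dict = {
    "run": {
        "stages": list(ALL_STAGES),
        "seed": 1,
        "out_dir": "runs/demo",
        "log_level": "INFO",
    },
    "head": {
        "shape": "ellipsoid",
        "semi_axes_mm": [70.0, 90.0, 80.0],
        "mesh_resolution_mm": 8.0,
    },
    "coverage": {
        "n_poses": 48,
        "spacing_mm": 4.0,
        "threshold_ut": 28.0,
        "standoff_mm": 5.0,
        "coil_radius_m": 0.075,
        "amp_turns": 11.0,
    },
    "sar": {
        "table_csv": "",  # empty -> packaged exposure table
    },
    "aging": {
        "working_c": 39.0,
        "elevated_c": 85.0,
        "q10": 2.0,
        "duty": 162.0 / 168.0,
        "accelerated_weeks": 22.0,
    },
    "drift": {
        "n_implants": 8,
        "duration_weeks": 52.0,
        "read_interval_days": 1.0,
        "true_drift_rate_mmhg_per_year": 0.5,
        "noise_sd_mmhg": 0.1,
        "limit_mmhg": 2.0,
    },
    "accuracy": {
        "error_halfwidth_mmhg": 1.0,
        "error_halfwidth_c": 1.0,
    },
    "icp": {
        "n_readings": 36,
        "duration_days": 90.0,
        "reading_s": 30.0,
        "heart_rate_bpm": 70.0,
        "pulse_amp_mmhg": 2.0,
        "resp_amp_mmhg": 0.5,
        "noise_sd_mmhg": 0.2,
        "mean_icp_mmhg": 10.0,
        "posture_offsets": {"lying": 5.0, "sitting": 0.0, "standing": -10.0},
        "baseline_window_days": 21.0,
        "flag_k": 3.0,
    },
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _merge_checked(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    unknown = [f"{path}{k}" for k in override if k not in defaults]
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    for key, dval in defaults.items():
        oval = override.get(key)
        if isinstance(dval, dict) and oval is not None:
            out[key] = _merge_checked(dval, oval, path=f"{path}{key}.")
        elif oval is not None:
            out[key] = oval
        else:
            out[key] = dval
    return out


class RunConfig:
    """Validated, fully resolved pipeline configuration."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge_checked(DEFAULT_CONFIG, overrides or {})
        bad = [s for s in self.data["run"]["stages"] if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid stages are {list(ALL_STAGES)}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def __getitem__(self, key: str) -> dict:
        return self.data[key]


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, ALL_STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


def _setup_logging(out_dir: Path, level: str) -> None:
    handlers = [logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log", mode="w")]
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None, seed: int | None = None) -> Path:
    """Execute the configured stages; returns the run directory."""
    cfg = config.data
    if seed is not None:
        cfg["run"]["seed"] = int(seed)
    if out_dir is not None:
        cfg["run"]["out_dir"] = str(out_dir)
    run_seed = int(cfg["run"]["seed"])
    out = Path(cfg["run"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, cfg["run"]["log_level"])
    io_mod.write_json(cfg, out / "resolved_config.json")

    artefacts: dict[str, Path] = {}
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in cfg["run"]["stages"]:
            continue
        log.info("running stage %s", stage)
        try:
            runner = globals()[f"_stage_{stage}"]
            artefacts.update(runner(cfg, out, _stage_seed(run_seed, stage), state))
        except Exception as exc:
            _write_manifest(cfg, out, artefacts)
            raise StageError(stage, exc) from exc
    _write_manifest(cfg, out, artefacts)
    return out


def _write_manifest(cfg: dict, out: Path, artefacts: dict[str, Path]) -> None:
    versions = {"icplab": __version__}
    for mod in ("numpy", "scipy", "pandas", "trimesh"):
        versions[mod] = __import__(mod).__version__
    manifest = {
        "seed": cfg["run"]["seed"],
        "stages": cfg["run"]["stages"],
        "versions": versions,
        "outputs": {name: io_mod.sha256_of(p) for name, p in sorted(artefacts.items()) if Path(p).exists()},
    }
    io_mod.write_json(manifest, out / "manifest.json")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, out: Path, seed: int, state: dict) -> dict[str, Path]:
    d = out / "inputs"
    d.mkdir(exist_ok=True)
    art: dict[str, Path] = {}

    head = cfg["head"]
    spec = syn.HeadMeshSpec(
        shape=head["shape"],
        semi_axes=tuple(head["semi_axes_mm"]),
        mesh_resolution=head["mesh_resolution_mm"],
    )
    mesh = syn.gen_head_mesh(spec)
    state["mesh"] = mesh
    art["head_ply"] = io_mod.write_mesh(mesh, d / "head.ply")
    art["head_stl"] = io_mod.write_mesh(mesh, d / "head.stl")

    dr = cfg["drift"]
    drift_df = syn.gen_drift_log(
        syn.DriftSimSpec(
            n_implants=int(dr["n_implants"]),
            duration_weeks=dr["duration_weeks"],
            read_interval=dr["read_interval_days"],
            true_drift_rate=dr["true_drift_rate_mmhg_per_year"],
            noise_sd=dr["noise_sd_mmhg"],
            seed=seed,
        )
    )
    drift_df.to_csv(d / "drift_log.csv", index=False)
    art["drift_log"] = d / "drift_log.csv"

    ac = cfg["accuracy"]

    def uniform_error(set_p, set_t, rng):
        return (
            rng.uniform(-ac["error_halfwidth_mmhg"], ac["error_halfwidth_mmhg"], size=len(set_p)),
            rng.uniform(-ac["error_halfwidth_c"], ac["error_halfwidth_c"], size=len(set_t)),
        )

    grid_df = syn.gen_accuracy_grid(error_model=uniform_error, seed=seed + 1)
    grid_df.to_csv(d / "accuracy_grid.csv", index=False)
    art["accuracy_grid"] = d / "accuracy_grid.csv"

    ic = cfg["icp"]
    rec_dir = d / "icp_readings"
    rec_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed + 2)
    postures = list(ic["posture_offsets"].items())
    times = np.sort(rng.uniform(0.0, ic["duration_days"], size=int(ic["n_readings"])))
    for i, t_day in enumerate(times):
        posture, offset = postures[i % len(postures)]
        rec = syn.gen_icp(
            syn.IcpSimSpec(
                duration_s=ic["reading_s"],
                mean_icp=ic["mean_icp_mmhg"] + offset,
                pulse_amp=ic["pulse_amp_mmhg"],
                heart_rate=ic["heart_rate_bpm"],
                resp_amp=ic["resp_amp_mmhg"],
                noise_sd=ic["noise_sd_mmhg"],
                seed=int(rng.integers(2**31)),
            )
        )
        rec.posture = posture
        rec.patient_id = "sim01"
        rec.start_time = pd.Timestamp("2024-01-01") + pd.Timedelta(days=float(t_day))
        csv_path, _ = io_mod.write_recording(rec, rec_dir / f"reading_{i:03d}.csv")
        art[f"icp_reading_{i:03d}"] = csv_path
    return art


def _stage_coverage(cfg: dict, out: Path, seed: int, state: dict) -> dict[str, Path]:
    d = out / "coverage"
    d.mkdir(exist_ok=True)
    mesh = state.get("mesh")
    if mesh is None:
        mesh = io_mod.read_mesh(out / "inputs" / "head.ply")
    c = cfg["coverage"]
    template = CoilSpec(radius=c["coil_radius_m"], amp_turns=c["amp_turns"])
    cmap = cov.coverage_map(
        mesh,
        coil_template=template,
        n_poses=int(c["n_poses"]),
        spacing=c["spacing_mm"],
        threshold=c["threshold_ut"] * 1e-6,
        standoff_mm=c["standoff_mm"],
        seed=seed,
    )
    state["coverage_map"] = cmap
    art = dict(io_mod.write_volume(cmap, d))
    mid = cmap.grid.dims[0] // 2
    cov.export_slice(cmap, "sagittal", mid, out_png=d / "sagittal_mid.png", out_csv=d / "sagittal_mid.csv")
    art["slice_png"] = d / "sagittal_mid.png"
    art["slice_csv"] = d / "sagittal_mid.csv"
    io_mod.write_json(
        {"summary": cmap.summary(), "class_counts": cmap.class_counts(), "n_poses": len(cmap.pose_set)},
        d / "coverage_summary.json",
    )
    art["coverage_summary"] = d / "coverage_summary.json"
    log.info("%s", cmap.summary())
    return art


def _stage_sar(cfg: dict, out: Path, seed: int, state: dict) -> dict[str, Path]:
    d = out / "sar"
    d.mkdir(exist_ok=True)
    src = cfg["sar"]["table_csv"]
    table = sarmod.load_exposure_table(src) if src else sarmod.builtin_exposure_table()
    report = sarmod.compliance_report(table)
    sarmod.write_report(report, d / "sar_report.json", d / "sar_report.csv")
    return {"sar_report_json": d / "sar_report.json", "sar_report_csv": d / "sar_report.csv"}


def _stage_qualification(cfg: dict, out: Path, seed: int, state: dict) -> dict[str, Path]:
    d = out / "qualification"
    d.mkdir(exist_ok=True)
    art: dict[str, Path] = {}

    ag = cfg["aging"]
    protocol = qual.AgingProtocol(
        working_temp=ag["working_c"], elevated_temp=ag["elevated_c"], q10=ag["q10"], duty=ag["duty"]
    )
    af = qual.acceleration_factor(protocol)
    aging_report = {
        "acceleration_factor": af,
        "acceleration_factor_1dp": round(af, 1),
        "accelerated_weeks": ag["accelerated_weeks"],
        "equivalent_years": qual.equivalent_duration(ag["accelerated_weeks"], protocol),
    }
    art["aging_report"] = io_mod.write_json(aging_report, d / "aging_report.json")

    log_df = io_mod.read_table(out / "inputs" / "drift_log.csv")
    drift_log = qual.DriftLog(log_df)
    results = qual.DriftModel(drift_log).fit()
    qtable = results.qualify(cfg["drift"]["limit_mmhg"])
    qtable.to_csv(d / "drift_qualification.csv")
    art["drift_qualification"] = d / "drift_qualification.csv"
    io_mod.write_json(
        {
            "limit_mmhg": cfg["drift"]["limit_mmhg"],
            "n_implants": int(len(qtable)),
            "n_passed": int(qtable["passed"].sum()),
            "cohort_mean_drift_mmhg_per_year": float(qtable["drift_rate_mmhg_per_year"].mean()),
            "cohort_max_excursion_mmhg": float(qtable["max_excursion_mmhg"].max()),
        },
        d / "drift_summary.json",
    )
    art["drift_summary"] = d / "drift_summary.json"

    grid_df = io_mod.read_table(out / "inputs" / "accuracy_grid.csv")
    report = qual.accuracy_evaluate(grid_df)
    report.cells.to_csv(d / "accuracy_cells.csv", index=False)
    art["accuracy_cells"] = d / "accuracy_cells.csv"
    io_mod.write_json(
        {
            "passed": report.passed,
            "n_measurements": report.n_measurements,
            "pressure_error_mean_mmhg": report.pressure_error_mean,
            "pressure_error_sd_mmhg": report.pressure_error_sd,
            "temp_error_mean_c": report.temp_error_mean,
            "temp_error_sd_c": report.temp_error_sd,
        },
        d / "accuracy_summary.json",
    )
    art["accuracy_summary"] = d / "accuracy_summary.json"
    return art


def _stage_icp(cfg: dict, out: Path, seed: int, state: dict) -> dict[str, Path]:
    d = out / "icp"
    d.mkdir(exist_ok=True)
    rec_dir = out / "inputs" / "icp_readings"
    rows = []
    for csv_path in sorted(rec_dir.glob("reading_*.csv")):
        rec = io_mod.read_recording(csv_path)
        rows.append(icpmod.reading_summary(rec))
    diary = pd.DataFrame(rows)
    diary.to_csv(d / "diary.csv", index=False)

    summary, stability = icpmod.longitudinal_summary(diary, window_days=cfg["icp"]["baseline_window_days"])
    summary.to_csv(d / "longitudinal_summary.csv", index=False)
    flags = icpmod.excursion_flags(
        diary, baseline_window_days=cfg["icp"]["baseline_window_days"], k=cfg["icp"]["flag_k"]
    )
    flags.to_csv(d / "excursion_flags.csv", index=False)
    io_mod.write_json(
        {
            "stability_mmhg": stability,
            "n_readings": int(len(diary)),
            "n_flagged": int(flags["flagged"].sum()),
            "median_pulse_amplitude_mmhg": float(diary["pulse_amplitude_mmhg"].median()),
        },
        d / "icp_summary.json",
    )
    return {
        "icp_diary": d / "diary.csv",
        "icp_longitudinal": d / "longitudinal_summary.csv",
        "icp_flags": d / "excursion_flags.csv",
        "icp_summary": d / "icp_summary.json",
    }
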