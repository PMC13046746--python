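"""Readers and writers for the pipeline's on-disk formats.

Meshes: STL/PLY/OBJ via trimesh (ASCII dialects are the canonical
fixture format).  Volumes: NIfTI (via nibabel) carrying the worst/best
field in tesla and the class labels, plus a JSON sidecar with the grid
metadata.  Tables: CSV with a header row, ISO-8601 timestamps, mmHg and
degC; schema violations are reported by column name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .coverage import CoverageMap, VoxelGrid
from .icp import IcpRecording

__all__ = [
    "read_mesh",
    "write_mesh",
    "write_volume",
    "read_volume",
    "read_table",
    "write_json",
    "read_recording",
    "write_recording",
    "sha256_of",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a triangulated surface mesh (STL/PLY/OBJ)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mesh = trimesh.load(path, force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path}: no triangulated surface found")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path, ascii_dialect: bool = True) -> Path:
    """Write a mesh as STL or PLY (ASCII by default, binary otherwise)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        data = mesh.export(file_type="ply", encoding="ascii" if ascii_dialect else "binary")
    elif suffix == ".stl":
        data = mesh.export(file_type="stl_ascii" if ascii_dialect else "stl")
    elif suffix == ".obj":
        data = mesh.export(file_type="obj")
    else:
        raise ValueError(f"unsupported mesh format {suffix!r} (use .stl/.ply/.obj)")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def _grid_affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= grid.spacing
    aff[:3, 3] = grid.origin + 0.5 * grid.spacing  # centre-of-voxel convention
    return aff


def write_volume(cmap: CoverageMap, out_dir: str | Path, stem: str = "coverage") -> dict[str, Path]:
    """Write W/M (tesla, float32) and class labels (uint8) as NIfTI + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _grid_affine(cmap.grid)
    paths = {}
    for name, arr, dtype in (
        ("worst_case_t", cmap.W, np.float32),
        ("best_case_t", cmap.M, np.float32),
        ("class", cmap.classes, np.uint8),
    ):
        p = out_dir / f"{stem}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), p)
        paths[name] = p
    sidecar = {
        "origin_mm": list(map(float, cmap.grid.origin)),
        "spacing_mm": cmap.grid.spacing,
        "dims": list(cmap.grid.dims),
        "threshold_t": cmap.threshold,
        "n_poses": len(cmap.pose_set),
        "n_poses_requested": cmap.pose_set.n_requested,
        "standoff_mm": cmap.pose_set.standoff_mm,
        "class_counts": cmap.class_counts(),
        "class_labels": {"0": "always_powered", "1": "orientation_dependent", "2": "unreachable", "255": "outside"},
    }
    p = out_dir / f"{stem}_grid.json"
    write_json(sidecar, p)
    paths["sidecar"] = p
    return paths


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume back as (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def read_table(path: str | Path, required: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a CSV table, enforcing required columns and dtypes.

    ``required`` maps column name -> dtype the column must coerce to;
    failures name the column (and the first offending row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {missing}")
        for col, dtype in required.items():
            try:
                df[col] = df[col].astype(dtype)
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()[:5]
                raise SchemaError(
                    f"{path}: column {col!r} not coercible to {dtype.__name__}"
                    + (f" (first bad row(s): {bad})" if bad else "")
                ) from exc
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def write_recording(rec: IcpRecording, csv_path: str | Path) -> tuple[Path, Path]:
    """Write one ICP recording as CSV (timestamp, mmHg) + JSON sidecar."""
    csv_path = Path(csv_path)
    t = rec.start_time + pd.to_timedelta(np.arange(len(rec.samples)) / rec.fs, unit="s")
    pd.DataFrame({"timestamp": t.strftime("%Y-%m-%dT%H:%M:%S.%f"), "icp_mmhg": rec.samples}).to_csv(
        csv_path, index=False
    )
    sidecar = csv_path.with_suffix(".json")
    write_json(
        {
            "fs_hz": rec.fs,
            "posture": rec.posture,
            "patient_id": rec.patient_id,
            "start_time": str(rec.start_time),
            "n_samples": len(rec.samples),
        },
        sidecar,
    )
    return csv_path, sidecar


def read_recording(csv_path: str | Path) -> IcpRecording:
    """Read an ICP recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    df = read_table(csv_path, required={"icp_mmhg": float})
    sidecar = csv_path.with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text()) if sidecar.exists() else {}
    return IcpRecording(
        samples=df["icp_mmhg"].to_numpy(),
        fs=float(meta.get("fs_hz", 50.0)),
        start_time=pd.Timestamp(meta.get("start_time", "2024-01-01T00:00:00")),
        posture=meta.get("posture", "unspecified"),
        patient_id=meta.get("patient_id", ""),
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
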