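"""IEEE C95.1 duty-cycle arithmetic for wand SAR exposure.

The electromagnetic SAR values themselves come from an external
quasistatic field solver; this module applies the regulatory
time-averaging on top of those printed scalars.  IEEE C95.1 averages the
peak spatial-average SAR (psSAR, any 10 g of tissue, limit 2 W/kg) over a
6-minute window and the whole-body absorbed power (limit 0.08 W/kg) over
a 30-minute window.  A wand measurement is a single exposure of at most
120 s per window, so the averaged quantities are simple duty-cycle
scalings of the continuous values.

All operations are pure closed forms; rounding happens only in the
reporting layer (2 decimals for W/kg, nearest 0.05 kg for mass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PSAR_LIMIT_WKG",
    "WB_LIMIT_WKG",
    "PSAR_WINDOW_S",
    "WB_WINDOW_S",
    "DEVICE_MAX_MEASUREMENT_S",
    "SarExposure",
    "MeasurementTimeBound",
    "psar_time_average",
    "min_safe_mass",
    "max_measurement_time",
    "compliance_report",
    "load_exposure_table",
    "builtin_exposure_table",
]

PSAR_LIMIT_WKG = 2.0  # peak spatial-average SAR limit, any 10 g
WB_LIMIT_WKG = 0.08  # whole-body SAR limit
PSAR_WINDOW_S = 360.0  # 6-minute psSAR averaging window
WB_WINDOW_S = 1800.0  # 30-minute whole-body averaging window
DEVICE_MAX_MEASUREMENT_S = 120.0  # longest exposure the wand allows

REQUIRED_COLUMNS = ("model_name", "psar_continuous_wkg", "absorbed_power_w", "measurement_s")


@dataclass(frozen=True)
class SarExposure:
    """One continuous-exposure scenario for a body model.

    ``psar_continuous`` is the continuous-wave peak spatial-average SAR in
    W/kg and ``absorbed_power`` the whole-body absorbed power in W, both
    as printed by the field solver.  ``measurement_s`` is the duration of
    the single measurement within the averaging windows (device maximum
    120 s).  ``body_mass`` (kg) is optional and only needed for the
    measurement-time bound.
    """

    psar_continuous: float
    absorbed_power: float
    measurement_s: float = DEVICE_MAX_MEASUREMENT_S
    body_mass: float | None = None
    psar_window_s: float = PSAR_WINDOW_S
    wb_window_s: float = WB_WINDOW_S
    psar_limit: float = PSAR_LIMIT_WKG
    wb_limit: float = WB_LIMIT_WKG
    model_name: str = ""

    def __post_init__(self):
        if self.psar_continuous < 0 or self.absorbed_power < 0:
            raise ValueError("powers must be >= 0")
        if self.measurement_s < 0:
            raise ValueError("measurement_s must be >= 0")
        if self.psar_window_s <= 0 or self.wb_window_s <= 0:
            raise ValueError("averaging windows must be > 0")
        if self.body_mass is not None and self.body_mass < 0:
            raise ValueError("body_mass must be >= 0")


def psar_time_average(exposure: SarExposure) -> float:
    """psSAR averaged over the 6-minute window, W/kg.

    A single exposure of ``measurement_s`` seconds inside the window
    contributes with duty factor min(measurement_s, window)/window.
    """
    duty = min(exposure.measurement_s, exposure.psar_window_s) / exposure.psar_window_s
    return exposure.psar_continuous * duty


def min_safe_mass(exposure: SarExposure) -> float:
    """Smallest body mass (kg) for which the whole-body limit is met.

    Whole-body SAR is absorbed power / mass averaged over the 30-minute
    window, so mass >= P * min(t, window)/window / limit.
    """
    duty = min(exposure.measurement_s, exposure.wb_window_s) / exposure.wb_window_s
    return exposure.absorbed_power * duty / exposure.wb_limit


@dataclass(frozen=True)
class MeasurementTimeBound:
    """Whole-body measurement-time bound for a given body mass."""

    raw_bound_s: float  # limit * mass * window / power, uncapped
    bound_s: float  # capped at the averaging window
    unconstrained_within_window: bool  # the cap bound
    device_bound_s: float  # additionally capped at the 120 s device maximum


def max_measurement_time(exposure: SarExposure) -> MeasurementTimeBound:
    """Longest single measurement (s) keeping whole-body SAR within limit."""
    if exposure.body_mass is None or exposure.body_mass <= 0:
        if exposure.body_mass is None:
            raise ValueError("max_measurement_time requires body_mass")
        return MeasurementTimeBound(0.0, 0.0, False, 0.0)
    if exposure.absorbed_power == 0:
        return MeasurementTimeBound(
            float("inf"), exposure.wb_window_s, True, DEVICE_MAX_MEASUREMENT_S
        )
    raw = exposure.wb_limit * exposure.body_mass * exposure.wb_window_s / exposure.absorbed_power
    capped = min(raw, exposure.wb_window_s)
    return MeasurementTimeBound(
        raw_bound_s=raw,
        bound_s=capped,
        unconstrained_within_window=raw >= exposure.wb_window_s,
        device_bound_s=min(capped, DEVICE_MAX_MEASUREMENT_S),
    )


def _round_mass(kg: float) -> float:
    return round(round(kg / 0.05) * 0.05, 2)


def compliance_report(table: pd.DataFrame) -> dict:
    """Per-row IEEE C95.1 compliance report for an exposure table.

    Expects columns ``model_name, psar_continuous_wkg, absorbed_power_w,
    measurement_s`` and optionally ``body_mass_kg``.  Malformed rows are
    reported by index under ``row_errors`` and excluded; an empty table
    yields an empty report.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"exposure table missing required column(s): {missing}")

    rows: list[dict] = []
    row_errors: dict[int, str] = {}
    for idx, rec in table.iterrows():
        try:
            mass = rec.get("body_mass_kg")
            mass = None if mass is None or pd.isna(mass) else float(mass)
            exp = SarExposure(
                psar_continuous=float(rec["psar_continuous_wkg"]),
                absorbed_power=float(rec["absorbed_power_w"]),
                measurement_s=float(rec["measurement_s"]),
                body_mass=mass,
                model_name=str(rec["model_name"]),
            )
        except (ValueError, TypeError) as exc:
            row_errors[int(idx)] = str(exc)
            continue

        psar_avg = psar_time_average(exp)
        mass_bound = min_safe_mass(exp)
        row = {
            "model_name": exp.model_name,
            "psar_continuous_wkg": exp.psar_continuous,
            "psar_avg_wkg": round(psar_avg, 2),
            "psar_pass": bool(psar_avg < exp.psar_limit),
            "absorbed_power_w": exp.absorbed_power,
            "min_safe_mass_kg": _round_mass(mass_bound),
        }
        if exp.body_mass is not None and exp.body_mass > 0:
            bound = max_measurement_time(exp)
            wb_avg = (
                exp.absorbed_power
                * min(exp.measurement_s, exp.wb_window_s)
                / exp.wb_window_s
                / exp.body_mass
            )
            row.update(
                body_mass_kg=exp.body_mass,
                wb_sar_avg_wkg=round(wb_avg, 4),
                wb_pass=bool(wb_avg < exp.wb_limit),
                max_measurement_s=round(bound.device_bound_s, 1),
                unconstrained_within_window=bound.unconstrained_within_window,
            )
        rows.append(row)

    return {
        "psar_limit_wkg": PSAR_LIMIT_WKG,
        "wb_limit_wkg": WB_LIMIT_WKG,
        "rows": rows,
        "row_errors": row_errors,
        "all_pass": all(
            r["psar_pass"] and r.get("wb_pass", True) for r in rows
        ),
    }


def write_report(report: dict, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    """Write a compliance report as JSON (and optionally per-row CSV)."""
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    if csv_path is not None:
        pd.DataFrame(report["rows"]).to_csv(csv_path, index=False)


def load_exposure_table(path: str | Path) -> pd.DataFrame:
    """Read an exposure CSV, checking required columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return df


def builtin_exposure_table() -> pd.DataFrame:
    """The packaged three-model exposure table (adult + two paediatric).

    Continuous psSAR and whole-body absorbed power for the 15 cm, 11 AT RMS
    wand coil against the three anatomical body models, as produced by the
    external field solver.  Columns are identified by position in the
    source table, not by model age.
    """
    with resources.as_file(resources.files("icplab.data") / "sar_exposures.csv") as p:
        return load_exposure_table(p)
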