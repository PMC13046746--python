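"""Sensor qualification: accuracy grids, zero-point drift, accelerated aging.

The implant reports absolute pressure; on the drift rig the reference is
an adjacent calibrated barometer plus a fixed fluid head of buffered
saline (1 cm of fluid = 0.73559 mmHg).  The zero-point error of a reading
is implant pressure minus that reference; a drift *series* re-zeroes the
error at the first reading so only change over time remains.

Accelerated aging uses the Q10 shortcut to the Arrhenius law
(rate doubles per 10 degC when Q10 = 2) with a duty factor for the time the
parts actually spend at the elevated temperature, following the
standardised medical-device accelerated-aging practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CM_FLUID_TO_MMHG",
    "DAYS_PER_YEAR",
    "AgingProtocol",
    "ToleranceSpec",
    "DriftLog",
    "DriftQualification",
    "DriftModel",
    "DriftResults",
    "AccuracyReport",
    "zero_point_error",
    "zero_point_series",
    "drift_qualify",
    "acceleration_factor",
    "equivalent_duration",
    "real_duration_for",
    "accuracy_evaluate",
]

#: pressure of 1 cm of pH 7.4 phosphate-buffered saline, mmHg/cm (used verbatim)
CM_FLUID_TO_MMHG = 0.73559

DAYS_PER_YEAR = 365.25

#: drift-log schema (CSV header names)
DRIFT_LOG_COLUMNS = (
    "timestamp",
    "implant_id",
    "implant_abs_pressure_mmhg",
    "barometer_mmhg",
    "head_cm",
    "temperature_c",
)

PLAUSIBLE_PRESSURE_MMHG = (400.0, 1000.0)


@dataclass(frozen=True)
class AgingProtocol:
    """Accelerated-aging protocol parameters.

    working_temp/elevated_temp in degC; q10 is the reaction-rate
    coefficient (rate multiplier per 10 degC); duty the fraction of the
    cycle actually spent at the elevated temperature (default 162 of 168
    hours per week, i.e. 96%).
    """

    working_temp: float = 39.0
    elevated_temp: float = 85.0
    q10: float = 2.0
    duty: float = 162.0 / 168.0

    def __post_init__(self):
        if self.q10 <= 1:
            raise ValueError(f"q10 must be > 1, got {self.q10}")
        if not 0 < self.duty <= 1:
            raise ValueError(f"duty must be in (0, 1], got {self.duty}")
        if self.elevated_temp < self.working_temp:
            raise ValueError("elevated_temp must be >= working_temp")


@dataclass(frozen=True)
class ToleranceSpec:
    """Accuracy acceptance band (pressure/temperature monitoring standard)."""

    pressure_tol: float = 2.0  # +- mmHg
    temp_tol: float = 2.0  # +- degC
    pressure_range: tuple[float, float] = (475.0, 950.0)  # mmHg absolute
    temp_range: tuple[float, float] = (35.0, 45.0)  # degC

    def __post_init__(self):
        if self.pressure_tol <= 0 or self.temp_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.pressure_range[0] >= self.pressure_range[1]:
            raise ValueError("pressure_range must be ordered (lo, hi)")
        if self.temp_range[0] >= self.temp_range[1]:
            raise ValueError("temp_range must be ordered (lo, hi)")


def acceleration_factor(protocol: AgingProtocol = AgingProtocol()) -> float:
    """Q10 Arrhenius acceleration factor, including the duty factor.

    AF = q10 ** ((elevated - working) / 10) * duty.  With the defaults
    (Q10 = 2, 39 -> 85 degC, duty 162/168) this is 23.385..., i.e. 23.4 to
    one decimal.
    """
    dT = protocol.elevated_temp - protocol.working_temp
    return protocol.q10 ** (dT / 10.0) * protocol.duty


def equivalent_duration(real_duration_weeks: float, protocol: AgingProtocol = AgingProtocol()) -> float:
    """Real-time-equivalent years represented by an accelerated test.

    weeks at the elevated condition x AF, converted with a 365.25-day year.
    """
    if real_duration_weeks <= 0:
        raise ValueError("duration must be > 0 weeks")
    return real_duration_weeks * acceleration_factor(protocol) * 7.0 / DAYS_PER_YEAR


def real_duration_for(equivalent_years: float, protocol: AgingProtocol = AgingProtocol()) -> float:
    """Inverse of :func:`equivalent_duration`: weeks of accelerated test needed."""
    if equivalent_years <= 0:
        raise ValueError("equivalent_years must be > 0")
    return equivalent_years * DAYS_PER_YEAR / 7.0 / acceleration_factor(protocol)


# ---------------------------------------------------------------------------
# zero-point drift
# ---------------------------------------------------------------------------


class DriftLog:
    """Validated drift-rig log.

    Wraps a DataFrame with columns ``timestamp, implant_id,
    implant_abs_pressure_mmhg, barometer_mmhg, head_cm, temperature_c``.
    Timestamps must be non-decreasing per implant and pressures within a
    plausible absolute range.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in DRIFT_LOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"drift log missing column(s): {missing}")
        df = df.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        if df["barometer_mmhg"].isna().any():
            bad = df.index[df["barometer_mmhg"].isna()].tolist()
            raise ValueError(f"missing barometer reading at row(s) {bad}; refusing to assume a default")
        lo, hi = PLAUSIBLE_PRESSURE_MMHG
        for col in ("implant_abs_pressure_mmhg", "barometer_mmhg"):
            bad = df.index[(df[col] < lo) | (df[col] > hi)].tolist()
            if bad:
                raise ValueError(f"{col} outside plausible range [{lo}, {hi}] mmHg at row(s) {bad[:10]}")
        for iid, grp in df.groupby("implant_id"):
            if not grp["timestamp"].is_monotonic_increasing:
                raise ValueError(f"timestamps not non-decreasing for implant {iid!r}")
        self.df = df

    @classmethod
    def from_csv(cls, path) -> "DriftLog":
        return cls(pd.read_csv(path))

    @property
    def implant_ids(self) -> list[str]:
        return sorted(self.df["implant_id"].unique().tolist())


def zero_point_error(implant_abs_pressure, barometer, head_cm):
    """Zero-point error, mmHg: implant absolute minus (barometer + fluid head)."""
    implant = np.asarray(implant_abs_pressure, dtype=float)
    baro = np.asarray(barometer, dtype=float)
    if np.any(np.isnan(baro)):
        raise ValueError("missing barometer reading; refusing to assume a default")
    return implant - (baro + np.asarray(head_cm, dtype=float) * CM_FLUID_TO_MMHG)


def zero_point_series(log: DriftLog, implant_id: str) -> pd.Series:
    """Zero-point drift series for one implant, re-zeroed at the first reading."""
    grp = log.df[log.df["implant_id"] == implant_id]
    if grp.empty:
        raise KeyError(f"unknown implant_id {implant_id!r}; have {log.implant_ids}")
    err = zero_point_error(
        grp["implant_abs_pressure_mmhg"].to_numpy(),
        grp["barometer_mmhg"].to_numpy(),
        grp["head_cm"].to_numpy(),
    )
    series = pd.Series(err - err[0], index=grp["timestamp"].to_numpy(), name=implant_id)
    return series


@dataclass(frozen=True)
class DriftQualification:
    passed: bool
    max_excursion_mmhg: float
    excursion_time: object
    limit_mmhg: float


def drift_qualify(series: pd.Series, limit_mmhg: float) -> DriftQualification:
    """Pass/fail a zero-point series against a drift limit (max |excursion|)."""
    if len(series) == 0:
        raise ValueError("empty zero-point series")
    excursions = series.abs()
    imax = excursions.to_numpy().argmax()
    max_exc = float(excursions.iloc[imax])
    return DriftQualification(
        passed=max_exc < limit_mmhg,
        max_excursion_mmhg=max_exc,
        excursion_time=series.index[imax],
        limit_mmhg=limit_mmhg,
    )


class DriftModel:
    """Linear zero-point drift model for a cohort of implants.

    ``fit()`` estimates a per-implant drift rate (mmHg/year) by ordinary
    least squares on the re-zeroed series against elapsed time.
    """

    def __init__(self, log: DriftLog):
        self.log = log

    def fit(self) -> "DriftResults":
        rows = []
        series = {}
        for iid in self.log.implant_ids:
            s = zero_point_series(self.log, iid)
            series[iid] = s
            t_years = (s.index - s.index[0]) / pd.Timedelta(days=DAYS_PER_YEAR)
            if len(s) >= 3 and np.ptp(t_years) > 0:
                res = stats.linregress(np.asarray(t_years, dtype=float), s.to_numpy())
                slope, stderr, intercept = res.slope, res.stderr, res.intercept
            else:
                slope, stderr, intercept = np.nan, np.nan, np.nan
            rows.append(
                {
                    "implant_id": iid,
                    "n_readings": len(s),
                    "drift_rate_mmhg_per_year": slope,
                    "drift_rate_se": stderr,
                    "intercept_mmhg": intercept,
                    "max_excursion_mmhg": float(s.abs().max()),
                }
            )
        return DriftResults(pd.DataFrame(rows).set_index("implant_id"), series)


class DriftResults:
    """Per-implant drift estimates and cohort qualification."""

    def __init__(self, table: pd.DataFrame, series: dict[str, pd.Series]):
        self.table = table
        self.series = series

    def qualify(self, limit_mmhg: float) -> pd.DataFrame:
        out = self.table.copy()
        out["passed"] = out["max_excursion_mmhg"] < limit_mmhg
        out["limit_mmhg"] = limit_mmhg
        return out

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Zero-point drift fit ({len(t)} implants)",
            f"  cohort mean drift rate: {t['drift_rate_mmhg_per_year'].mean():+.3f} mmHg/yr",
            f"  cohort max |excursion|: {t['max_excursion_mmhg'].max():.3f} mmHg",
        ]
        for iid, row in t.iterrows():
            lines.append(
                f"  {iid}: {row['drift_rate_mmhg_per_year']:+.3f} "
                f"+- {row['drift_rate_se']:.3f} mmHg/yr, "
                f"max excursion {row['max_excursion_mmhg']:.3f} mmHg"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# accuracy grid
# ---------------------------------------------------------------------------


@dataclass
class AccuracyReport:
    passed: bool
    coverage_ok: bool
    cells: pd.DataFrame  # per-cell errors and in/out of tolerance
    pressure_error_mean: float
    pressure_error_sd: float
    temp_error_mean: float
    temp_error_sd: float
    n_measurements: int
    tolerance: ToleranceSpec

    def summary(self) -> str:
        return (
            f"Accuracy grid: N={self.n_measurements} measurements, "
            f"pressure error {self.pressure_error_mean:+.3f} +- {self.pressure_error_sd:.3f} mmHg, "
            f"temperature error {self.temp_error_mean:+.3f} +- {self.temp_error_sd:.3f} degC, "
            f"{'PASS' if self.passed else 'FAIL'} "
            f"(+-{self.tolerance.pressure_tol} mmHg / +-{self.tolerance.temp_tol} degC)"
        )


class GridCoverageError(ValueError):
    """The accuracy grid does not span the required condition ranges."""


def accuracy_evaluate(grid: pd.DataFrame, tol: ToleranceSpec = ToleranceSpec()) -> AccuracyReport:
    """Evaluate an accuracy grid against the tolerance band.

    ``grid`` needs columns ``set_pressure_mmhg, set_temp_c,
    implant_pressure_mmhg, implant_temp_c``.  A grid that does not span
    the required ranges raises :class:`GridCoverageError` — a coverage
    failure, deliberately distinct from a tolerance failure.
    """
    required = ["set_pressure_mmhg", "set_temp_c", "implant_pressure_mmhg", "implant_temp_c"]
    missing = [c for c in required if c not in grid.columns]
    if missing:
        raise ValueError(f"accuracy grid missing column(s): {missing}")

    span_tol = 1e-9
    p_lo, p_hi = grid["set_pressure_mmhg"].min(), grid["set_pressure_mmhg"].max()
    t_lo, t_hi = grid["set_temp_c"].min(), grid["set_temp_c"].max()
    coverage_ok = (
        p_lo <= tol.pressure_range[0] + span_tol
        and p_hi >= tol.pressure_range[1] - span_tol
        and t_lo <= tol.temp_range[0] + span_tol
        and t_hi >= tol.temp_range[1] - span_tol
    )
    if not coverage_ok:
        raise GridCoverageError(
            f"grid spans [{p_lo}, {p_hi}] mmHg x [{t_lo}, {t_hi}] degC but the "
            f"tolerance ranges {tol.pressure_range} mmHg x {tol.temp_range} degC must be covered"
        )

    cells = grid.copy()
    cells["pressure_error_mmhg"] = cells["implant_pressure_mmhg"] - cells["set_pressure_mmhg"]
    cells["temp_error_c"] = cells["implant_temp_c"] - cells["set_temp_c"]
    cells["pressure_ok"] = cells["pressure_error_mmhg"].abs() <= tol.pressure_tol
    cells["temp_ok"] = cells["temp_error_c"].abs() <= tol.temp_tol
    passed = bool(cells["pressure_ok"].all() and cells["temp_ok"].all())
    return AccuracyReport(
        passed=passed,
        coverage_ok=True,
        cells=cells,
        pressure_error_mean=float(cells["pressure_error_mmhg"].mean()),
        pressure_error_sd=float(cells["pressure_error_mmhg"].std(ddof=1)),
        temp_error_mean=float(cells["temp_error_c"].mean()),
        temp_error_sd=float(cells["temp_error_c"].std(ddof=1)),
        n_measurements=len(cells),
        tolerance=tol,
    )
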