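"""Quasistatic magnetic field of a circular current-carrying coil.

The external power wand is modelled as a single circular filament with
lumped amp-turns: the winding cross-section is ignored and only the coil
diameter and the RMS ampere-turns enter the model.  The field of an ideal
circular filament has a closed form in terms of the complete elliptic
integrals K and E; that closed form is evaluated here, so the result is
exact (to floating point) everywhere off the filament.

All geometry is SI: positions in metres, field in tesla.  Because the
drive current is specified as an RMS value, the returned field is the RMS
field amplitude — no time-domain waveform is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe, ellipk

__all__ = ["MU0", "CoilSpec", "SingularPointError", "coil_field", "field_batch"]

MU0 = 4e-7 * np.pi
"""Vacuum permeability, T·m/A."""

#: points closer than this to the filament circle raise SingularPointError
FILAMENT_EXCLUSION_M = 1e-6


class SingularPointError(ValueError):
    """Raised when a field evaluation point lies (numerically) on the filament."""

    def __init__(self, indices: np.ndarray):
        self.indices = np.atleast_1d(indices)
        super().__init__(
            f"field requested on or within {FILAMENT_EXCLUSION_M} m of the coil "
            f"filament at point index/indices {self.indices.tolist()}"
        )


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class CoilSpec:
    """A circular filament coil.

    Parameters
    ----------
    center : (3,) array-like, metres
        Centre of the coil circle.
    axis : (3,) array-like
        Normal of the coil plane; normalised on construction.
    radius : float, metres
        Filament radius.  Default 0.075 m (15 cm diameter wand coil).
    amp_turns : float, A·turns RMS
        Lumped drive strength N·I.  Default 11 AT RMS, the wand maximum.
    """

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius: float = 0.075
    amp_turns: float = 11.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"coil radius must be > 0, got {self.radius}")
        if self.amp_turns < 0:
            raise ValueError(f"amp_turns must be >= 0, got {self.amp_turns}")
        object.__setattr__(self, "center", tuple(np.asarray(self.center, dtype=float)))
        object.__setattr__(self, "axis", tuple(_unit(self.axis)))

    def frame(self) -> np.ndarray:
        """Orthonormal frame (3x3, rows e1, e2, axis) with the coil axis last."""
        ez = np.asarray(self.axis)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(ez @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = _unit(np.cross(helper, ez))
        e2 = np.cross(ez, e1)
        return np.vstack([e1, e2, ez])

    def rim_points(self, n: int = 16) -> np.ndarray:
        """n points on the filament circle, shape (n, 3)."""
        phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        f = self.frame()
        return (
            np.asarray(self.center)
            + self.radius * np.outer(np.cos(phi), f[0])
            + self.radius * np.outer(np.sin(phi), f[1])
        )


def field_batch(coil: CoilSpec, points: np.ndarray) -> np.ndarray:
    """RMS B-field of *coil* at many points, shape (n, 3), tesla.

    Closed-form filament field (elliptic integrals), vectorised over
    points.  Raises :class:`SingularPointError` naming the offending
    indices if any point lies on the filament circle.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3), got {pts.shape}")

    frame = coil.frame()
    local = (pts - np.asarray(coil.center)) @ frame.T
    rho = np.hypot(local[:, 0], local[:, 1])
    z = local[:, 2]
    R = coil.radius
    current = coil.amp_turns

    # distance to the filament circle
    d_fil = np.hypot(rho - R, z)
    bad = d_fil < FILAMENT_EXCLUSION_M
    if np.any(bad):
        raise SingularPointError(np.flatnonzero(bad))

    alpha2 = R * R + rho * rho + z * z - 2 * R * rho
    beta2 = R * R + rho * rho + z * z + 2 * R * rho
    beta = np.sqrt(beta2)
    m = 4 * R * rho / beta2  # elliptic parameter k^2
    K = ellipk(m)
    E = ellipe(m)
    C = MU0 * current / np.pi

    Bz = C / (2 * alpha2 * beta) * ((R * R - rho * rho - z * z) * E + alpha2 * K)
    with np.errstate(invalid="ignore", divide="ignore"):
        Brho = (
            C
            * z
            / (2 * alpha2 * beta * rho)
            * ((R * R + rho * rho + z * z) * E - alpha2 * K)
        )
    on_axis = rho < 1e-12 * max(R, 1.0)
    Brho = np.where(on_axis, 0.0, Brho)

    # back to world frame: B = Brho * rho_hat + Bz * axis
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = np.where(on_axis, 1.0, local[:, 0] / np.where(on_axis, 1.0, rho))
        sinphi = np.where(on_axis, 0.0, local[:, 1] / np.where(on_axis, 1.0, rho))
    B_local = np.column_stack([Brho * cosphi, Brho * sinphi, Bz])
    return B_local @ frame


def coil_field(coil: CoilSpec, point: np.ndarray) -> np.ndarray:
    """RMS B-field vector (tesla) of *coil* at a single point (metres)."""
    return field_batch(coil, np.asarray(point, dtype=float).reshape(1, 3))[0]
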