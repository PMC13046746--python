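"""Worst-case wireless-power coverage mapping inside a head mesh.

The implant can harvest power when the component of the wand's magnetic
field along its coil normal ``a`` exceeds a bench-measured threshold
(28 uT RMS when ideally oriented).  The operator may move the wand, so
the field available at a point is the *best over wand poses*; the
implant orientation is unknown, so the worst case is the *minimum over
orientations* of that best value:

    W(x) = min_{|a|=1}  max_p  |B_p(x) . a|        (worst case)
    M(x) =              max_p  |B_p(x)|            (ideal orientation)

Each voxel of a 1 mm rectilinear grid inside the head is classified as
always powered (W >= threshold), orientation dependent (M >= threshold >
W) or unreachable (M < threshold).

The minimax over ``a`` is solved by dense unit-sphere sampling (icosphere
subdivision, 2562 directions) followed by a shrinking pattern-search
refinement; an exact rank shortcut handles <= 2 poses, where an
orientation orthogonal to every field exists and W = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import least_squares

from .geometry import closest_surface, grid_inside_mask, ray_mesh_hits, surface_distance
from .magnetics import CoilSpec, field_batch

__all__ = [
    "DEFAULT_THRESHOLD_T",
    "CLASS_NAMES",
    "VoxelGrid",
    "WandPoseSet",
    "CoverageMap",
    "voxelize",
    "place_wand_poses",
    "worst_case_field",
    "best_case_field",
    "coverage_map",
    "export_slice",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_T = 2.8e-5  # 28 uT RMS minimum powering field, ideally oriented

CLASS_ALWAYS = 0
CLASS_ORIENTATION = 1
CLASS_UNREACHABLE = 2
CLASS_OUTSIDE = 255
CLASS_NAMES = {
    CLASS_ALWAYS: "always_powered",
    CLASS_ORIENTATION: "orientation_dependent",
    CLASS_UNREACHABLE: "unreachable",
    CLASS_OUTSIDE: "outside",
}

MM_PER_M = 1000.0

# minimax solver tuning
_COARSE_SUBDIV = 2  # 162 directions for the per-voxel pre-pass
_FINE_SUBDIV = 4  # 2562 directions, the documented sampling density


@dataclass
class VoxelGrid:
    """Rectilinear voxelization of a head interior (mm units).

    Voxel centres follow the centre-of-voxel convention:
    ``origin + (index + 0.5) * spacing`` with 0-based indices.
    ``inside_mask`` is True only for centres strictly inside the mesh.
    """

    origin: np.ndarray  # (3,) mm, grid corner
    spacing: float  # mm
    dims: tuple[int, int, int]
    inside_mask: np.ndarray  # (nx, ny, nz) bool

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.spacing

    def inside_centers_mm(self) -> np.ndarray:
        idx = np.argwhere(self.inside_mask)
        return self.origin + (idx + 0.5) * self.spacing

    def voxel_volume_mm3(self) -> float:
        return self.spacing**3


def voxelize(mesh: trimesh.Trimesh, spacing: float = 1.0) -> VoxelGrid:
    """Voxelize the strict interior of a watertight mesh at ``spacing`` mm."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not mesh.is_watertight:
        raise ValueError(
            "mesh is not watertight (open boundary or non-manifold edges); "
            "containment is undefined for open surfaces"
        )
    lo, hi = mesh.bounds
    origin = lo - spacing  # one-voxel margin all round
    dims = tuple(int(np.ceil((hi[i] + spacing - origin[i]) / spacing)) for i in range(3))
    centers = [origin[i] + (np.arange(dims[i]) + 0.5) * spacing for i in range(3)]
    mask = grid_inside_mask(mesh, *centers)
    return VoxelGrid(origin=np.asarray(origin, dtype=float), spacing=float(spacing), dims=dims, inside_mask=mask)


# ---------------------------------------------------------------------------
# wand pose placement
# ---------------------------------------------------------------------------


@dataclass
class WandPoseSet:
    """Optimized scalp poses for the wand coil.

    ``poses`` are SI :class:`~icplab.magnetics.CoilSpec` (metres); seed
    directions whose optimization failed are dropped and listed in
    ``dropped`` — never silently substituted.
    """

    poses: list[CoilSpec]
    n_requested: int
    standoff_mm: float
    dropped: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.poses)


def fibonacci_directions(n: int, phase: float = 0.0) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i + phase
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def _rim_mm(center_mm: np.ndarray, axis: np.ndarray, radius_mm: float, n: int = 16) -> np.ndarray:
    e1, e2 = _axis_frame(axis)
    phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return center_mm + radius_mm * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))


def place_wand_poses(
    mesh: trimesh.Trimesh,
    n: int = 720,
    standoff_mm: float = 5.0,
    seed: int = 0,
    coil_template: CoilSpec = CoilSpec(),
    n_rim: int = 16,
) -> WandPoseSet:
    """Optimize ``n`` wand poses resting on the scalp.

    Seed directions are distributed quasi-uniformly around the mesh
    centroid; for each, a nonlinear least-squares search moves the coil
    centre so the coil rim sits as close to ``standoff_mm`` from the
    surface as the geometry allows, with the coil axis along the local
    outward normal.  The axial clearance between coil plane and scalp is
    constrained to at least ``standoff_mm`` (the wand housing thickness),
    and rim penetration is forbidden.  Failed searches are dropped and
    logged.
    """
    if n < 1:
        raise ValueError("need n >= 1 poses")
    if not mesh.is_watertight:
        raise ValueError("mesh must be watertight to place poses")
    rng = np.random.default_rng(seed)
    dirs = fibonacci_directions(n, phase=rng.uniform(0.0, 2 * np.pi))
    centroid = mesh.center_mass
    radius_mm = coil_template.radius * MM_PER_M

    def project(c_param: np.ndarray):
        """Snap a free point to a scalp-contact pose (centre, outward axis).

        The axis uses barycentrically interpolated vertex normals so the
        coil orientation follows the smooth surface, not the facets.
        """
        closest, _, tri_id = closest_surface(mesh, c_param[None, :])
        q = closest[0]
        face = mesh.faces[tri_id[0]]
        tri = mesh.vertices[face]
        # barycentric coordinates of q in its triangle
        v0, v1 = tri[1] - tri[0], tri[2] - tri[0]
        v2 = q - tri[0]
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        det = max(d00 * d11 - d01 * d01, 1e-30)
        wb = (d11 * d20 - d01 * d21) / det
        wc = (d00 * d21 - d01 * d20) / det
        bary = np.clip([1.0 - wb - wc, wb, wc], 0.0, 1.0)
        axis = bary @ mesh.vertex_normals[face]
        axis /= np.linalg.norm(axis)
        center = q + standoff_mm * axis
        return center, axis

    def residuals(c_param: np.ndarray) -> np.ndarray:
        center, axis = project(c_param)
        rim = _rim_mm(center, axis, radius_mm, n_rim)
        return surface_distance(mesh, rim) - standoff_mm

    poses: list[CoilSpec] = []
    dropped: list[int] = []
    for i, u in enumerate(dirs):
        t_hits = ray_mesh_hits(mesh, centroid, u)
        if len(t_hits) == 0:
            dropped.append(i)
            log.warning("pose seed %d: centroid ray misses the mesh; dropped", i)
            continue
        c0 = centroid + u * (t_hits[-1] + standoff_mm + 20.0)
        try:
            sol = least_squares(residuals, c0, xtol=1e-8, ftol=1e-10, max_nfev=40, diff_step=0.05)
        except Exception as exc:  # pragma: no cover - defensive
            dropped.append(i)
            log.warning("pose seed %d: optimizer raised %s; dropped", i, exc)
            continue

        center, axis = project(sol.x)
        rim = _rim_mm(center, axis, radius_mm, n_rim)
        sd = surface_distance(mesh, rim)
        if sd.min() < -0.25:
            dropped.append(i)
            log.warning("pose seed %d: rejected, coil rim penetrates surface by %.2f mm", i, -sd.min())
            continue
        poses.append(
            CoilSpec(
                center=tuple(center / MM_PER_M),
                axis=tuple(axis),
                radius=coil_template.radius,
                amp_turns=coil_template.amp_turns,
            )
        )
    if dropped:
        log.info("placed %d/%d wand poses (%d dropped)", len(poses), n, len(dropped))
    return WandPoseSet(poses=poses, n_requested=n, standoff_mm=standoff_mm, dropped=dropped)


# ---------------------------------------------------------------------------
# minimax over implant orientation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _icosphere_directions(subdivisions: int) -> np.ndarray:
    v = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0).vertices
    return np.asarray(v / np.linalg.norm(v, axis=1, keepdims=True))


@lru_cache(maxsize=8)
def _icosphere_adjacency(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Vertex adjacency of the icosphere as flat (edges_a, edges_b) arrays."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    e = mesh.edges_unique
    return e[:, 0].copy(), e[:, 1].copy()


def _subdiv_for(n_directions: int) -> int:
    for s in range(2, 6):
        if 10 * 4**s + 2 >= n_directions:
            return s
    return 5


def _f_over_dirs(B: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """f(d) = max_p |B_p . d| for each direction, shape (n_dirs,)."""
    return np.abs(B @ dirs.T).max(axis=0)


def _pattern_refine(B: np.ndarray, d0: np.ndarray, delta0: float, iters: int = 26, n_az: int = 12):
    """Shrinking azimuthal pattern search of f on the unit sphere."""
    d = d0 / np.linalg.norm(d0)
    fd = float(np.abs(B @ d).max())
    delta = delta0
    az = np.linspace(0.0, 2 * np.pi, n_az, endpoint=False)
    for _ in range(iters):
        e1, e2 = _axis_frame(d)
        ring = np.cos(delta) * d + np.sin(delta) * (
            np.outer(np.cos(az), e1) + np.outer(np.sin(az), e2)
        )
        ring /= np.linalg.norm(ring, axis=1, keepdims=True)
        vals = _f_over_dirs(B, ring)
        j = int(vals.argmin())
        if vals[j] < fd:
            d, fd = ring[j], float(vals[j])
        else:
            delta *= 0.5
    return d, fd


def worst_case_field(
    B_set: np.ndarray, n_directions: int = 2562, refine: bool = True
) -> tuple[float, np.ndarray]:
    """Worst-case available field W = min_a max_p |B_p . a| (tesla).

    Returns ``(W, a)`` with ``a`` the arg-min implant orientation.  With
    fewer than three linearly independent field vectors an exactly
    orthogonal orientation exists and W = 0.  Otherwise the minimax is
    solved over >= ``n_directions`` icosphere directions, optionally
    followed by pattern-search refinement from the three best sampled
    minima (ties broken by first index).
    """
    B = np.atleast_2d(np.asarray(B_set, dtype=float))
    if B.size == 0:
        raise ValueError("B_set must be non-empty")
    if B.shape[1] != 3:
        raise ValueError(f"B_set must have shape (n_poses, 3), got {B.shape}")

    # exact rank shortcut: a direction orthogonal to span(B) gives W = 0
    _, s, Vt = np.linalg.svd(B, full_matrices=True)
    if B.shape[0] < 3 or s[-1] <= 1e-12 * s[0]:
        return 0.0, Vt[-1]

    subdiv = _subdiv_for(n_directions)
    dirs = _icosphere_directions(subdiv)
    vals = _f_over_dirs(B, dirs)
    j0 = int(vals.argmin())
    best_d, best_f = dirs[j0], float(vals[j0])
    if refine:
        spacing = np.pi / (2 ** (subdiv + 1))  # ~ angular resolution
        # restart a local pattern search from every local minimum of the
        # sampled field: the minimax of piecewise-linear |B . a| has many
        # basins and the global one need not hold the lowest sample
        ea, eb = _icosphere_adjacency(subdiv)
        not_min = np.zeros(len(dirs), dtype=bool)
        np.logical_or.at(not_min, ea, vals[ea] > vals[eb])
        np.logical_or.at(not_min, eb, vals[eb] > vals[ea])
        seeds = np.flatnonzero(~not_min)
        seeds = seeds[np.argsort(vals[seeds], kind="stable")][:40]
        cand = [dirs[seeds], Vt[-1][None, :], _stationary_candidates(B)]
        for d0 in np.vstack([c for c in cand if len(c)]):
            d, f = _pattern_refine(B, d0, delta0=2.0 * spacing)
            if f < best_f:
                best_d, best_f = d, f
    return best_f, best_d


def _stationary_candidates(B: np.ndarray, max_poses: int = 10) -> np.ndarray:
    """Candidate minimax orientations from the active-set geometry.

    Local minima of max_p |b_p . a| sit where up to three constraints are
    active: equal-|dot| solutions of pose triples (any sign pattern) and
    directions orthogonal to pose pairs.  Enumerating them seeds the
    refinement with every narrow basin that coarse sampling can miss.
    """
    P = len(B)
    if P > max_poses:
        return np.empty((0, 3))
    from itertools import combinations

    out = []
    signs = np.array([[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=float)
    for idx in combinations(range(P), 3):
        B3 = B[list(idx)]
        if abs(np.linalg.det(B3)) < 1e-12 * np.prod(np.linalg.norm(B3, axis=1) + 1e-300):
            continue
        sols = np.linalg.solve(B3, signs.T).T
        out.append(sols)
    for i, j in combinations(range(P), 2):
        c = np.cross(B[i], B[j])
        if np.linalg.norm(c) > 1e-12:
            out.append(c[None, :])
    if not out:
        return np.empty((0, 3))
    cand = np.vstack(out)
    norms = np.linalg.norm(cand, axis=1)
    cand = cand[norms > 1e-300] / norms[norms > 1e-300, None]
    return cand


def best_case_field(B_set: np.ndarray) -> float:
    """Ideal-orientation field M = max_p |B_p| (tesla)."""
    B = np.atleast_2d(np.asarray(B_set, dtype=float))
    if B.size == 0:
        raise ValueError("B_set must be non-empty")
    return float(np.linalg.norm(B, axis=1).max())


# ---------------------------------------------------------------------------
# the coverage map
# ---------------------------------------------------------------------------


@dataclass
class CoverageMap:
    """Per-voxel worst/best-case available field and powerability class.

    ``W`` and ``M`` are full 3-D float arrays in tesla (NaN outside the
    head); ``classes`` is uint8 with 0 = always_powered, 1 =
    orientation_dependent, 2 = unreachable, 255 = outside.
    """

    grid: VoxelGrid
    W: np.ndarray
    M: np.ndarray
    classes: np.ndarray
    threshold: float
    pose_set: WandPoseSet

    def class_counts(self) -> dict[str, int]:
        inside = self.classes[self.grid.inside_mask]
        return {
            CLASS_NAMES[c]: int((inside == c).sum())
            for c in (CLASS_ALWAYS, CLASS_ORIENTATION, CLASS_UNREACHABLE)
        }

    def summary(self) -> str:
        counts = self.class_counts()
        n = self.grid.n_inside
        lines = [
            f"Coverage map: {n} voxels at {self.grid.spacing} mm, "
            f"{len(self.pose_set)} wand poses, threshold {self.threshold * 1e6:.1f} uT",
        ]
        for name, c in counts.items():
            lines.append(f"  {name}: {c} voxels ({100.0 * c / max(n, 1):.1f}%)")
        return "\n".join(lines)


@lru_cache(maxsize=4)
def _fine_neighborhoods(coarse_subdiv: int, fine_subdiv: int, radius_rad: float) -> tuple[np.ndarray, ...]:
    """For each coarse direction, the fine directions within ``radius_rad``."""
    coarse = _icosphere_directions(coarse_subdiv)
    fine = _icosphere_directions(fine_subdiv)
    cos_r = np.cos(radius_rad)
    dots = coarse @ fine.T
    return tuple(np.flatnonzero(dots[c] >= cos_r) for c in range(len(coarse)))


def _minimax_fields(B: np.ndarray, n_candidates: int = 3) -> np.ndarray:
    """Per-voxel orientation minimax W for a (V, P, 3) field block.

    Hierarchical search over the fine (2562) icosphere: a coarse (162)
    pass of f(d) = max_p |B . d| per voxel, whose local minima over the
    coarse adjacency seed a restricted fine pass on their neighbourhoods.
    Running max over poses keeps memory at O(V x directions).
    """
    V, P, _ = B.shape
    coarse = _icosphere_directions(_COARSE_SUBDIV).astype(B.dtype)
    fine = _icosphere_directions(_FINE_SUBDIV).astype(B.dtype)

    F0 = np.zeros((V, len(coarse)), dtype=B.dtype)
    for p in range(P):
        np.maximum(F0, np.abs(B[:, p, :] @ coarse.T), out=F0)

    # local minima of F0 over the coarse-icosphere graph
    ea, eb = _icosphere_adjacency(_COARSE_SUBDIV)
    not_min = np.zeros((V, len(coarse)), dtype=bool)
    np.logical_or.at(not_min.T, ea, (F0[:, ea] > F0[:, eb]).T)
    np.logical_or.at(not_min.T, eb, (F0[:, eb] > F0[:, ea]).T)
    F0_masked = np.where(not_min, np.inf, F0)
    cand = np.argpartition(F0_masked, n_candidates, axis=1)[:, :n_candidates]  # (V, k)

    # restricted fine pass around each candidate basin
    spacing = 1.1 * np.arccos(np.clip((coarse[ea[0]] * coarse[eb[0]]).sum(), -1, 1))
    hoods = _fine_neighborhoods(_COARSE_SUBDIV, _FINE_SUBDIV, float(spacing))
    W = F0.min(axis=1).astype(np.float64)
    D = coarse[F0.argmin(axis=1)].astype(np.float64)
    for c in range(len(coarse)):
        rows = np.unique(np.nonzero(cand == c)[0])
        if len(rows) == 0:
            continue
        Dn = fine[hoods[c]].T  # (3, m)
        Fl = np.zeros((len(rows), Dn.shape[1]), dtype=B.dtype)
        Bc = B[rows]
        for p in range(P):
            np.maximum(Fl, np.abs(Bc[:, p, :] @ Dn), out=Fl)
        jmin = Fl.argmin(axis=1)
        better = Fl[np.arange(len(rows)), jmin] < W[rows]
        W[rows[better]] = Fl[np.arange(len(rows)), jmin][better]
        D[rows[better]] = fine[hoods[c]][jmin[better]]
    return _map_pattern_refine(B.astype(np.float64), D, W)


def _map_pattern_refine(
    B: np.ndarray, D: np.ndarray, W: np.ndarray, delta0: float = 0.07, iters: int = 14, n_az: int = 6
) -> np.ndarray:
    """Shrinking ring pattern search on the sphere, vectorised over voxels."""
    V, P, _ = B.shape
    az = np.linspace(0.0, 2 * np.pi, n_az, endpoint=False)
    cos_az, sin_az = np.cos(az), np.sin(az)
    delta = np.full(V, delta0)
    for _ in range(iters):
        helper = np.where(np.abs(D[:, :1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
        e1 = np.cross(helper, D)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(D, e1)
        cd, sd = np.cos(delta)[:, None], np.sin(delta)[:, None]
        # ring directions (V, n_az, 3)
        ring = (
            cd[:, :, None] * D[:, None, :]
            + sd[:, :, None] * (cos_az[None, :, None] * e1[:, None, :] + sin_az[None, :, None] * e2[:, None, :])
        )
        F = np.zeros((V, n_az))
        for p in range(P):
            np.maximum(F, np.abs(np.einsum("vc,vrc->vr", B[:, p, :], ring)), out=F)
        j = F.argmin(axis=1)
        fbest = F[np.arange(V), j]
        better = fbest < W
        W[better] = fbest[better]
        D[better] = ring[np.arange(V), j][better]
        delta[~better] *= 0.5
    return W


def coverage_map(
    mesh: trimesh.Trimesh,
    coil_template: CoilSpec = CoilSpec(),
    n_poses: int = 720,
    spacing: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD_T,
    standoff_mm: float = 5.0,
    seed: int = 0,
    pose_set: WandPoseSet | None = None,
    chunk_voxels: int = 65536,
) -> CoverageMap:
    """Compose voxelization, pose placement and the orientation minimax.

    ``mesh`` is in mm.  Deterministic given ``seed``.  A precomputed
    ``pose_set`` may be passed to reuse placements across thresholds or
    amp-turns scalings.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    grid = voxelize(mesh, spacing)
    if pose_set is None:
        pose_set = place_wand_poses(mesh, n=n_poses, standoff_mm=standoff_mm, seed=seed, coil_template=coil_template)
    if len(pose_set) == 0:
        raise RuntimeError("no wand poses could be placed on this mesh")

    centers_m = grid.inside_centers_mm() / MM_PER_M
    V = len(centers_m)

    W_in = np.empty(V)
    M_in = np.empty(V)
    for s in range(0, V, chunk_voxels):
        pts = centers_m[s : s + chunk_voxels]
        B = np.empty((len(pts), len(pose_set.poses), 3), dtype=np.float32)
        for j, p in enumerate(pose_set.poses):
            B[:, j, :] = field_batch(p, pts)
        M_in[s : s + chunk_voxels] = np.linalg.norm(B, axis=2).max(axis=1)
        W_in[s : s + chunk_voxels] = _minimax_fields(B)

    # sampled minimax can exceed M only by float roundoff; clamp to keep W <= M exact
    W_in = np.minimum(W_in, M_in)

    shape = grid.dims
    W = np.full(shape, np.nan)
    M = np.full(shape, np.nan)
    classes = np.full(shape, CLASS_OUTSIDE, dtype=np.uint8)
    mask = grid.inside_mask
    W[mask] = W_in
    M[mask] = M_in
    cls_in = np.where(W_in >= threshold, CLASS_ALWAYS, np.where(M_in < threshold, CLASS_UNREACHABLE, CLASS_ORIENTATION))
    classes[mask] = cls_in.astype(np.uint8)
    return CoverageMap(grid=grid, W=W, M=M, classes=classes, threshold=threshold, pose_set=pose_set)


# ---------------------------------------------------------------------------
# slice export
# ---------------------------------------------------------------------------

_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}

_CLASS_RGB = {
    CLASS_ALWAYS: (0.60, 0.85, 1.00),  # light blue: powered in any orientation
    CLASS_ORIENTATION: (0.10, 0.25, 0.60),  # dark blue: needs a suitable orientation
    CLASS_UNREACHABLE: (0.55, 0.55, 0.55),
    CLASS_OUTSIDE: (1.00, 1.00, 1.00),
}


def export_slice(
    cmap: CoverageMap,
    plane: str,
    index: int,
    out_png: str | Path | None = None,
    out_csv: str | Path | None = None,
) -> np.ndarray:
    """Extract one class-label slice; optionally write PNG and CSV.

    Returns the 2-D uint8 class image.  The CSV holds one class label
    per cell and round-trips exactly.
    """
    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXIS)}, got {plane!r}")
    ax = _PLANE_AXIS[plane]
    if not 0 <= index < cmap.grid.dims[ax]:
        raise IndexError(f"slice index {index} out of range [0, {cmap.grid.dims[ax]})")
    sl = [slice(None)] * 3
    sl[ax] = index
    img = cmap.classes[tuple(sl)]

    if out_csv is not None:
        labels = np.vectorize(CLASS_NAMES.get)(img)
        np.savetxt(out_csv, labels, fmt="%s", delimiter=",")
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        rgb = np.zeros(img.shape + (3,))
        for c, col in _CLASS_RGB.items():
            rgb[img == c] = col
        plt.imsave(out_png, np.transpose(rgb, (1, 0, 2))[::-1])
    return img
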