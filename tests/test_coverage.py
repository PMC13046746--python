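"""Voxelization, wand-pose placement and the orientation minimax."""

import inspect

import numpy as np
import pytest

from icplab.coverage import (
    CLASS_ALWAYS,
    CLASS_NAMES,
    CLASS_UNREACHABLE,
    WandPoseSet,
    best_case_field,
    coverage_map,
    export_slice,
    fibonacci_directions,
    place_wand_poses,
    voxelize,
    worst_case_field,
)
from icplab.geometry import points_in_mesh
from icplab.magnetics import CoilSpec


def brute_force_minimax(B: np.ndarray, n: int = 100_000) -> float:
    """Independent oracle: exhaustive search over quasi-uniform directions."""
    d = fibonacci_directions(n)
    return float(np.abs(np.atleast_2d(B) @ d.T).max(axis=0).min())


class TestVoxelize:
    def test_sphere_count_matches_analytic_volume(self, sphere_mesh_fine):
        grid = voxelize(sphere_mesh_fine, spacing=1.0)
        assert grid.n_inside == pytest.approx(4 / 3 * np.pi * 50**3, rel=0.005)

    def test_halving_spacing_scales_count_by_eight(self, sphere_mesh_fine):
        c2 = voxelize(sphere_mesh_fine, spacing=2.0).n_inside
        c1 = voxelize(sphere_mesh_fine, spacing=1.0).n_inside
        assert c1 / c2 == pytest.approx(8.0, rel=0.03)

    def test_masked_centers_pass_winding_oracle(self, sphere_mesh_coarse, rng):
        grid = voxelize(sphere_mesh_coarse, spacing=2.5)
        centers = grid.inside_centers_mm()
        sub = centers[rng.choice(len(centers), 400, replace=False)]
        assert points_in_mesh(sphere_mesh_coarse, sub, method="winding").all()

    def test_non_watertight_mesh_rejected(self, sphere_mesh_coarse):
        import trimesh

        open_mesh = trimesh.Trimesh(
            vertices=sphere_mesh_coarse.vertices, faces=sphere_mesh_coarse.faces[:-10], process=False
        )
        with pytest.raises(ValueError, match="watertight"):
            voxelize(open_mesh, spacing=2.0)


class TestPosePlacement:
    def test_sphere_rim_distance_matches_closed_form(self, sphere_mesh_coarse):
        R, s = 50.0, 5.0
        poses = place_wand_poses(sphere_mesh_coarse, n=16, standoff_mm=s, seed=1)
        assert len(poses) == 16
        r = poses.poses[0].radius * 1000.0
        # rim points share one distance from the centre: coil plane rests at
        # R + s, so each rim point sits at sqrt((R+s)^2 + r_coil^2)
        expected = np.sqrt((R + s) ** 2 + r**2)
        for pose in poses.poses:
            d = np.linalg.norm(pose.rim_points(16) * 1000.0, axis=1)
            assert np.abs(d - expected).max() < 1.0

    def test_default_request_is_720_poses(self):
        assert inspect.signature(place_wand_poses).parameters["n"].default == 720

    def test_axes_point_outward(self, sphere_mesh_coarse):
        poses = place_wand_poses(sphere_mesh_coarse, n=8, seed=0)
        for pose in poses.poses:
            c = np.asarray(pose.center)
            assert np.dot(pose.axis, c / np.linalg.norm(c)) > 0.99

    def test_placed_plus_dropped_partition_requests(self, ellipsoid_mesh):
        poses = place_wand_poses(ellipsoid_mesh, n=12, seed=3)
        assert len(poses) + len(poses.dropped) == 12
        assert poses.n_requested == 12

    def test_final_distance_not_above_initial(self, sphere_mesh_coarse):
        # seeds start 20 mm above the scalp; optimized poses rest on it
        poses = place_wand_poses(sphere_mesh_coarse, n=6, standoff_mm=5.0, seed=2)
        from icplab.geometry import surface_distance

        for pose in poses.poses:
            clearance = surface_distance(sphere_mesh_coarse, np.asarray(pose.center)[None, :] * 1000.0)[0]
            assert clearance <= 25.0 + 1e-6


class TestWorstCase:
    def test_single_pose_is_zero(self):
        W, a = worst_case_field([[1.0, 2.0, 3.0]])
        assert W == 0.0
        assert abs(np.dot(a, [1.0, 2.0, 3.0])) < 1e-9

    def test_two_poses_are_zero(self, rng):
        B = rng.normal(size=(2, 3))
        W, a = worst_case_field(B)
        assert W == 0.0
        assert np.abs(B @ a).max() < 1e-9 * np.linalg.norm(B)

    def test_orthogonal_triple_closed_form(self):
        b = 2.5
        W, a = worst_case_field(np.eye(3) * b)
        assert W == pytest.approx(b / np.sqrt(3), abs=1e-4)
        assert np.allclose(np.abs(a), 1 / np.sqrt(3), atol=1e-3)

    def test_against_brute_force_oracle(self, rng):
        for _ in range(20):
            B = rng.normal(size=(int(rng.integers(3, 6)), 3))
            W, _ = worst_case_field(B)
            Wb = brute_force_minimax(B)
            scale = np.linalg.norm(B, axis=1).max()
            assert W <= Wb * (1 + 1e-9) + 1e-12
            assert Wb - W <= 0.005 * scale

    def test_ten_vectors_match_oracle_within_half_percent(self, rng):
        B = rng.normal(size=(10, 3))
        W, _ = worst_case_field(B)
        assert W == pytest.approx(brute_force_minimax(B), rel=0.005)

    def test_monotone_in_added_poses(self, rng):
        B = rng.normal(size=(4, 3))
        W4, _ = worst_case_field(B)
        W5, _ = worst_case_field(np.vstack([B, rng.normal(size=(1, 3))]))
        assert W5 >= W4 - 1e-12
        assert best_case_field(np.vstack([B, rng.normal(size=(1, 3))])) >= best_case_field(B)

    def test_scaling_linearity(self, rng):
        B = rng.normal(size=(4, 3))
        W1, _ = worst_case_field(B)
        W2, _ = worst_case_field(3.0 * B)
        assert W2 == pytest.approx(3.0 * W1, rel=1e-9)

    def test_density_doubling_converged(self, rng):
        for _ in range(5):
            B = rng.normal(size=(4, 3))
            W1, _ = worst_case_field(B, n_directions=2562)
            W2, _ = worst_case_field(B, n_directions=10242)
            assert abs(W1 - W2) <= 0.005 * max(W1, 1e-12)

    def test_best_case_is_max_norm_and_dominates(self, rng):
        B = rng.normal(size=(5, 3))
        M = best_case_field(B)
        assert M == pytest.approx(np.linalg.norm(B, axis=1).max())
        W, _ = worst_case_field(B)
        assert W <= M


@pytest.fixture(scope="module")
def small_map(sphere_mesh_coarse):
    return coverage_map(sphere_mesh_coarse, n_poses=12, spacing=5.0, seed=1)


class TestCoverageMap:
    def test_invariants(self, small_map):
        mask = small_map.grid.inside_mask
        W, M, cls = small_map.W[mask], small_map.M[mask], small_map.classes[mask]
        assert (W <= M).all()
        assert np.array_equal(cls == CLASS_ALWAYS, W >= small_map.threshold)
        assert np.array_equal(cls == CLASS_UNREACHABLE, M < small_map.threshold)

    def test_zero_threshold_all_powered(self, sphere_mesh_coarse, small_map):
        cmap = coverage_map(
            sphere_mesh_coarse, n_poses=12, spacing=5.0, seed=1, threshold=0.0, pose_set=small_map.pose_set
        )
        inside = cmap.classes[cmap.grid.inside_mask]
        assert (inside == CLASS_ALWAYS).all()

    def test_infinite_threshold_all_unreachable(self, sphere_mesh_coarse, small_map):
        cmap = coverage_map(
            sphere_mesh_coarse, n_poses=12, spacing=5.0, seed=1, threshold=np.inf, pose_set=small_map.pose_set
        )
        inside = cmap.classes[cmap.grid.inside_mask]
        assert (inside == CLASS_UNREACHABLE).all()

    def test_deterministic_given_seed(self, sphere_mesh_coarse, small_map):
        again = coverage_map(sphere_mesh_coarse, n_poses=12, spacing=5.0, seed=1)
        assert np.array_equal(
            np.nan_to_num(again.W), np.nan_to_num(small_map.W)
        )
        assert np.array_equal(again.classes, small_map.classes)

    def test_matches_single_point_solver(self, small_map, rng):
        from icplab.magnetics import field_batch

        centers = small_map.grid.inside_centers_mm() / 1000.0
        W = small_map.W[small_map.grid.inside_mask]
        for i in rng.choice(len(centers), 10, replace=False):
            B = np.array([field_batch(p, centers[i][None])[0] for p in small_map.pose_set.poses])
            Wref, _ = worst_case_field(B)
            assert W[i] == pytest.approx(Wref, rel=0.03, abs=1e-12)


class TestExportSlice:
    def test_round_trip_csv(self, tmp_path, sphere_mesh_coarse):
        cmap = coverage_map(sphere_mesh_coarse, n_poses=6, spacing=6.0, seed=0)
        mid = cmap.grid.dims[0] // 2
        img = export_slice(cmap, "sagittal", mid, out_png=tmp_path / "s.png", out_csv=tmp_path / "s.csv")
        labels = np.loadtxt(tmp_path / "s.csv", dtype=str, delimiter=",")
        name_to_code = {v: k for k, v in CLASS_NAMES.items()}
        back = np.vectorize(name_to_code.get)(labels)
        assert np.array_equal(back, img)
        assert (tmp_path / "s.png").exists()

    def test_single_class_slice(self, sphere_mesh_coarse, tmp_path):
        cmap = coverage_map(sphere_mesh_coarse, n_poses=6, spacing=6.0, seed=0, threshold=np.inf)
        img = export_slice(cmap, "axial", cmap.grid.dims[2] // 2)
        inside = img != 255
        assert inside.any() and (img[inside] == CLASS_UNREACHABLE).all()

    def test_index_out_of_range(self, sphere_mesh_coarse):
        cmap = coverage_map(sphere_mesh_coarse, n_poses=6, spacing=6.0, seed=0)
        with pytest.raises(IndexError):
            export_slice(cmap, "coronal", 10_000)
        with pytest.raises(ValueError):
            export_slice(cmap, "diagonal", 0)
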