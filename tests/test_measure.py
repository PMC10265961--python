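"""Outlier removal, windowed-mean skeleton, scale-radius estimation, and the
calibrated measurement with its invariances."""

import numpy as np
import pytest

from scarmetry.measure import (
    calibrate_length,
    estimate_scale_radius,
    extract_skeleton,
    measure_scar,
    polyline_length,
    remove_outliers,
)
from scarmetry.remap import LabeledMesh


def _segment_cloud(rng, n=10_000, length=100.0, jitter=0.2):
    pts = np.zeros((n, 3))
    pts[:, 0] = rng.uniform(0, length, n)
    pts[:, 1] = rng.uniform(-jitter, jitter, n)
    pts[:, 2] = rng.uniform(-jitter, jitter, n)
    return pts


def _disk_cloud(rng, n=5000, radius=5.0):
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.stack([r * np.cos(th), r * np.sin(th), np.zeros(n)], axis=1)


class TestRemoveOutliers:
    def test_displaced_point_removed(self, rng):
        pts = _segment_cloud(rng, n=1000, length=10.0, jitter=0.01)
        spacing = 10.0 / 1000
        cloud = np.vstack([pts, [[5.0, 100 * spacing * 100, 0.0]]])
        out = remove_outliers(cloud, k=20, alpha=2.0)
        assert len(out) == 1000
        assert out[:, 1].max() < 1.0

    def test_uniform_cloud_mostly_retained(self, rng):
        # a uniform cloud has no true outliers; the only removals are cube
        # boundary points, whose neighbourhoods are half-empty
        pts = rng.uniform(0, 1, size=(2000, 3))
        out = remove_outliers(pts, k=20, alpha=2.0)
        assert len(out) >= 0.95 * len(pts)
        interior = np.all((pts > 0.2) & (pts < 0.8), axis=1)
        kept = set(map(tuple, out))
        retained = [tuple(p) in kept for p in pts[interior]]
        assert np.mean(retained) >= 0.999

    def test_tiny_cloud_returned_unchanged_with_warning(self, rng):
        pts = rng.random((5, 3))
        with pytest.warns(UserWarning, match="too small"):
            out = remove_outliers(pts, k=20)
        assert np.array_equal(out, pts)


class TestSkeleton:
    def test_window_count_formula_and_centreline_recovery(self, rng):
        pts = _segment_cloud(rng)  # X range ~[0,100], R=5 -> windows of 0.5
        sk = extract_skeleton(pts, R=5.0)
        assert sk.n_windows == int(np.floor(sk.x_range / 0.5))
        assert abs(sk.n_windows - 200) <= 1  # empirical range shrinks slightly
        # ~50 points per window, jitter uniform +/-0.2 -> window-mean sigma
        # ~0.016; individual means stay within ~5 sigma and average out
        assert np.abs(sk.points[:, 1:]).max() < 0.08
        assert np.abs(sk.points[:, 1:].mean(axis=0)).max() < 0.005

    def test_mirror_symmetric_cloud_gives_exact_zero_mean(self, rng):
        half = _segment_cloud(rng, n=2000)
        pts = np.vstack([half, half * [1, -1, 1]])
        sk = extract_skeleton(pts, R=5.0)
        # exact in real arithmetic; float summation order leaves ~1 ulp
        assert np.abs(sk.points[:, 1]).max() < 1e-12

    def test_largest_span_axis_selected_and_relabelled(self, rng):
        pts = _segment_cloud(rng, n=3000)[:, [1, 2, 0]]  # main direction now Z
        sk = extract_skeleton(pts, R=5.0)
        assert sk.main_axis == 2
        assert np.all(np.diff(sk.points[:, 0]) > 0)  # ordered along main axis
        assert sk.points[:, 0].min() >= 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            extract_skeleton(np.zeros((1, 3)), R=1.0)
        with pytest.raises(ValueError):
            extract_skeleton(np.zeros((10, 3)), R=1.0)  # zero span
        with pytest.raises(ValueError):
            extract_skeleton(np.random.default_rng(0).random((10, 3)), R=-1.0)


class TestPolylineLength:
    def test_three_four_five(self):
        assert polyline_length(np.array([[0.0, 0, 0], [3.0, 4.0, 0]])) == 5.0

    def test_collinear_skeleton_spans_range(self, rng):
        pts = _segment_cloud(rng, jitter=0.0)
        sk = extract_skeleton(pts, R=5.0)
        L = polyline_length(sk)
        assert L == pytest.approx(sk.points[-1, 0] - sk.points[0, 0], rel=1e-12)
        assert L == pytest.approx(100.0, rel=0.02)

    def test_dense_semicircle_length_is_pi_r(self, rng):
        # monotone-in-x semicircle sampled as a band, windowed at R/10; the
        # window must stay small against the end curvature (the arc turns
        # vertical at x = +/-r, where wide windows would flatten the mean)
        r = 20.0
        n = 200_000
        th = rng.uniform(0, np.pi, n)
        pts = np.stack([
            r * np.cos(th) + rng.normal(0, 0.02, n),
            r * np.sin(th) + rng.normal(0, 0.02, n),
            np.zeros(n),
        ], axis=1)
        sk = extract_skeleton(pts, R=0.2)
        assert polyline_length(sk) == pytest.approx(np.pi * r, rel=0.01)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            polyline_length(np.zeros((1, 3)))


class TestScaleRadius:
    def test_planar_disk_radius_within_two_percent(self, rng):
        est = estimate_scale_radius(_disk_cloud(rng, n=5000, radius=5.0))
        assert est.radius == pytest.approx(5.0, rel=0.02)
        assert est.radius == pytest.approx(np.median(est.edge_radii), rel=1e-12)

    def test_disk_on_cylinder_close_to_planar_value(self, rng):
        flat = _disk_cloud(rng, n=5000, radius=2.5)
        est_flat = estimate_scale_radius(flat)
        a = 50.0  # cylinder radius in the same model units
        bent = np.stack([
            a * np.sin(flat[:, 0] / a), flat[:, 1], a * np.cos(flat[:, 0] / a) - a
        ], axis=1)
        est_bent = estimate_scale_radius(bent)
        assert est_bent.radius == pytest.approx(est_flat.radius, rel=0.03)

    def test_tilted_disk_is_handled_by_plane_fit(self, rng):
        pts = _disk_cloud(rng, n=5000, radius=5.0)
        th = np.deg2rad(40)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(th), -np.sin(th)],
                        [0, np.sin(th), np.cos(th)]])
        est = estimate_scale_radius(pts @ rot.T + [3, -2, 7])
        assert est.radius == pytest.approx(5.0, rel=0.02)

    def test_degenerate_clouds_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            estimate_scale_radius(rng.random((40, 3)))
        line = np.zeros((100, 3))
        line[:, 0] = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            estimate_scale_radius(line)
        with pytest.raises(ValueError):
            estimate_scale_radius(np.zeros((100, 3)))


class TestMeasureScar:
    def test_calibration_arithmetic(self):
        assert calibrate_length(100.0, 10.0, r_true=0.5) == pytest.approx(5.0)
        assert calibrate_length(100.0, 10.0, r_true=1.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            calibrate_length(1.0, 0.0)

    def test_straight_scar_measured_within_five_percent(self, small_scene):
        lmesh = LabeledMesh(mesh=small_scene.mesh, face_labels=small_scene.face_labels)
        res = measure_scar(lmesh, repeats=3, seed=0)
        assert abs(res.length_cm - small_scene.L_true) / small_scene.L_true < 0.05
        assert len(res.per_repeat_cm) == 3
        assert res.length_cm == pytest.approx(np.mean(res.per_repeat_cm), rel=1e-12)

    def test_repeated_measurement_is_deterministic(self, small_scene):
        lmesh = LabeledMesh(mesh=small_scene.mesh, face_labels=small_scene.face_labels)
        a = measure_scar(lmesh, repeats=3, seed=11)
        b = measure_scar(lmesh, repeats=3, seed=11)
        assert a.per_repeat_cm == b.per_repeat_cm
        assert a.length_cm == b.length_cm

    def test_scale_equivariance_of_the_ratio(self, small_scene):
        # scaling all coordinates by c scales L_pc and R by c and leaves the
        # calibrated length unchanged
        lmesh = LabeledMesh(mesh=small_scene.mesh, face_labels=small_scene.face_labels)
        base = measure_scar(lmesh, repeats=2, seed=5)
        import trimesh as tm

        scaled_mesh = tm.Trimesh(
            vertices=small_scene.mesh.vertices * 3.0,
            faces=small_scene.mesh.faces, process=False,
        )
        # density per square unit must shrink by c^2 to keep the same points
        scaled = measure_scar(
            LabeledMesh(mesh=scaled_mesh, face_labels=small_scene.face_labels),
            repeats=2, seed=5, density=1000.0 / 9.0,
        )
        for a, b in zip(base.per_repeat_L_pc, scaled.per_repeat_L_pc):
            assert b == pytest.approx(3.0 * a, rel=1e-9)
        for a, b in zip(base.per_repeat_R, scaled.per_repeat_R):
            assert b == pytest.approx(3.0 * a, rel=1e-9)
        assert scaled.length_cm == pytest.approx(base.length_cm, rel=1e-9)

    def test_rigid_motion_changes_length_below_one_percent(self, small_scene):
        import trimesh as tm
        from scipy.spatial.transform import Rotation

        lmesh = LabeledMesh(mesh=small_scene.mesh, face_labels=small_scene.face_labels)
        base = measure_scar(lmesh, repeats=3, seed=5)
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        moved = tm.Trimesh(
            vertices=small_scene.mesh.vertices @ rot.T + [7.0, -3.0, 2.0],
            faces=small_scene.mesh.faces, process=False,
        )
        res = measure_scar(
            LabeledMesh(mesh=moved, face_labels=small_scene.face_labels),
            repeats=3, seed=5,
        )
        assert res.length_cm == pytest.approx(base.length_cm, rel=0.01)

    def test_error_shrinks_with_density(self, small_scene):
        lmesh = LabeledMesh(mesh=small_scene.mesh, face_labels=small_scene.face_labels)
        errs = []
        for density in (250.0, 1000.0, 4000.0):
            res = measure_scar(lmesh, repeats=4, seed=9, density=density)
            errs.append(abs(res.length_cm - small_scene.L_true) / small_scene.L_true)
        assert errs[2] <= errs[0] + 1e-12
        assert errs[2] < 0.05
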