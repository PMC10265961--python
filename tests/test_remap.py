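"""2D->3D label projection, cross-view fusion, sampling and class extraction."""

import numpy as np
import pytest
import trimesh

from scarmetry.cameras import CameraView, look_at
from scarmetry.remap import (
    LabeledMesh,
    LabeledPointCloud,
    extract_class_cloud,
    fuse_view_labels,
    project_mask_to_faces,
    sample_labeled_cloud,
)
from scarmetry.render import rasterize
from scarmetry.scene import Label


def _front_camera(distance=10.0, size=128, f=300.0):
    R, t = look_at((0, 0, distance), (0, 0, 0), up=(0, 1, 0))
    return CameraView(fx=f, fy=f, cx=(size - 1) / 2, cy=(size - 1) / 2,
                      width=size, height=size, R=R, t=t)


def _quad(z=0.0):
    verts = np.array([[-1, -1, z], [1, -1, z], [1, 1, z], [-1, 1, z]], dtype=float)
    return verts, np.array([[0, 1, 2], [0, 2, 3]])


class TestProjectMask:
    def test_facing_face_receives_mask_label_vote(self):
        verts, faces = _quad()
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        cam = _front_camera()
        mask = np.full((cam.height, cam.width), int(Label.SCAR))
        votes = project_mask_to_faces(mesh, cam, mask)
        assert (votes[:, int(Label.SCAR)] == 1).all()
        assert votes.sum() == 2

    def test_occluded_face_gets_no_vote(self):
        v0, f0 = _quad(z=0.0)
        v1, f1 = _quad(z=5.0)  # closer sheet occludes
        mesh = trimesh.Trimesh(vertices=np.vstack([v0, v1]),
                               faces=np.vstack([f0, f1 + 4]), process=False)
        cam = _front_camera()
        mask = np.full((cam.height, cam.width), int(Label.SCAR))
        votes = project_mask_to_faces(mesh, cam, mask)
        assert votes[:2].sum() == 0   # far sheet occluded
        assert votes[2:].sum() == 2   # near sheet votes

    def test_face_behind_camera_gets_no_vote(self):
        verts, faces = _quad(z=20.0)  # behind the camera at z=10 looking at -z
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        votes = project_mask_to_faces(
            mesh, _front_camera(), np.full((128, 128), int(Label.SCAR))
        )
        assert votes.sum() == 0

    def test_back_facing_face_gets_no_vote(self):
        verts, faces = _quad()
        mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=False)
        votes = project_mask_to_faces(
            mesh, _front_camera(), np.full((128, 128), int(Label.SCAR))
        )
        assert votes.sum() == 0


class TestFusion:
    def test_majority_tiebreak_and_default(self):
        # vote columns are (background, scar, scale)
        votes = np.array([
            [1, 3, 0],   # scar majority over a background vote
            [0, 0, 0],   # no votes -> background
            [0, 2, 2],   # foreground tie -> scar beats scale
            [2, 0, 1],   # lone scale vote wins: background votes do not compete
            [3, 0, 3],   # scale vote wins regardless of background count
        ])
        labels = fuse_view_labels(votes)
        assert labels.tolist() == [
            int(Label.SCAR), int(Label.BACKGROUND), int(Label.SCAR),
            int(Label.SCALE), int(Label.SCALE),
        ]

    def test_adding_a_view_never_unlabels_a_face(self, small_scene, small_views):
        votes = [
            project_mask_to_faces(small_scene.mesh, v, v.gt_mask) for v in small_views
        ]
        prev = fuse_view_labels(votes[:1])
        for k in range(2, len(votes) + 1):
            cur = fuse_view_labels(votes[:k])
            newly_unlabelled = (prev != Label.BACKGROUND) & (cur == Label.BACKGROUND)
            assert not newly_unlabelled.any()
            prev = cur

    def test_ground_truth_round_trip_on_synthetic_scene(self, small_scene, small_views):
        votes = [
            project_mask_to_faces(small_scene.mesh, v, v.gt_mask) for v in small_views
        ]
        fused = fuse_view_labels(votes)
        seen = np.sum([np.asarray(v).sum(axis=1) > 0 for v in votes], axis=0)
        check = seen >= 2
        agree = (fused[check] == small_scene.face_labels[check]).mean()
        assert agree >= 0.99


class TestSampling:
    def test_count_and_barycentric_consistency(self):
        verts, faces = _quad()
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)  # area 4
        lmesh = LabeledMesh(mesh=mesh, face_labels=np.array([1, 2]))
        cloud = sample_labeled_cloud(lmesh, density=250.0, seed=0)
        assert len(cloud) == 1000
        assert np.allclose(cloud.points[:, 2], 0.0, atol=1e-12)  # on the plane
        inside = (np.abs(cloud.points[:, 0]) <= 1) & (np.abs(cloud.points[:, 1]) <= 1)
        assert inside.all()

    def test_same_seed_identical_clouds(self, small_scene):
        lmesh = LabeledMesh(mesh=small_scene.mesh, face_labels=small_scene.face_labels)
        a = sample_labeled_cloud(lmesh, 10.0, seed=42)
        b = sample_labeled_cloud(lmesh, 10.0, seed=42)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.labels, b.labels)
        c = sample_labeled_cloud(lmesh, 10.0, seed=43)
        assert not np.array_equal(a.points, c.points)

    def test_points_inherit_face_labels_and_colors(self):
        verts, faces = _quad()
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        lmesh = LabeledMesh(mesh=mesh, face_labels=np.array([int(Label.SCAR), int(Label.SCALE)]))
        cloud = sample_labeled_cloud(lmesh, density=500.0, seed=1)
        scar_pts = cloud.labels == Label.SCAR
        assert scar_pts.any() and (~scar_pts).any()
        assert np.all(cloud.colors[scar_pts] == [255, 0, 0])
        assert np.all(cloud.colors[~scar_pts] == [0, 255, 0])

    def test_degenerate_mesh_rejected(self):
        mesh = trimesh.Trimesh(vertices=np.zeros((3, 3)), faces=[[0, 1, 2]], process=False)
        with pytest.raises(ValueError):
            sample_labeled_cloud(LabeledMesh(mesh=mesh, face_labels=np.array([1])), 100.0, 0)


class TestExtraction:
    def test_pure_colour_extraction(self, rng):
        pts = rng.random((350, 3))
        colors = np.zeros((350, 3), dtype=np.uint8)
        colors[:100] = [255, 0, 0]
        colors[100:150] = [0, 255, 0]
        cloud = LabeledPointCloud(points=pts, colors=colors)
        scar = extract_class_cloud(cloud, "scar")
        scale = extract_class_cloud(cloud, "scale")
        assert len(scar) == 100 and len(scale) == 50
        assert np.array_equal(scar.points, pts[:100])

    def test_dominance_rule_accepts_dull_red(self):
        cloud = LabeledPointCloud(
            points=np.zeros((1, 3)), colors=np.array([[130, 10, 10]], dtype=np.uint8)
        )
        assert len(extract_class_cloud(cloud, "scar")) == 1
        with pytest.raises(ValueError, match="scale"):
            extract_class_cloud(cloud, "scale")

    def test_extraction_partitions_cloud(self, rng):
        n = 500
        colors = rng.integers(0, 256, size=(n, 3)).astype(np.uint8)
        cloud = LabeledPointCloud(points=rng.random((n, 3)), colors=colors)
        c = colors.astype(int)
        scar = (c[:, 0] > 2 * np.maximum(c[:, 1], c[:, 2])) & (c[:, 0] > 60)
        scale = (c[:, 1] > 2 * np.maximum(c[:, 0], c[:, 2])) & (c[:, 1] > 60)
        assert not (scar & scale).any()  # disjoint by construction of the rule
        n_scar = int(scar.sum())
        n_scale = int(scale.sum())
        if n_scar:
            assert len(extract_class_cloud(cloud, "scar")) == n_scar
        if n_scale:
            assert len(extract_class_cloud(cloud, "scale")) == n_scale
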