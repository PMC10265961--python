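"""Remapping per-view 2D segmentation maps onto the 3D surface.

Each view casts one vote per visible face: the face centroid is projected
into the view, checked against the view's depth buffer (z-buffer visibility)
and against the face orientation, and receives the mask label found at that
pixel. Votes are fused across views by per-face majority with a fixed
priority tie-break, the labelled mesh is sampled to a point cloud by
area-weighted barycentric sampling, and per-class clouds are extracted by a
colour dominance rule (or directly by label).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .cameras import CameraView
from .render import rasterize
from .scene import Label, SCAR_COLOR, SCALE_COLOR

__all__ = [
    "LabeledMesh",
    "LabeledPointCloud",
    "project_mask_to_faces",
    "fuse_view_labels",
    "sample_labeled_cloud",
    "extract_class_cloud",
]

N_CLASSES = 3
# label -> display colour used when colouring sampled points
CLASS_COLORS = {
    int(Label.BACKGROUND): np.array([0, 0, 0], dtype=np.uint8),
    int(Label.SCAR): SCAR_COLOR,
    int(Label.SCALE): SCALE_COLOR,
}


@dataclass
class LabeledMesh:
    """Triangle mesh with fused per-face class labels and the vote tally
    (faces x classes) that produced them."""

    mesh: trimesh.Trimesh
    face_labels: np.ndarray
    votes: np.ndarray | None = None


@dataclass
class LabeledPointCloud:
    """Points with per-point class labels and display colours."""

    points: np.ndarray            # (N,3)
    labels: np.ndarray | None = None   # (N,)
    colors: np.ndarray | None = None   # (N,3) uint8

    def __len__(self) -> int:
        return len(self.points)


def project_mask_to_faces(
    mesh: trimesh.Trimesh,
    camera: CameraView,
    mask: np.ndarray,
    *,
    depth: np.ndarray | None = None,
    depth_rel_tol: float = 1e-2,
) -> np.ndarray:
    """One view's vote tally: ``(n_faces, 3)`` counts.

    A face votes iff its centroid projects inside the image, the face is
    front-facing for this camera, and the centroid passes a z-buffer test
    against the mesh's own depth map (within a relative tolerance, since the
    centroid lies on the surface that generated the buffer). The vote goes to
    the mask label at the projected pixel.
    """
    if camera.R is None or camera.t is None:
        raise ValueError("camera has no registered pose")
    mask = np.asarray(mask)
    if mask.shape != (camera.height, camera.width):
        raise ValueError("mask dimensions do not match the camera")
    if depth is None:
        depth = rasterize(mesh, camera).depth

    centroids = mesh.triangles_center
    pix, z = camera.project(centroids)
    u = np.round(pix[:, 0]).astype(int)
    v = np.round(pix[:, 1]).astype(int)
    ok = (z > 0) & (u >= 0) & (u < camera.width) & (v >= 0) & (v < camera.height)

    # front-facing: outward normal makes an obtuse angle with the view ray
    view_dir = centroids - camera.center
    ok &= (mesh.face_normals * view_dir).sum(axis=1) < 0

    votes = np.zeros((len(mesh.faces), N_CLASSES), dtype=np.int64)
    idx = np.flatnonzero(ok)
    zb = depth[v[idx], u[idx]]
    vis = z[idx] <= zb * (1.0 + depth_rel_tol)
    idx = idx[vis]
    votes[idx, mask[v[idx], u[idx]]] += 1
    return votes


def fuse_view_labels(votes: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Fuse per-view vote tallies into per-face labels.

    Majority vote among the foreground classes, ties resolved by priority
    scar > scale; a face is background iff it received no foreground vote in
    any view. Background votes are recorded in the tally but do not compete:
    counting them would let late views strip a label that an earlier view
    established, breaking the guarantee that adding a view never unlabels a
    visible face.
    """
    if isinstance(votes, list):
        if not votes:
            raise ValueError("no views to fuse")
        votes = np.sum(votes, axis=0)
    votes = np.asarray(votes)
    # order columns by priority so argmax implements the tie-break
    priority = [int(Label.SCAR), int(Label.SCALE)]
    fg = votes[:, priority]
    winner = np.argmax(fg, axis=1)
    labels = np.array(priority, dtype=np.int64)[winner]
    labels[fg.sum(axis=1) == 0] = int(Label.BACKGROUND)
    return labels


def sample_labeled_cloud(
    lmesh: LabeledMesh, density: float, seed: int | None = None
) -> LabeledPointCloud:
    """Sample the labelled mesh to a point cloud, ``density`` points per
    square model unit, area-weighted and uniform within each face. Each point
    inherits the label and class colour of its source face. Deterministic for
    a fixed seed.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    mesh = lmesh.mesh
    areas = mesh.area_faces
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    n = int(round(density * total))
    if n == 0:
        raise ValueError("density too low: zero points requested")
    rng = np.random.default_rng(seed)
    face_idx = rng.choice(len(areas), size=n, p=areas / total)
    # uniform barycentric coordinates via the square-root trick
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    b0 = 1.0 - r1
    b1 = r1 * (1.0 - r2)
    b2 = r1 * r2
    tri = mesh.triangles[face_idx]
    pts = b0[:, None] * tri[:, 0] + b1[:, None] * tri[:, 1] + b2[:, None] * tri[:, 2]
    labels = np.asarray(lmesh.face_labels)[face_idx]
    colors = np.zeros((n, 3), dtype=np.uint8)
    for lab, col in CLASS_COLORS.items():
        colors[labels == lab] = col
    return LabeledPointCloud(points=pts, labels=labels, colors=colors)


def extract_class_cloud(cloud: LabeledPointCloud, cls: int | str) -> LabeledPointCloud:
    """Extract the sub-cloud of one class.

    If the cloud carries colours, a dominance rule is applied (scar iff
    r > 2*max(g, b) and r > 60; scale iff g > 2*max(r, b) and g > 60), which
    is exact on the pure-colour encoding and tolerant to interpolation; black
    background points never pass. Otherwise labels are matched directly.
    """
    name = cls if isinstance(cls, str) else Label(cls).name.lower()
    name = name.lower()
    if name not in ("scar", "scale"):
        raise ValueError("extraction is defined for the scar and scale classes")
    if cloud.colors is not None:
        c = cloud.colors.astype(np.int64)
        r, g, b = c[:, 0], c[:, 1], c[:, 2]
        if name == "scar":
            keep = (r > 2 * np.maximum(g, b)) & (r > 60)
        else:
            keep = (g > 2 * np.maximum(r, b)) & (g > 60)
    elif cloud.labels is not None:
        target = int(Label.SCAR) if name == "scar" else int(Label.SCALE)
        keep = cloud.labels == target
    else:
        raise ValueError("cloud has neither colours nor labels")
    if not keep.any():
        raise ValueError(f"no points extracted for class {name!r}: segmentation failed")
    return LabeledPointCloud(
        points=cloud.points[keep],
        labels=None if cloud.labels is None else cloud.labels[keep],
        colors=None if cloud.colors is None else cloud.colors[keep],
    )
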