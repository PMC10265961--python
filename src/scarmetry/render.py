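"""Flat-shaded z-buffer rasterization of labelled meshes.

Renders the scene mesh into RGB images, hard label masks, depth maps and
per-pixel face indices with one and the same projection, so images and
ground-truth masks are pixel-aligned by construction. No lighting model is
applied: each face is filled with its flat colour, which keeps the colour
coding of scar / scale / skin exact. Optional Gaussian pixel noise and a
global colour jitter are available for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .cameras import CameraView
from .scene import Label, SyntheticScene

__all__ = ["RasterResult", "rasterize", "render_views"]

_NEAR = 1e-6


@dataclass
class RasterResult:
    depth: np.ndarray     # (H,W) float, +inf where empty
    face_id: np.ndarray   # (H,W) int, -1 where empty
    labels: np.ndarray | None = None  # (H,W) int
    rgb: np.ndarray | None = None     # (H,W,3) uint8

    @property
    def coverage(self) -> int:
        return int((self.face_id >= 0).sum())


def rasterize(
    mesh: trimesh.Trimesh,
    camera: CameraView,
    *,
    face_labels: np.ndarray | None = None,
    face_colors: np.ndarray | None = None,
    background_color=(0, 0, 0),
) -> RasterResult:
    """Rasterize a triangle mesh with a z-buffer.

    Depth is interpolated perspective-correctly (1/z linear in screen space).
    Faces with any vertex behind the camera are skipped; the synthetic rigs
    never straddle the image plane.
    """
    H, W = camera.height, camera.width
    pix, z = camera.project(mesh.vertices)
    depth = np.full((H, W), np.inf)
    face_id = np.full((H, W), -1, dtype=np.int64)

    tri_pix = pix[mesh.faces]          # (F,3,2)
    tri_z = z[mesh.faces]              # (F,3)
    valid = (tri_z > _NEAR).all(axis=1)
    # conservative screen-bounds cull
    xmin = np.floor(tri_pix[:, :, 0].min(axis=1)).astype(int)
    xmax = np.ceil(tri_pix[:, :, 0].max(axis=1)).astype(int)
    ymin = np.floor(tri_pix[:, :, 1].min(axis=1)).astype(int)
    ymax = np.ceil(tri_pix[:, :, 1].max(axis=1)).astype(int)
    valid &= (xmax >= 0) & (xmin <= W - 1) & (ymax >= 0) & (ymin <= H - 1)

    xmin = np.clip(xmin, 0, W - 1)
    xmax = np.clip(xmax, 0, W - 1)
    ymin = np.clip(ymin, 0, H - 1)
    ymax = np.clip(ymax, 0, H - 1)

    inv_z = 1.0 / tri_z
    for f in np.flatnonzero(valid):
        (x0, y0), (x1, y1), (x2, y2) = tri_pix[f]
        det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if det == 0.0:
            continue
        xs = np.arange(xmin[f], xmax[f] + 1)
        ys = np.arange(ymin[f], ymax[f] + 1)
        gx = xs[None, :] - x0
        gy = ys[:, None] - y0
        l1 = ((y2 - y0) * gx - (x2 - x0) * gy) / det
        l2 = (-(y1 - y0) * gx + (x1 - x0) * gy) / det
        l0 = 1.0 - l1 - l2
        inside = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        if not inside.any():
            continue
        invz = l0 * inv_z[f, 0] + l1 * inv_z[f, 1] + l2 * inv_z[f, 2]
        with np.errstate(divide="ignore"):
            d = 1.0 / invz
        sub = depth[ymin[f] : ymax[f] + 1, xmin[f] : xmax[f] + 1]
        win = inside & (d < sub)
        if not win.any():
            continue
        sub[win] = d[win]
        face_id[ymin[f] : ymax[f] + 1, xmin[f] : xmax[f] + 1][win] = f

    res = RasterResult(depth=depth, face_id=face_id)
    covered = face_id >= 0
    if face_labels is not None:
        lab = np.zeros((H, W), dtype=np.int64)
        lab[covered] = np.asarray(face_labels)[face_id[covered]]
        res.labels = lab
    if face_colors is not None:
        rgb = np.empty((H, W, 3), dtype=np.uint8)
        rgb[:] = np.asarray(background_color, dtype=np.uint8)
        rgb[covered] = np.asarray(face_colors, dtype=np.uint8)[face_id[covered]]
        res.rgb = rgb
    return res


def render_views(
    scene: SyntheticScene,
    cameras: list[CameraView],
    *,
    noise_sigma: float = 0.0,
    color_jitter: float = 0.0,
    seed: int | None = None,
    require_classes: bool = True,
) -> list[CameraView]:
    """Render the scene into each camera, attaching the RGB image and the
    pixel-aligned ground-truth mask.

    Raises
    ------
    ValueError
        Naming the camera index, if a camera sees nothing of the mesh or
        (when ``require_classes``) misses the scar or the scale entirely.
    """
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    out = []
    for i, cam in enumerate(cameras):
        res = rasterize(
            scene.mesh, cam,
            face_labels=scene.face_labels, face_colors=scene.face_colors,
        )
        if res.coverage == 0:
            raise ValueError(f"camera {i}: empty frustum (mesh not visible)")
        if require_classes:
            present = set(np.unique(res.labels[res.face_id >= 0]).tolist())
            missing = [
                name for name, val in (("scar", Label.SCAR), ("scale", Label.SCALE))
                if int(val) not in present
            ]
            if missing:
                raise ValueError(f"camera {i}: {' and '.join(missing)} not visible")
        img = res.rgb.astype(float)
        if color_jitter > 0:
            img = img * (1.0 + rng.uniform(-color_jitter, color_jitter, size=3))
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        out.append(
            CameraView(
                fx=cam.fx, fy=cam.fy, cx=cam.cx, cy=cam.cy,
                width=cam.width, height=cam.height, R=cam.R, t=cam.t,
                name=cam.name, image=img, gt_mask=res.labels,
            )
        )
    return out
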