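"""Pinhole cameras, multiview rigs, and camera-set serialization.

Conventions: world units are model units (cm for synthetic scenes); the
extrinsics map world to camera coordinates, ``x_cam = R @ x_world + t`` with
the camera looking along +z and image y pointing down. Pixels are 0-based,
origin at the top-left, pixel centres at integer coordinates. The same
world-to-camera convention is used by the COLMAP text format, so conversion
is quaternion packing only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["CameraView", "look_at", "ring_rig", "save_cameras_json",
           "load_cameras_json", "save_cameras_colmap", "load_cameras_colmap"]


@dataclass
class CameraView:
    """A pinhole camera with optional image and ground-truth mask."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    R: np.ndarray  # (3,3) world->camera rotation
    t: np.ndarray  # (3,)  world->camera translation
    name: str = ""
    image: np.ndarray | None = None      # (H,W,3) uint8
    gt_mask: np.ndarray | None = None    # (H,W) int labels

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")
        if self.image is not None and self.image.shape[:2] != (self.height, self.width):
            raise ValueError("image does not match declared dimensions")
        if self.gt_mask is not None and self.gt_mask.shape[:2] != (self.height, self.width):
            raise ValueError("mask does not match declared dimensions")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0, self.cx], [0, self.fy, self.cy], [0, 0, 1.0]])

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.R.T @ self.t

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points; returns ``(pixels (N,2), depth (N,))``.
        Points behind the camera get negative depth; callers must filter."""
        pc = self.to_camera(np.atleast_2d(points))
        z = pc[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.fx * pc[:, 0] / z + self.cx
            v = self.fy * pc[:, 1] / z + self.cy
        return np.stack([u, v], axis=-1), z


def look_at(position, target, up=(0.0, 1.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
    """World-to-camera (R, t) for a camera at ``position`` looking at
    ``target``. ``up`` is the world direction that should map to image-up."""
    position = np.asarray(position, dtype=float)
    forward = np.asarray(target, dtype=float) - position
    nf = np.linalg.norm(forward)
    if nf == 0:
        raise ValueError("camera position coincides with target")
    forward = forward / nf
    up = np.asarray(up, dtype=float)
    right = np.cross(forward, up)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise ValueError("up direction parallel to viewing direction")
    right /= nr
    down = np.cross(forward, right)  # image y points down
    R = np.stack([right, down, forward], axis=0)
    t = -R @ position
    return R, t


def ring_rig(
    n_views: int,
    target,
    distance: float,
    *,
    elevation_deg: float = 45.0,
    arc_deg: float = 120.0,
    fx: float = 800.0,
    fy: float | None = None,
    width: int = 640,
    height: int = 640,
    axis_up=(0.0, 0.0, 1.0),
) -> list[CameraView]:
    """N cameras on a circular arc aimed at the scene centre, emulating a
    handheld capture that moves around the subject.

    The arc lies at ``elevation_deg`` above the surface tangent plane and
    spans ``arc_deg`` degrees of azimuth centred on the surface normal.
    """
    if n_views < 1:
        raise ValueError("need at least one view")
    target = np.asarray(target, dtype=float)
    axis_up = np.asarray(axis_up, dtype=float)
    axis_up = axis_up / np.linalg.norm(axis_up)
    # orthonormal frame around the up axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis_up) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis_up, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_up, e1)
    elev = np.deg2rad(elevation_deg)
    if n_views == 1:
        azims = np.array([0.0])
    else:
        azims = np.deg2rad(np.linspace(-arc_deg / 2, arc_deg / 2, n_views))
    views = []
    for i, az in enumerate(azims):
        direction = (
            np.cos(elev) * (np.cos(az) * e1 + np.sin(az) * e2) + np.sin(elev) * axis_up
        )
        pos = target + distance * direction
        R, t = look_at(pos, target, up=axis_up)
        views.append(
            CameraView(
                fx=fx, fy=fy if fy is not None else fx,
                cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                width=width, height=height, R=R, t=t, name=f"view{i:03d}.png",
            )
        )
    return views


# ---------------------------------------------------------------------------
# serialization: JSON dialect and COLMAP text dialect


def save_cameras_json(views: list[CameraView], path: str | Path) -> None:
    recs = []
    for v in views:
        recs.append(
            {
                "name": v.name, "fx": v.fx, "fy": v.fy, "cx": v.cx, "cy": v.cy,
                "width": v.width, "height": v.height,
                "R": [float(x) for x in v.R.ravel()],  # row-major
                "t": [float(x) for x in v.t],
            }
        )
    Path(path).write_text(json.dumps({"cameras": recs}, indent=2))


def load_cameras_json(path: str | Path) -> list[CameraView]:
    data = json.loads(Path(path).read_text())
    views = []
    for r in data["cameras"]:
        views.append(
            CameraView(
                fx=r["fx"], fy=r["fy"], cx=r["cx"], cy=r["cy"],
                width=r["width"], height=r["height"],
                R=np.array(r["R"], dtype=float).reshape(3, 3),
                t=np.array(r["t"], dtype=float), name=r.get("name", ""),
            )
        )
    return views


def save_cameras_colmap(views: list[CameraView], out_dir: str | Path) -> None:
    """Write cameras.txt / images.txt (PINHOLE model, one camera per image)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cam_lines = ["# Camera list: CAMERA_ID, MODEL, WIDTH, HEIGHT, PARAMS[]"]
    img_lines = [
        "# Image list: IMAGE_ID, QW, QX, QY, QZ, TX, TY, TZ, CAMERA_ID, NAME",
        "#   POINTS2D[] as (X, Y, POINT3D_ID)",
    ]
    for i, v in enumerate(views, start=1):
        cam_lines.append(
            f"{i} PINHOLE {v.width} {v.height} {v.fx:.12g} {v.fy:.12g} {v.cx:.12g} {v.cy:.12g}"
        )
        # scipy uses (x, y, z, w); COLMAP wants (w, x, y, z)
        x, y, z, w = Rotation.from_matrix(v.R).as_quat()
        name = v.name or f"view{i - 1:03d}.png"
        img_lines.append(
            f"{i} {w:.12g} {x:.12g} {y:.12g} {z:.12g} "
            f"{v.t[0]:.12g} {v.t[1]:.12g} {v.t[2]:.12g} {i} {name}"
        )
        img_lines.append("")  # empty 2D-points line
    (out / "cameras.txt").write_text("\n".join(cam_lines) + "\n")
    (out / "images.txt").write_text("\n".join(img_lines) + "\n")


def load_cameras_colmap(cameras_txt: str | Path, images_txt: str | Path) -> list[CameraView]:
    """Parse the COLMAP text dialect (PINHOLE / SIMPLE_PINHOLE models)."""
    intrinsics: dict[int, dict] = {}
    for line in Path(cameras_txt).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        cam_id, model = int(parts[0]), parts[1]
        w, h = int(parts[2]), int(parts[3])
        params = [float(p) for p in parts[4:]]
        if model == "PINHOLE":
            fx, fy, cx, cy = params
        elif model == "SIMPLE_PINHOLE":
            fx = fy = params[0]
            cx, cy = params[1], params[2]
        else:
            raise ValueError(f"unsupported COLMAP camera model {model!r}")
        intrinsics[cam_id] = dict(fx=fx, fy=fy, cx=cx, cy=cy, width=w, height=h)

    views = []
    lines = [
        ln.strip()
        for ln in Path(images_txt).read_text().splitlines()
        if not ln.lstrip().startswith("#")
    ]
    # image entries come in pairs: a pose line followed by a 2D-points line
    # (which may be empty); alternate through them in order
    pose_lines = lines[0::2]
    for ln in pose_lines:
        if not ln:
            continue
        parts = ln.split()
        qw, qx, qy, qz = (float(p) for p in parts[1:5])
        tx, ty, tz = (float(p) for p in parts[5:8])
        cam_id = int(parts[8])
        name = parts[9]
        intr = intrinsics[cam_id]
        R = Rotation.from_quat([qx, qy, qz, qw]).as_matrix()
        views.append(CameraView(R=R, t=np.array([tx, ty, tz]), name=name, **intr))
    return views
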