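"""End-to-end orchestration: images + cameras + mesh -> calibrated length.

The pipeline wires the measurement stages together: acquire (generate a
synthetic scene or ingest an external reconstruction), segment (network
inference or ground-truth masks), remap (2D masks -> fused 3D face labels),
measure (sampling, skeleton, scale calibration, repeats) and evaluate
(relative error against a reference, when one is known). Reports are JSON;
stage timings go to a separate sidecar so the report itself is byte-stable
for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import trimesh

from . import __version__
from .cameras import CameraView, load_cameras_colmap, load_cameras_json
from .evaluate import relative_error
from .measure import MeasurementResult, extract_skeleton, measure_scar
from .presets import default_rig, simulation_scene_configs
from .remap import (
    LabeledMesh,
    fuse_view_labels,
    project_mask_to_faces,
    sample_labeled_cloud,
    extract_class_cloud,
)
from .render import rasterize, render_views
from .scene import Label, SceneConfig, generate_scene
from .segmentation import hard_mask, load_checkpoint, predict_masks, segmentation_metrics

logger = logging.getLogger("scarmetry")

__all__ = ["PipelineConfig", "RunReport", "ingest_reconstruction", "run_pipeline",
           "labels_from_colors"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    mode ``synthetic`` generates a preset scene and renders its views; mode
    ``reconstructed`` ingests an external reconstruction (mesh + registered
    cameras + images). ``mask_source`` selects ground-truth masks (synthetic
    only), a trained model checkpoint, or a directory of mask PNGs matched
    to views by filename.
    """

    mode: str = "synthetic"                     # synthetic | reconstructed
    scene: str | SceneConfig = "scar1"          # preset name or explicit config
    n_views: int = 4
    mesh_path: str | None = None
    cameras_path: str | None = None
    images_dir: str | None = None
    mask_source: str = "groundtruth"            # groundtruth | model | dir
    model_path: str | None = None
    masks_dir: str | None = None
    r_true: float = 0.5                         # fiducial radius, cm
    density: float = 1000.0                     # points per square model unit
    repeats: int = 10
    seed: int = 0
    reference_length_cm: float | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "reconstructed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.r_true <= 0 or self.density <= 0 or self.repeats < 1:
            raise ValueError("r_true and density must be positive, repeats >= 1")
        if self.mode == "reconstructed":
            for name in ("mesh_path", "cameras_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or does not exist: {p}")
            if self.mask_source == "groundtruth":
                raise ValueError("ground-truth masks are only available in synthetic mode")
        if self.mask_source == "model" and (
            self.model_path is None or not Path(self.model_path).exists()
        ):
            raise ValueError(f"model checkpoint missing: {self.model_path}")
        if self.mask_source == "dir" and (
            self.masks_dir is None or not Path(self.masks_dir).is_dir()
        ):
            raise ValueError(f"masks directory missing: {self.masks_dir}")
        if isinstance(self.scene, str) and self.scene not in simulation_scene_configs():
            raise ValueError(f"unknown scene preset {self.scene!r}")


@dataclass
class RunReport:
    measurement: MeasurementResult
    config: dict
    version: str
    segmentation: list[dict] = field(default_factory=list)
    error: dict | None = None
    timings: dict = field(default_factory=dict)
    L_true_cm: float | None = None

    def to_dict(self, include_timings: bool = False) -> dict:
        out = {
            "version": self.version,
            "config": self.config,
            "measurement": self.measurement.to_dict(),
            "segmentation": self.segmentation,
            "error": self.error,
            "L_true_cm": self.L_true_cm,
        }
        if include_timings:
            out["timings"] = self.timings
        return out


def labels_from_colors(colors: np.ndarray) -> np.ndarray:
    """Class labels from RGB colours by the same dominance rule used for
    point clouds (scar iff r > 2*max(g,b) and r > 60; scale analogously)."""
    c = np.asarray(colors)[..., :3].astype(np.int64)
    r, g, b = c[..., 0], c[..., 1], c[..., 2]
    labels = np.zeros(c.shape[:-1], dtype=np.int64)
    labels[(r > 2 * np.maximum(g, b)) & (r > 60)] = int(Label.SCAR)
    labels[(g > 2 * np.maximum(r, b)) & (g > 60)] = int(Label.SCALE)
    return labels


def ingest_reconstruction(
    mesh_path: str | Path,
    cameras_path: str | Path,
    images_dir: str | Path | None = None,
) -> tuple[trimesh.Trimesh, list[CameraView]]:
    """Load an externally reconstructed mesh and its registered cameras.

    ``cameras_path`` may be the JSON dialect written by this package, a
    directory containing COLMAP ``cameras.txt``/``images.txt``, or one of
    those two files. When ``images_dir`` is given, each view's image is
    loaded by filename; a missing file is an error naming it.
    """
    mesh = trimesh.load(str(mesh_path), force="mesh", process=False)
    cpath = Path(cameras_path)
    if cpath.is_dir():
        views = load_cameras_colmap(cpath / "cameras.txt", cpath / "images.txt")
    elif cpath.suffix == ".json":
        views = load_cameras_json(cpath)
    elif cpath.name == "cameras.txt":
        views = load_cameras_colmap(cpath, cpath.with_name("images.txt"))
    elif cpath.name == "images.txt":
        views = load_cameras_colmap(cpath.with_name("cameras.txt"), cpath)
    else:
        raise ValueError(f"unrecognized cameras file {cpath}")
    if images_dir is not None:
        for v in views:
            img_path = Path(images_dir) / v.name
            if not img_path.exists():
                raise FileNotFoundError(f"image referenced by cameras is missing: {img_path}")
            img = iio.imread(img_path)
            if img.shape[:2] != (v.height, v.width):
                raise ValueError(f"{v.name}: image size {img.shape[:2]} != camera size")
            v.image = img[..., :3]
    return mesh, views


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and (optionally) write artifacts to ``out_dir``.

    Deterministic for a fixed config and seed. Any stage failure raises with
    the stage name; artifacts of completed stages are preserved.
    """
    config.validate()
    timings: dict[str, float] = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage %s: start", name)
        return time.perf_counter()

    # ---- acquire ---------------------------------------------------------
    t0 = stage("acquire")
    L_true = None
    if config.mode == "synthetic":
        scene_cfg = (
            simulation_scene_configs()[config.scene]
            if isinstance(config.scene, str)
            else config.scene
        )
        scene = generate_scene(scene_cfg, seed=config.seed)
        rig = default_rig(scene, n_views=config.n_views)
        views = render_views(scene, rig, seed=config.seed)
        mesh = scene.mesh
        L_true = scene.L_true
    else:
        mesh, views = ingest_reconstruction(
            config.mesh_path, config.cameras_path, config.images_dir
        )
    timings["acquire"] = time.perf_counter() - t0
    logger.info("acquire: %d faces, %d views", len(mesh.faces), len(views))

    # ---- segment ---------------------------------------------------------
    t0 = stage("segment")
    seg_records: list[dict] = []
    masks: list[np.ndarray] = []
    if config.mask_source == "groundtruth":
        masks = [v.gt_mask for v in views]
    elif config.mask_source == "model":
        model = load_checkpoint(config.model_path)
        probs = predict_masks(model, [v.image for v in views])
        masks = [hard_mask(p) for p in probs]
    else:
        for v in views:
            mpath = Path(config.masks_dir) / v.name
            if not mpath.exists():
                raise FileNotFoundError(f"segment: mask missing for view {v.name}")
            m = iio.imread(mpath)
            masks.append(labels_from_colors(m) if m.ndim == 3 else m.astype(np.int64))
    for v, m in zip(views, masks):
        if v.gt_mask is not None and m is not v.gt_mask:
            rec = {"view": v.name}
            for cls in ("scar", "scale"):
                met = segmentation_metrics(m, v.gt_mask, cls)
                rec[cls] = {"dsc": met.dsc, "sen": met.sen, "spe": met.spe}
            seg_records.append(rec)
    timings["segment"] = time.perf_counter() - t0

    # ---- remap -----------------------------------------------------------
    t0 = stage("remap")
    votes = [project_mask_to_faces(mesh, v, m) for v, m in zip(views, masks)]
    labels = fuse_view_labels(votes)
    n_scar = int((labels == Label.SCAR).sum())
    n_scale = int((labels == Label.SCALE).sum())
    if n_scar == 0 or n_scale == 0:
        raise RuntimeError(
            f"remap: fused labels contain {n_scar} scar and {n_scale} scale faces; "
            "need at least one of each"
        )
    lmesh = LabeledMesh(mesh=mesh, face_labels=labels, votes=np.sum(votes, axis=0))
    timings["remap"] = time.perf_counter() - t0
    logger.info("remap: %d scar faces, %d scale faces", n_scar, n_scale)

    # ---- measure ---------------------------------------------------------
    t0 = stage("measure")
    result = measure_scar(
        lmesh, r_true=config.r_true, repeats=config.repeats, seed=config.seed,
        density=config.density,
    )
    timings["measure"] = time.perf_counter() - t0
    logger.info("measure: L_scar = %.4f cm over %d repeats", result.length_cm, result.repeats)

    # ---- evaluate --------------------------------------------------------
    reference = config.reference_length_cm if config.reference_length_cm is not None else L_true
    error = None
    if reference is not None:
        error = {
            "reference_cm": float(reference),
            "re_percent": relative_error(result.length_cm, reference),
        }

    report = RunReport(
        measurement=result,
        config=_config_echo(config),
        version=__version__,
        segmentation=seg_records,
        error=error,
        timings=timings,
        L_true_cm=L_true,
    )

    if out_dir:
        (out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        (out_dir / "timings.json").write_text(json.dumps(timings, indent=2))
        _export_clouds(out_dir, lmesh, result, config)
    return report


def _config_echo(config: PipelineConfig) -> dict:
    d = dict(vars(config))
    if isinstance(d["scene"], SceneConfig):
        d["scene"] = "<inline SceneConfig>"
    d.pop("out_dir")  # where the report lands is not part of what it states
    return d


def _export_clouds(out_dir: Path, lmesh: LabeledMesh, result, config: PipelineConfig) -> None:
    """Visual-QC artifacts: labelled cloud and skeleton/edge points as PLY."""
    # QC artifact only: cap the exported cloud at ~2e5 points
    qc_density = min(config.density, 2e5 / lmesh.mesh.area)
    cloud = sample_labeled_cloud(lmesh, qc_density, seed=config.seed)
    trimesh.PointCloud(cloud.points, colors=cloud.colors).export(out_dir / "labeled_cloud.ply")
    try:
        scar = extract_class_cloud(cloud, "scar")
        R = float(np.mean(result.per_repeat_R))
        skel = extract_skeleton(scar, R)
        inv = np.argsort([skel.main_axis] + [a for a in range(3) if a != skel.main_axis])
        pts = skel.points[:, inv]
        pts[:, skel.main_axis] += scar.points[:, skel.main_axis].min()
        trimesh.PointCloud(pts).export(out_dir / "skeleton.ply")
    except ValueError:
        logger.warning("skeleton export skipped")
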