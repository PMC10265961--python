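"""Standard synthetic scenes and camera rigs.

``simulation_scene_configs`` returns five scenes that re-create the regime of
the artificial-scar validation experiment: scars of different curvatures and
lengths (roughly 1.4, 6.8, 10.5, 12.7 and 20 cm) drawn on a plane, cylinder
patches, a sphere patch and a paraboloid patch, each with the standard
0.5 cm circular scale placed beside the scar. Surface shapes are this
package's own choice — chosen to span gentle-to-moderate skin-like
curvature — since only the scar lengths of the original experiment are
known.
"""

from __future__ import annotations

import numpy as np

from .cameras import CameraView, ring_rig
from .scene import ScarCurve, ScaleDisk, SceneConfig, SyntheticScene
from .surfaces import ParametricSurface

__all__ = ["simulation_scene_configs", "default_rig"]


def simulation_scene_configs() -> dict[str, SceneConfig]:
    """Five named scene configurations spanning ~1.4-20 cm scar lengths."""
    cfgs: dict[str, SceneConfig] = {}

    # 1. straight 12.68 cm scar on a plane
    cfgs["scar1"] = SceneConfig(
        surface=ParametricSurface("plane", u_range=(-7.5, 7.5), v_range=(-4.0, 4.0)),
        curve=ScarCurve("line", {"p0": (-6.34, -1.5), "p1": (6.34, -1.5)}),
        disk=ScaleDisk(center=(0.0, 2.0)),
    )
    # 2. 6.8 cm scar wrapped around an 8 cm-radius cylinder
    cfgs["scar2"] = SceneConfig(
        surface=ParametricSurface("cylinder", u_range=(-5.0, 5.0), v_range=(-4.0, 4.0), radius=8.0),
        curve=ScarCurve("line", {"p0": (-3.4, -1.5), "p1": (3.4, -1.5)}),
        disk=ScaleDisk(center=(0.0, 1.8)),
    )
    # 3. short 1.41 cm scar on a 12 cm-radius sphere patch
    cfgs["scar3"] = SceneConfig(
        surface=ParametricSurface("sphere", u_range=(-3.0, 3.0), v_range=(-3.0, 3.0), radius=12.0),
        curve=ScarCurve("line", {"p0": (-0.705, -1.2), "p1": (0.705, -1.2)}),
        disk=ScaleDisk(center=(0.0, 1.2)),
    )
    # 4. wavy ~10.5 cm scar on a 6 cm-radius cylinder
    cfgs["scar4"] = SceneConfig(
        surface=ParametricSurface("cylinder", u_range=(-6.0, 6.0), v_range=(-4.5, 4.5), radius=6.0),
        curve=ScarCurve(
            "sine", {"u0": -4.8, "u1": 4.8, "v0": -1.8, "amplitude": 1.0, "periods": 1.5}
        ),
        disk=ScaleDisk(center=(0.0, 2.2)),
    )
    # 5. long ~20 cm gently curved scar on a shallow paraboloid
    cfgs["scar5"] = SceneConfig(
        surface=ParametricSurface(
            "paraboloid", u_range=(-11.0, 11.0), v_range=(-5.0, 5.0), focal=25.0
        ),
        curve=ScarCurve(
            "sine", {"u0": -9.5, "u1": 9.5, "v0": -2.0, "amplitude": 0.8, "periods": 1.0}
        ),
        disk=ScaleDisk(center=(0.0, 3.0)),
    )
    return cfgs


def default_rig(
    scene: SyntheticScene,
    n_views: int = 4,
    *,
    width: int = 512,
    height: int = 512,
    arc_deg: float = 100.0,
    elevation_deg: float = 55.0,
    distance_factor: float = 1.6,
) -> list[CameraView]:
    """A handheld-style arc of cameras around the scene.

    The rig distance scales with the scene extent and the focal length is set
    so the scene fills ~85% of the frame, which keeps the ground-sample
    distance well below the mesh cell size (sub-millimetre at these scales).
    """
    bounds = scene.mesh.bounds
    target = bounds.mean(axis=0)
    extent = float(np.max(bounds[1] - bounds[0]))
    distance = distance_factor * extent
    fx = 0.85 * min(width, height) * distance / extent
    return ring_rig(
        n_views, target, distance,
        elevation_deg=elevation_deg, arc_deg=arc_deg,
        fx=fx, width=width, height=height, axis_up=(0.0, 0.0, 1.0),
    )
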