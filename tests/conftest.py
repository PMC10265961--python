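"""Shared fixtures: small, fast synthetic scenes and rendered views."""

from __future__ import annotations

import numpy as np
import pytest

from scarmetry.cameras import CameraView
from scarmetry.presets import default_rig
from scarmetry.render import render_views
from scarmetry.scene import ScarCurve, ScaleDisk, SceneConfig, generate_scene
from scarmetry.surfaces import ParametricSurface


@pytest.fixture(scope="session")
def small_scene_cfg() -> SceneConfig:
    """A small plane scene with a straight 5 cm scar and the standard disk."""
    return SceneConfig(
        surface=ParametricSurface("plane", u_range=(-4.0, 4.0), v_range=(-4.0, 4.0)),
        curve=ScarCurve("line", {"p0": (-2.5, -1.2), "p1": (2.5, -1.2)}, width=0.3),
        disk=ScaleDisk(center=(0.0, 1.5)),
        cell_size=0.2,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_cfg):
    return generate_scene(small_scene_cfg, seed=7)


@pytest.fixture(scope="session")
def small_views(small_scene):
    rig = default_rig(small_scene, n_views=4, width=256, height=256)
    return render_views(small_scene, rig, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
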