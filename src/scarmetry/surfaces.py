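"""Parametric surface patches that stand in for curved skin regions.

Each surface maps 2D parameters ``(u, v)`` (cm) to 3D points (cm). The
parametrizations are chosen to be (near-)isometric around the patch origin —
the ``u`` coordinate of the cylinder is arc length, the sphere uses the
exponential map — so that curves and fiducial disks drawn in parameter space
keep their metric size when imprinted on the surface, exactly as a printed
sheet wrapped onto a curved object does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = ["ParametricSurface", "make_surface"]

_KINDS = ("plane", "cylinder", "sphere", "paraboloid")


@dataclass(frozen=True)
class ParametricSurface:
    """A rectangular patch of an analytic surface.

    Parameters
    ----------
    kind
        One of ``plane``, ``cylinder`` (radius ``radius``, curved along u),
        ``sphere`` (radius ``radius``, exponential-map parametrization) or
        ``paraboloid`` (``z = (u^2+v^2) / (2*focal)``).
    u_range, v_range
        Patch extent in cm.
    radius
        Cylinder / sphere radius in cm (ignored for the plane).
    focal
        Paraboloid shape parameter in cm (larger = flatter).
    """

    kind: str
    u_range: tuple[float, float] = (-5.0, 5.0)
    v_range: tuple[float, float] = (-5.0, 5.0)
    radius: float = 10.0
    focal: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind in ("cylinder", "sphere") and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.kind == "cylinder":
            span = self.u_range[1] - self.u_range[0]
            if span >= 2 * np.pi * self.radius:
                raise ValueError("cylinder patch wraps around itself")

    def point(self, u, v) -> np.ndarray:
        """Map parameter coordinates to 3D, vectorized over the inputs."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.kind == "plane":
            z = np.zeros(np.broadcast(u, v).shape)
            return np.stack(np.broadcast_arrays(u, v, z), axis=-1)
        if self.kind == "cylinder":
            a = self.radius
            x = a * np.sin(u / a)
            z = a * np.cos(u / a) - a
            return np.stack(np.broadcast_arrays(x, v, z), axis=-1)
        if self.kind == "sphere":
            a = self.radius
            rho = np.hypot(u, v)
            with np.errstate(invalid="ignore", divide="ignore"):
                du = np.where(rho > 0, u / np.where(rho > 0, rho, 1.0), 0.0)
                dv = np.where(rho > 0, v / np.where(rho > 0, rho, 1.0), 0.0)
            theta = rho / a
            x = a * np.sin(theta) * du
            y = a * np.sin(theta) * dv
            z = a * (np.cos(theta) - 1.0)
            return np.stack(np.broadcast_arrays(x, y, z), axis=-1)
        # paraboloid
        z = (u**2 + v**2) / (2.0 * self.focal)
        return np.stack(np.broadcast_arrays(u, v, z), axis=-1)

    def mesh(
        self,
        cell_size: float = 0.1,
        refine: list[tuple[float, float, float, float, float]] | None = None,
    ) -> tuple[trimesh.Trimesh, np.ndarray]:
        """Tessellate the patch into a triangle mesh.

        Returns the mesh and the ``(n_vertices, 2)`` array of vertex (u, v)
        coordinates. Grid cells are at most ``cell_size`` cm on a side; each
        cell is split into two triangles. ``refine`` is an optional list of
        ``(u_lo, u_hi, v_lo, v_hi, fine_cell)`` boxes whose grid lines are
        densified to ``fine_cell`` spacing (the structured grid is an outer
        product, so refinement bands extend across the patch).
        """
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        u0, u1 = self.u_range
        v0, v1 = self.v_range
        us = _grid_lines(u0, u1, cell_size, [(r[0], r[1], r[4]) for r in (refine or [])])
        vs = _grid_lines(v0, v1, cell_size, [(r[2], r[3], r[4]) for r in (refine or [])])
        nu, nv = len(us) - 1, len(vs) - 1
        uu, vv = np.meshgrid(us, vs, indexing="ij")
        uv = np.stack([uu.ravel(), vv.ravel()], axis=-1)
        verts = self.point(uv[:, 0], uv[:, 1])

        # two triangles per grid cell, consistent winding
        i, j = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
        a = (i * (nv + 1) + j).ravel()
        b = ((i + 1) * (nv + 1) + j).ravel()
        c = ((i + 1) * (nv + 1) + j + 1).ravel()
        d = (i * (nv + 1) + j + 1).ravel()
        faces = np.concatenate(
            [np.stack([a, b, c], axis=-1), np.stack([a, c, d], axis=-1)], axis=0
        )
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        return mesh, uv


def _grid_lines(
    lo: float, hi: float, cell: float, bands: list[tuple[float, float, float]]
) -> np.ndarray:
    """Base grid lines at ``cell`` spacing, densified inside refinement bands."""
    n = max(1, int(np.ceil((hi - lo) / cell)))
    lines = np.linspace(lo, hi, n + 1)
    for b_lo, b_hi, fine in bands:
        b_lo, b_hi = max(lo, b_lo), min(hi, b_hi)
        if b_hi <= b_lo or fine >= cell:
            continue
        m = max(1, int(np.ceil((b_hi - b_lo) / fine)))
        lines = np.union1d(lines, np.linspace(b_lo, b_hi, m + 1))
    # prune near-duplicate lines that would create sliver cells
    keep = np.concatenate([[True], np.diff(lines) > 1e-9])
    return lines[keep]


def make_surface(kind: str, **kwargs) -> ParametricSurface:
    """Convenience constructor mirroring :class:`ParametricSurface`."""
    return ParametricSurface(kind=kind, **kwargs)
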