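"""Constructive solid geometry for synthetic dendritic spines.

A synthetic spine is a surface of revolution swept along a planar circular-arc
axis: a short dendrite stub (constant-radius cylinder), a smoothstep blend, a
neck whose radius varies along its length, and a spherical head truncated
where the neck joins it.  Because every piece is defined by an analytic radius
profile ``R(t)`` over axis arc-length ``t``, all ground-truth quantities
(volumes, mean/min diameters, threshold-crossing positions) can be computed
exactly from the profile, independently of any mesh discretization.

For a circular-arc axis with cross-sections taken perpendicular to the axis,
the enclosed volume is exactly ``integral of pi R(t)^2 dt`` (Pappus), provided
the bend radius exceeds the tube radius, which the mild default bend
guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ArcAxis",
    "SpineSolid",
    "smoothstep",
    "polygon_radius_factor",
    "sweep_mesh",
]


def smoothstep(x: np.ndarray | float) -> np.ndarray | float:
    """C1 smoothstep 3x^2 - 2x^3 clamped to [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def polygon_radius_factor(n: int) -> float:
    """Radial inflation making a regular n-gon's area equal pi r^2.

    A regular n-gon inscribed in a circle of radius r has area
    (n/2) r^2 sin(2 pi/n) < pi r^2; scaling vertices by this factor removes
    the leading-order area (and hence volume) bias of the swept mesh.
    """
    return float(np.sqrt(2.0 * np.pi / (n * np.sin(2.0 * np.pi / n))))


@dataclass(frozen=True)
class ArcAxis:
    """Planar circular-arc axis in the x-z plane, parameterized by arc length.

    ``bend_angle`` is the total turn (radians) over ``length``; zero gives a
    straight axis along +x.  The bend lies in x-z so that, when a mesh is
    resampled on anisotropic serial sections stacked along z, the neck sweeps
    through several section phases instead of sitting in one.
    """

    length: float
    bend_angle: float = 0.0

    @property
    def curvature(self) -> float:
        return self.bend_angle / self.length

    def point(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        k = self.curvature
        out = np.zeros((t.size, 3))
        if abs(k) < 1e-12:
            out[:, 0] = t
        else:
            out[:, 0] = np.sin(k * t) / k
            out[:, 2] = (1.0 - np.cos(k * t)) / k
        return out

    def tangent(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        k = self.curvature
        out = np.zeros((t.size, 3))
        out[:, 0] = np.cos(k * t)
        out[:, 2] = np.sin(k * t)
        return out

    def frame(self, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Two unit normals spanning the section plane at t (RMF for a planar arc)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        k = self.curvature
        # chosen so that (n1, n2, tangent) is right-handed: n1 x n2 = tangent
        n1 = np.zeros((t.size, 3))
        n1[:, 0] = np.sin(k * t)
        n1[:, 2] = -np.cos(k * t)
        n2 = np.tile(np.array([0.0, 1.0, 0.0]), (t.size, 1))
        return n1, n2


@dataclass
class SpineSolid:
    """Analytic radius profile of a spine along its (possibly bent) axis.

    Pieces, in order of increasing arc length t:

    - ``[0, stub_length]``           dendrite stub, radius ``stub_radius``
    - ``[stub_length, +blend_width]`` smoothstep from stub down to neck radius
    - core neck of length ``core_length`` with radius
      ``neck_radius_fn(u)`` for normalized position u in [0, 1]
    - spherical head of radius ``head_radius`` whose profile continues the
      neck radius at the junction and ends at the apex.
    """

    stub_length: float
    stub_radius: float
    blend_width: float
    core_length: float
    neck_radius_fn: Callable[[np.ndarray], np.ndarray]
    head_radius: float
    bend_angle: float = 0.0
    axis: ArcAxis = field(init=False)

    def __post_init__(self) -> None:
        r_j = float(self.neck_radius_fn(np.array([1.0]))[0])
        if r_j >= self.head_radius:
            raise ValueError(
                f"neck radius at junction ({r_j:.4g}) must be smaller than "
                f"head radius ({self.head_radius:.4g})"
            )
        self.t_core_start = self.stub_length + self.blend_width
        self.t_junction = self.t_core_start + self.core_length
        # sphere center placed so its profile equals the neck radius at the junction
        self.t_head_center = self.t_junction + float(
            np.sqrt(self.head_radius**2 - r_j**2)
        )
        self.t_apex = self.t_head_center + self.head_radius
        self.axis = ArcAxis(self.t_apex, self.bend_angle)

    # ------------------------------------------------------------------ profile
    def radius(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        r = np.empty_like(t)
        r0 = float(self.neck_radius_fn(np.array([0.0]))[0])

        stub = t < self.stub_length
        blend = (~stub) & (t < self.t_core_start)
        core = (~stub) & (~blend) & (t < self.t_junction)
        head = t >= self.t_junction

        r[stub] = self.stub_radius
        if blend.any():
            f = smoothstep((self.t_core_start - t[blend]) / self.blend_width)
            r[blend] = r0 + (self.stub_radius - r0) * f
        if core.any():
            u = (t[core] - self.t_core_start) / self.core_length
            r[core] = self.neck_radius_fn(u)
        if head.any():
            dt = np.minimum(np.abs(t[head] - self.t_head_center), self.head_radius)
            r[head] = np.sqrt(np.maximum(self.head_radius**2 - dt**2, 0.0))
        return r

    def diameter(self, t: np.ndarray | float) -> np.ndarray:
        return 2.0 * self.radius(t)

    def volume_between(self, t0: float, t1: float, n: int = 4001) -> float:
        """Enclosed volume between the section planes at t0 and t1 (Simpson)."""
        from scipy.integrate import simpson

        t = np.linspace(t0, t1, n)
        return float(simpson(np.pi * self.radius(t) ** 2, x=t))

    def total_volume(self) -> float:
        return self.volume_between(0.0, self.t_apex)

    # -------------------------------------------------- operational boundaries
    def threshold_crossings(self, threshold_diameter: float, n: int = 20001
                            ) -> tuple[float, float]:
        """First and last axis positions where the diameter is <= threshold.

        These are the operational neck boundaries under the "expands
        significantly" rule: the outermost positions whose diameter is still
        at or below the threshold.  Along-neck diameter variation may poke
        above the threshold in the interior; such excursions are bridged (they
        are neck, not head or dendrite).  The scan stops at the head center,
        mirroring a measured profile (a centerline ends at the point of
        maximal interior distance, i.e. the head center, so the apex taper is
        never reached and the flare on each side is monotone).
        """
        t = np.linspace(self.stub_length, self.t_head_center, n)
        d = self.diameter(t)
        below = d <= threshold_diameter
        if not below.any():
            raise ValueError("threshold below the entire profile; no neck region")
        idx = np.flatnonzero(below)
        lo, hi = t[idx[0]], t[idx[-1]]
        # refine by bisection against the continuous profile
        from scipy.optimize import brentq

        step = t[1] - t[0]

        def f(x: float) -> float:
            return float(self.diameter(x)[0]) - threshold_diameter

        if idx[0] > 0 and f(t[idx[0] - 1]) > 0:
            lo = brentq(f, t[idx[0] - 1], t[idx[0]], xtol=1e-9)
        if idx[-1] < n - 1 and f(t[idx[-1] + 1]) > 0:
            hi = brentq(f, t[idx[-1]], t[idx[-1] + 1], xtol=1e-9)
        del step
        return float(lo), float(hi)


# ---------------------------------------------------------------------- meshing
def sweep_mesh(solid: SpineSolid, resolution: float, n_theta: int = 28
               ) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the swept solid; returns (vertices, faces).

    Rings are placed every ``resolution`` along the tube and at matching
    angular steps over the head sphere; end caps are triangle fans to the base
    center (the base point) and the apex.  Ring vertices are radially inflated
    by :func:`polygon_radius_factor` so each ring polygon has exactly the
    intended cross-sectional area.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    # ring stations: fine steps where the radius varies (blend + neck core),
    # coarser in the constant-radius stub, uniform polar angle over the head
    coarse = max(resolution, 0.016)
    head_step = max(resolution, 0.008)
    t_stub = np.arange(0.0, solid.stub_length, coarse)
    t_fine = np.arange(solid.stub_length, solid.t_junction, resolution)
    t_tube = np.concatenate([t_stub, t_fine, [solid.t_junction]])
    cos_j = (solid.t_head_center - solid.t_junction) / solid.head_radius
    psi_j = np.arccos(np.clip(cos_j, -1.0, 1.0))
    n_head = max(10, int(np.ceil((np.pi - psi_j) * solid.head_radius / head_step)))
    psi = np.linspace(psi_j, np.pi, n_head + 1)[1:-1]  # junction ring already placed
    t_head = solid.t_head_center - solid.head_radius * np.cos(psi)
    t_rings = np.concatenate([t_tube, t_head])
    t_rings = np.unique(t_rings)

    radii = solid.radius(t_rings) * polygon_radius_factor(n_theta)
    centers = solid.axis.point(t_rings)
    n1, n2 = solid.axis.frame(t_rings)

    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    # (n_rings, n_theta, 3)
    verts = (
        centers[:, None, :]
        + radii[:, None, None] * (ct[None, :, None] * n1[:, None, :]
                                  + st[None, :, None] * n2[:, None, :])
    )
    n_rings = t_rings.size
    ring_verts = verts.reshape(-1, 3)
    base_center = solid.axis.point(0.0)[0]
    apex = solid.axis.point(solid.t_apex)[0]
    vertices = np.vstack([ring_verts, base_center[None, :], apex[None, :]])
    i_base = n_rings * n_theta
    i_apex = i_base + 1

    faces = []
    # base fan (outward = -tangent at t=0): wind so normals point out
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([i_base, jn, j])
    # side strips
    for i in range(n_rings - 1):
        a0 = i * n_theta
        b0 = (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a0 + j, a0 + jn, b0 + j])
            faces.append([a0 + jn, b0 + jn, b0 + j])
    # apex fan
    last = (n_rings - 1) * n_theta
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([last + j, last + jn, i_apex])
    return vertices, np.asarray(faces, dtype=np.int64)
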