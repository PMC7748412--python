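"""Helper constructors shared across test modules."""

from __future__ import annotations

import numpy as np

from spinemorph.geometry import SpineSolid, sweep_mesh
from spinemorph.meshio import SpineMesh


def constant_radius(r: float):
    return lambda u: np.full_like(np.asarray(u, dtype=float), r)


def build_spine_mesh(d0: float = 0.2, length: float = 1.0, rh: float = 0.3,
                     bend_deg: float = 0.0, resolution: float = 0.01,
                     radius_fn=None) -> tuple[SpineSolid, SpineMesh]:
    solid = SpineSolid(stub_length=0.25, stub_radius=max(0.22, 0.9 * d0),
                       blend_width=0.04, core_length=length,
                       neck_radius_fn=radius_fn or constant_radius(d0 / 2.0),
                       head_radius=rh, bend_angle=np.deg2rad(bend_deg))
    v, f = sweep_mesh(solid, resolution)
    mesh = SpineMesh(v, f, solid.axis.point(0.0)[0], "fixture").validate()
    return solid, mesh
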