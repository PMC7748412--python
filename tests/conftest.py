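"""Shared fixtures: canonical analytic spines and small seeded populations."""

from __future__ import annotations

import pytest

from helpers import build_spine_mesh
from spinemorph.synthetic import cryo_default_spec, sample_population


@pytest.fixture(scope="session")
def straight_spine():
    """Cylindrical neck d=0.2 um, L=1 um, spherical head r=0.3 um."""
    return build_spine_mesh(d0=0.2, length=1.0, rh=0.3)


@pytest.fixture(scope="session")
def bent_spine():
    """Same spine with the standard mild 30-degree axis bend."""
    return build_spine_mesh(d0=0.2, length=1.0, rh=0.3, bend_deg=30.0)


@pytest.fixture(scope="session")
def small_cryo_population():
    """Eight cryo-condition spines with within-spine diameter variation."""
    return sample_population(cryo_default_spec(n_spines=8, seed=11))
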