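"""Shared fixtures: geometries, phantom scenarios, and a small envelope."""

from __future__ import annotations

import numpy as np
import pytest

from gridfit import ArrayGeometry, ElectrodeSet
from gridfit.brainshift import compute_sce
from gridfit.simulate import Placement, make_phantom_surface, place_array


@pytest.fixture
def grid_geometry() -> ArrayGeometry:
    return ArrayGeometry("grid", 4, 4, 10.0)


@pytest.fixture
def strip_geometry() -> ArrayGeometry:
    return ArrayGeometry("strip", 1, 6, 5.0)


@pytest.fixture
def depth_geometry() -> ArrayGeometry:
    return ArrayGeometry("depth", 1, 8, 3.0)


@pytest.fixture(scope="session")
def sphere_sce():
    """Envelope of a lightly corrugated sphere phantom (session-cached)."""
    pial = make_phantom_surface("gyral", size=50.0, gyral_amplitude=2.0, gyral_wavelength=25.0)
    return compute_sce(pial, closing_radius=50.0, voxel_size=2.0)


@pytest.fixture(scope="session")
def shifted_grid_on_sphere():
    """A 4x6 grid draped at radius 50 then rigidly shifted 6 mm inward."""
    g = ArrayGeometry("grid", 4, 6, 10.0)
    truth = place_array(
        g, None, Placement(direction=np.array([0.0, 0.0, 1.0])), sphere_radius=50.0
    )
    n = truth.coordinates.mean(axis=0)
    n /= np.linalg.norm(n)
    shifted = ElectrodeSet(truth.coordinates - 6.0 * n, g, provenance="gridfit")
    return truth, shifted


def rigid_motion(rng: np.random.Generator):
    """Random proper rotation + translation."""
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    return lambda x: x @ q.T + t
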