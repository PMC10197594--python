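"""Energy terms against brute-force double-loop oracles and hand values."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import convolve2d

from gridfit import ArrayGeometry, VoxelCloud, build_grid_model, build_model, connection_ratio
from gridfit.energies import (
    LAPLACIAN_2D,
    anchor_energy,
    correlation_energy,
    deformation_energy,
    energy_correlation,
    energy_deformation,
    energy_translation,
    roughness_energy,
    translation_energy,
)

from conftest import rigid_motion


# ---------------------------------------------------------------------------
# independent brute-force implementations

def brute_translation(points, m0):
    return sum(np.dot(a - b, a - b) for a, b in zip(m0, points)) / len(points)


def brute_deformation(points, connections, rest):
    total = 0.0
    for c, d0 in zip(connections, rest):
        d = np.linalg.norm(points[c.j] - points[c.k])
        total += c.alpha * ((d0 - d) / d0) ** 2
    return total / len(connections)


def brute_correlation(elec, vox, w, sigma, u, n_mod):
    total = 0.0
    for n in range(len(vox)):
        for j in range(len(elec)):
            r2 = np.dot(vox[n] - elec[j], vox[n] - elec[j])
            total += w[n] * u[j] * np.exp(-r2 / (2 * sigma**2))
    return total / (n_mod * w.sum() * sigma * np.sqrt(2 * np.pi))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_energies_match_bruteforce(seed):
    """Vectorized terms equal naive double loops to 1e-10 on random instances."""
    rng = np.random.default_rng(seed)
    geometry = ArrayGeometry("grid", 4, 5, 8.0)
    model = build_grid_model(geometry)
    pts = model.points + rng.normal(scale=0.8, size=model.points.shape)
    vox = rng.uniform(-25, 25, size=(200, 3))
    w = rng.uniform(0.0, 1.0, size=200)
    u = connection_ratio(model)

    assert translation_energy(pts, model.points) == pytest.approx(
        brute_translation(pts, model.points), abs=1e-10
    )
    assert deformation_energy(
        pts, model.connection_pairs, model.alphas, model.rest_lengths
    ) == pytest.approx(brute_deformation(pts, model.connections, model.rest_lengths), abs=1e-10)
    assert correlation_energy(
        pts[model.electrode_index], vox, w, 5.0, u, model.n_points
    ) == pytest.approx(
        brute_correlation(pts[model.electrode_index], vox, w, 5.0, u, model.n_points),
        abs=1e-10,
    )


class TestTranslation:
    def test_at_rest_zero(self):
        model = build_grid_model(ArrayGeometry("grid", 2, 2, 10.0))
        assert energy_translation(model) == 0.0

    def test_uniform_half_mm(self):
        model = build_grid_model(ArrayGeometry("grid", 2, 2, 10.0))
        shifted = model.with_points(model.points + [0.5, 0.0, 0.0])
        assert energy_translation(shifted) == pytest.approx(0.25)

    def test_single_point_two_mm(self):
        model = build_grid_model(ArrayGeometry("grid", 2, 2, 10.0))
        pts = model.points.copy()
        pts[0, 2] += 2.0
        assert energy_translation(model.with_points(pts)) == pytest.approx(1.0)


class TestDeformation:
    def test_rigid_motion_zero(self):
        rng = np.random.default_rng(5)
        model = build_model(ArrayGeometry("grid", 3, 4, 10.0))
        moved = model.with_points(rigid_motion(rng)(model.points))
        assert energy_deformation(moved) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scaling_all_alpha_one(self):
        from gridfit import ConnectionWeights

        model = build_grid_model(
            ArrayGeometry("grid", 3, 3, 10.0), ConnectionWeights(1.0, 1.0, 1.0)
        )
        scaled = model.with_points(model.points * 1.1)
        assert energy_deformation(scaled) == pytest.approx(0.01, abs=1e-12)

    def test_uniform_scaling_mixed_alpha(self):
        model = build_grid_model(ArrayGeometry("grid", 3, 3, 10.0))
        scaled = model.with_points(model.points * 1.1)
        expected = 0.01 * model.alphas.sum() / model.n_connections
        assert energy_deformation(scaled) == pytest.approx(expected, abs=1e-12)


class TestCorrelation:
    def test_coincident_single_pair(self):
        """One contact on one unit voxel, sigma=1: E = 1/sqrt(2 pi)."""
        e = correlation_energy(
            np.zeros((1, 3)), np.zeros((1, 3)), np.ones(1), 1.0, np.ones(1), 1
        )
        assert e == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-12)

    def test_far_field_vanishes(self):
        e = correlation_energy(
            np.array([[100.0, 0, 0]]), np.zeros((1, 3)), np.ones(1), 1.0, np.ones(1), 1
        )
        assert e < 1e-10

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(2)
        model = build_grid_model(ArrayGeometry("grid", 2, 3, 10.0))
        cloud = VoxelCloud(rng.uniform(-10, 10, (50, 3)), rng.uniform(0.1, 1, 50))
        u = connection_ratio(model)
        e1 = energy_correlation(model, cloud, 5.0, u)
        doubled = VoxelCloud(cloud.coordinates, 2 * cloud.intensities)
        assert energy_correlation(model, doubled, 5.0, u) == pytest.approx(e1, rel=1e-12)


class TestAnchor:
    def test_identity_zero_and_unit_displacement(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-10, 10, (6, 3))
        assert anchor_energy(coords, coords) == 0.0
        off = coords + np.array([1.0, 0.0, 0.0])
        assert anchor_energy(coords, off) == pytest.approx(1.0)
        assert anchor_energy(off, coords) == pytest.approx(anchor_energy(coords, off))


class TestRoughness:
    def test_undeformed_and_uniform_expansion_zero(self):
        g = ArrayGeometry("grid", 5, 5, 10.0)
        pts = build_grid_model(g).points
        assert roughness_energy(pts, g) == 0.0
        assert roughness_energy(pts * 1.1, g) == pytest.approx(0.0, abs=1e-20)

    def test_single_stretched_connection_matches_convolution_oracle(self):
        """One horizontal link of a 5x5 grid stretched 1 mm: direct conv2 check."""
        g = ArrayGeometry("grid", 5, 5, 10.0)
        pts = build_grid_model(g).points.reshape(5, 5, 3).copy()
        pts[2, 3:, 0] += 1.0  # stretches connection (2,2)-(2,3) only
        flat = pts.reshape(-1, 3)
        # oracle: build G matrices explicitly, convolve, average over NAdj
        e3 = flat.reshape(5, 5, 3)
        dh = np.linalg.norm(e3[:, 1:] - e3[:, :-1], axis=2)
        dv = np.linalg.norm(e3[1:] - e3[:-1], axis=2)
        gh, gv = 10.0 - dh, 10.0 - dv
        lh = convolve2d(gh, LAPLACIAN_2D, mode="valid")
        lv = convolve2d(gv, LAPLACIAN_2D, mode="valid")
        n_adj = 5 * 4 + 4 * 5
        expected = (np.sum(lh**2) + np.sum(lv**2)) / n_adj
        assert expected > 0
        assert roughness_energy(flat, g) == pytest.approx(expected, abs=1e-12)

    def test_chain_uses_1d_stencil(self):
        g = ArrayGeometry("strip", 1, 6, 10.0)
        chain = np.column_stack([np.arange(6) * 10.0, np.zeros(6), np.zeros(6)])
        assert roughness_energy(chain, g) == 0.0
        bent = chain.copy()
        bent[3, 0] += 1.0  # gaps become [10 10 11 9 10]; G = [0 0 -1 1 0]
        # L = conv([0,0,-1,1,0], [1,-2,1], valid) = [-1, 3, -3]; NAdj = 5
        assert roughness_energy(bent, g) == pytest.approx((1 + 9 + 9) / 5.0)

    def test_transposed_layout_matches(self):
        g = ArrayGeometry("grid", 5, 4, 10.0)
        gt = ArrayGeometry("grid", 4, 5, 10.0)
        rng = np.random.default_rng(3)
        pts = build_grid_model(gt).points + rng.normal(scale=0.3, size=(20, 3))
        transposed = pts.reshape(4, 5, 3).transpose(1, 0, 2).reshape(-1, 3)
        assert roughness_energy(pts, gt) == pytest.approx(
            roughness_energy(transposed, g), abs=1e-12
        )


def test_gradients_match_finite_differences():
    """Analytic gradients of every term agree with central differences."""
    rng = np.random.default_rng(9)
    g = ArrayGeometry("grid", 4, 5, 10.0)
    model = build_grid_model(g)
    pts = model.points + rng.normal(scale=0.4, size=model.points.shape)
    vox = rng.uniform(-20, 20, (80, 3))
    w = rng.uniform(0.1, 1, 80)
    u = connection_ratio(model)

    cases = [
        (lambda p: translation_energy(p, model.points, grad=True), None),
        (
            lambda p: deformation_energy(
                p, model.connection_pairs, model.alphas, model.rest_lengths, grad=True
            ),
            None,
        ),
        (lambda p: correlation_energy(p, vox, w, 4.0, u[: len(p)], 20, grad=True), "elec"),
        (lambda p: roughness_energy(p, g, grad=True), None),
        (lambda p: anchor_energy(p, model.points, grad=True), None),
    ]
    h = 1e-6
    for fun, _ in cases:
        e0, grad = fun(pts)
        for idx in [(0, 0), (7, 1), (19, 2)]:
            stepped = pts.copy()
            stepped[idx] += h
            back = pts.copy()
            back[idx] -= h
            fd = (fun(stepped)[0] - fun(back)[0]) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)
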