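"""Localization error, batch accuracy, dispersion, and projection diagnostics."""

from __future__ import annotations

import numpy as np
import pytest

from gridfit import ArrayGeometry, ElectrodeSet
from gridfit.metrics import (
    EvaluationReport,
    accuracy_to_mean_error,
    anatomical_labels,
    batch_accuracy,
    estimated_hfa,
    ied_mad,
    local_deformation,
    localization_error,
    projection_distance,
)
from gridfit.simulate import make_phantom_surface

from conftest import rigid_motion


def _lattice_set(geometry: ArrayGeometry) -> ElectrodeSet:
    ys, xs = np.meshgrid(np.arange(geometry.n_rows), np.arange(geometry.n_cols), indexing="ij")
    coords = np.column_stack(
        [xs.ravel() * geometry.ied, ys.ravel() * geometry.ied, np.zeros(geometry.n_elec)]
    )
    return ElectrodeSet(coords, geometry)


class TestLocalizationError:
    def test_identical_sets_zero(self):
        s = _lattice_set(ArrayGeometry("grid", 3, 3, 10.0))
        rep = localization_error(s, s)
        assert rep.d_loc_med == 0.0 and rep.d_loc_max == 0.0

    def test_single_offset_contact(self):
        s = _lattice_set(ArrayGeometry("grid", 3, 3, 10.0))
        moved = s.coordinates.copy()
        moved[4, 2] += 5.0  # D/2, center contact (symmetry-invariant spot)
        rep = localization_error(s, s.with_coordinates(moved))
        assert rep.d_loc_med == 0.0
        assert rep.d_loc_max == pytest.approx(0.5)

    def test_mean_error_conversion(self):
        """0.24 mm mean error corresponds to 92% accuracy at 3 mm spacing."""
        g = ArrayGeometry("grid", 3, 3, 3.0)
        s = _lattice_set(g)
        moved = s.coordinates + np.array([0.24, 0.0, 0.0])
        rep = localization_error(s, s.with_coordinates(moved), resolve_symmetry=False)
        assert rep.d_loc_med == pytest.approx(0.08)
        assert rep.accuracy == pytest.approx(0.92)
        assert accuracy_to_mean_error(rep.accuracy, 3.0) == pytest.approx(0.24)

    def test_cardinality_mismatch(self):
        a = _lattice_set(ArrayGeometry("grid", 3, 3, 10.0))
        b = _lattice_set(ArrayGeometry("grid", 2, 2, 10.0))
        with pytest.raises(ValueError):
            localization_error(a, b)

    def test_symmetry_relabeling_only_permutes(self):
        """A flipped but otherwise exact fit scores zero error."""
        s = _lattice_set(ArrayGeometry("grid", 3, 4, 10.0))
        flipped = s.coordinates.reshape(3, 4, 3)[::-1, ::-1].reshape(-1, 3)
        rep = localization_error(s, s.with_coordinates(flipped))
        assert rep.d_loc_max == 0.0


class TestBatchAccuracy:
    def test_uniform_batch(self):
        reports = [EvaluationReport(0.03, 0.05) for _ in range(10)]
        acc, rejected = batch_accuracy(reports)
        assert acc == pytest.approx(0.97)
        assert rejected == 0

    def test_extreme_outlier_rejected(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.03, 0.002, size=50).clip(0.001)
        reports = [EvaluationReport(float(v), float(v)) for v in vals]
        reports.append(EvaluationReport(5.0, 5.0))
        acc, rejected = batch_accuracy(reports)
        assert rejected == 1
        assert reports[-1].outlier
        assert acc == pytest.approx(1.0 - np.median(vals), abs=1e-9)


class TestIedMad:
    def test_regular_lattice_zero(self):
        s = _lattice_set(ArrayGeometry("grid", 4, 4, 10.0))
        assert ied_mad(s) == 0.0

    def test_uneven_chain(self):
        g = ArrayGeometry("strip", 1, 3, 10.0)
        coords = np.array([[0.0, 0, 0], [9.0, 0, 0], [20.0, 0, 0]])  # gaps 9, 11
        assert ied_mad(ElectrodeSet(coords, g)) == pytest.approx(1.0)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        s = _lattice_set(ArrayGeometry("grid", 3, 4, 10.0))
        moved = s.with_coordinates(rigid_motion(rng)(s.coordinates))
        assert ied_mad(moved) == pytest.approx(ied_mad(s), abs=1e-9)


class TestProjectionDistance:
    def test_zero_and_ratio_and_scale_invariance(self):
        g = ArrayGeometry("strip", 1, 3, 10.0)
        pre = ElectrodeSet(np.array([[70.0, 0, 0], [70, 10, 0], [70, 20, 0]]), g)
        assert np.allclose(projection_distance(pre, pre, np.zeros(3)), 0.0)
        post = pre.with_coordinates(pre.coordinates + [7.0, 0, 0])
        d = projection_distance(pre, post, np.zeros(3))
        assert d[0] == pytest.approx(0.1)
        pre2 = pre.with_coordinates(pre.coordinates * 2)
        post2 = post.with_coordinates(post.coordinates * 2)
        assert np.allclose(projection_distance(pre2, post2, np.zeros(3)), d)

    def test_center_collision_rejected(self):
        g = ArrayGeometry("strip", 1, 3, 10.0)
        pre = ElectrodeSet(np.array([[0.0, 0, 0], [10, 0, 0], [20, 0, 0]]), g)
        with pytest.raises(ValueError):
            projection_distance(pre, pre, np.zeros(3))


class TestLocalDeformation:
    def test_undeformed_and_uniform_expansion(self):
        s = _lattice_set(ArrayGeometry("grid", 4, 4, 10.0))
        assert np.allclose(local_deformation(s), 1.0)
        expanded = s.with_coordinates(s.coordinates * 1.1)
        assert np.allclose(local_deformation(expanded), 1.1)

    def test_neighbor_counts_enter_average(self):
        g = ArrayGeometry("grid", 3, 3, 10.0)
        s = _lattice_set(g)
        # corner has 2 first neighbors, center 4: stretching one row spacing
        # changes them by different fractions of their own averages
        coords = s.coordinates.copy()
        coords[6:, 1] += 1.0
        out = local_deformation(s.with_coordinates(coords))
        assert out[0] == pytest.approx(1.0)  # corner in unstretched rows
        assert out[3] > 1.0


class TestEstimatedHfa:
    def test_monotone_in_distance(self):
        pial = make_phantom_surface("sphere", size=50.0)
        g = ArrayGeometry("strip", 1, 3, 10.0)
        coords = np.array([[51.0, 0, 0], [0, 60.0, 0], [0, 0, 55.0]])
        scores = estimated_hfa(ElectrodeSet(coords, g), pial)
        dists = np.array([1.0, 10.0, 5.0])
        assert np.array_equal(np.argsort(scores), np.argsort(-dists))

    def test_equal_distances_equal_scores(self):
        pial = make_phantom_surface("sphere", size=50.0)
        g = ArrayGeometry("strip", 1, 2, 10.0)
        coords = np.array([[55.0, 0, 0], [0, 55.0, 0]])
        scores = estimated_hfa(ElectrodeSet(coords, g), pial)
        assert scores[0] == pytest.approx(scores[1], abs=1e-3)


class TestAnatomicalLabels:
    def _volume(self):
        vol = np.zeros((40, 40, 40), dtype=int)
        vol[:, :, :] = 7  # homogeneous region label
        affine = np.eye(4)
        affine[:3, 3] = -20.0  # 1 mm voxels centered at origin
        return vol, affine

    def test_homogeneous_region(self):
        vol, aff = self._volume()
        g = ArrayGeometry("strip", 1, 2, 10.0)
        s = ElectrodeSet(np.array([[0.0, 0, 0], [5.0, 0, 0]]), g)
        out = anatomical_labels(s, vol, aff, radius=3.0)
        assert out[0] == {7: 1.0}

    def test_half_space_boundary(self):
        vol, aff = self._volume()
        vol[20:, :, :] = 9  # plane x >= 0 has the other label
        g = ArrayGeometry("strip", 1, 2, 10.0)
        s = ElectrodeSet(np.array([[-0.5, 0.0, 0.0], [5.0, 0, 0]]), g)
        out = anatomical_labels(s, vol, aff, radius=3.0)
        # contact on the boundary plane (voxel centers at -19.5..): ~50/50
        assert out[0][7] == pytest.approx(0.5, abs=0.1)
        assert out[0][9] == pytest.approx(0.5, abs=0.1)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        vol, aff = self._volume()
        vol[:] = rng.integers(0, 5, size=vol.shape)
        g = ArrayGeometry("strip", 1, 2, 10.0)
        s = ElectrodeSet(np.array([[0.0, 0, 0], [3.0, 2.0, -1.0]]), g)
        for d in anatomical_labels(s, vol, aff, radius=3.0):
            assert sum(d.values()) == pytest.approx(1.0, abs=1e-9)

    def test_outside_volume_rejected(self):
        vol, aff = self._volume()
        g = ArrayGeometry("strip", 1, 2, 10.0)
        s = ElectrodeSet(np.array([[500.0, 0, 0], [5.0, 0, 0]]), g)
        with pytest.raises(ValueError):
            anatomical_labels(s, vol, aff)
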