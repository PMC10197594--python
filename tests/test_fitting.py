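"""PCA alignment, smooth approximations, initial estimates, and the two-step fit."""

from __future__ import annotations

import numpy as np
import pytest

from gridfit import (
    ArrayGeometry,
    FitConfig,
    VoxelCloud,
    fit_line,
    fit_surface,
    gridfit,
    initial_depth_estimate,
    initial_grid_estimate,
    pca_align,
)
from gridfit.fitting import (
    FitError,
    InfeasibleFixedError,
    calibrate_kcorr,
    first_fit,
    second_fit,
    _placed_model,
)
from gridfit.metrics import localization_error
from gridfit.simulate import SimCondition, make_scenario

from conftest import rigid_motion


def _uniform_cloud(rng, n=300):
    pts = rng.normal(size=(n, 3)) * [10.0, 4.0, 1.0]
    return VoxelCloud(pts, rng.uniform(0.2, 1.0, n)).normalize()


class TestPcaAlign:
    def test_axis_aligned_cloud_keeps_axes(self):
        rng = np.random.default_rng(0)
        cloud = _uniform_cloud(rng)
        aligned, tr = pca_align(cloud)
        # already sorted variances: rotation is a signed permutation near identity
        assert np.allclose(np.abs(tr.rotation), np.eye(3), atol=0.15)

    def test_variances_nonincreasing(self):
        rng = np.random.default_rng(1)
        cloud = VoxelCloud(rng.normal(size=(200, 3)) * [2.0, 9.0, 5.0], np.ones(200))
        aligned, _ = pca_align(cloud)
        var = aligned.coordinates.var(axis=0)
        assert var[0] >= var[1] >= var[2]

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        cloud = _uniform_cloud(rng)
        aligned, tr = pca_align(cloud)
        back = tr.invert(aligned.coordinates)
        assert np.allclose(back, cloud.coordinates, atol=1e-9)

    def test_collinear_flag(self):
        x = np.linspace(0, 30, 50)
        cloud = VoxelCloud(np.column_stack([x, np.zeros(50), np.zeros(50)]), np.ones(50))
        _, tr = pca_align(cloud)
        assert tr.is_collinear


class TestFitSurface:
    def test_flat_plane_recovered(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(-20, 20, (400, 2))
        cloud = VoxelCloud(np.column_stack([xy, np.zeros(400)]), np.ones(400))
        f = fit_surface(cloud)
        q = rng.uniform(-15, 15, (50, 2))
        assert np.max(np.abs(f(q[:, 0], q[:, 1]))) < 1e-6

    def test_tilted_plane(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(-20, 20, (500, 2))
        z = xy[:, 0]  # z = x
        f = fit_surface(VoxelCloud(np.column_stack([xy, z]), np.ones(500)))
        q = rng.uniform(-12, 12, (50, 2))
        assert np.max(np.abs(f(q[:, 0], q[:, 1]) - q[:, 0])) < 1e-3

    def test_paraboloid_interior_residuals(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-20, 20, (2000, 2))
        z = (xy[:, 0] ** 2 + xy[:, 1] ** 2) / 100.0
        f = fit_surface(VoxelCloud(np.column_stack([xy, z]), np.ones(2000)), 0.3)
        q = rng.uniform(-12, 12, (100, 2))
        pred = f(q[:, 0], q[:, 1])
        truth = (q[:, 0] ** 2 + q[:, 1] ** 2) / 100.0
        assert np.max(np.abs(pred - truth)) < 0.1

    def test_degenerate_footprint_rejected(self):
        cloud = VoxelCloud(
            np.column_stack([np.linspace(0, 10, 20), np.zeros(20), np.zeros(20)]),
            np.ones(20),
        )
        with pytest.raises(FitError):
            fit_surface(cloud)


class TestFitLine:
    def test_linear_recovery(self):
        x = np.linspace(-10, 10, 40)
        cloud = VoxelCloud(np.column_stack([x, 2 * x + 1, np.zeros(40)]), np.ones(40))
        f = fit_line(cloud)
        assert np.allclose(f.coefficients, [0, 0, 2, 1], atol=1e-9)

    def test_cubic_recovery(self):
        x = np.linspace(-10, 10, 40)
        cloud = VoxelCloud(np.column_stack([x, 0.01 * x**3, np.zeros(40)]), np.ones(40))
        f = fit_line(cloud)
        assert f.coefficients[0] == pytest.approx(0.01, abs=1e-6)

    def test_constant_x_rejected(self):
        cloud = VoxelCloud(
            np.column_stack([np.ones(10), np.linspace(0, 5, 10), np.zeros(10)]), np.ones(10)
        )
        with pytest.raises(FitError):
            fit_line(cloud)


class TestInitialEstimates:
    def _grid_cloud(self, geometry, jitter=0.0, seed=0):
        """Noise-free voxel lattice over the grid footprint."""
        rng = np.random.default_rng(seed)
        nr, nc, D = geometry.n_rows, geometry.n_cols, geometry.ied
        ys, xs = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        centers = np.column_stack(
            [
                xs.ravel() * D - (nc - 1) * D / 2,
                ys.ravel() * D - (nr - 1) * D / 2,
                np.zeros(nr * nc),
            ]
        )
        vox = []
        for c in centers:
            offs = rng.uniform(-0.5, 0.5, (20, 3)) * [1, 1, 0.2]
            vox.append(c + offs)
        return VoxelCloud(np.vstack(vox), np.ones(20 * nr * nc)).normalize()

    def test_corners_recovered_on_planar_lattice(self):
        """One voxel per contact, exactly on the lattice: corners come out exact."""
        g = ArrayGeometry("grid", 4, 4, 10.0)
        lattice = self._true_lattice(g)
        cloud = VoxelCloud(lattice, np.ones(len(lattice))).normalize()
        f = fit_surface(cloud)
        e0 = initial_grid_estimate(cloud, g, f)
        report = localization_error(e0, e0.with_coordinates(lattice))
        assert report.d_loc_max * g.ied < 0.25  # half a 0.5 mm voxel

    @staticmethod
    def _true_lattice(g):
        ys, xs = np.meshgrid(np.arange(g.n_rows), np.arange(g.n_cols), indexing="ij")
        return np.column_stack(
            [
                xs.ravel() * g.ied - (g.n_cols - 1) * g.ied / 2,
                ys.ravel() * g.ied - (g.n_rows - 1) * g.ied / 2,
                np.zeros(g.n_elec),
            ]
        )

    def test_count_and_on_surface(self):
        g = ArrayGeometry("grid", 4, 5, 10.0)
        cloud = self._grid_cloud(g)
        f = fit_surface(cloud)
        e0 = initial_grid_estimate(cloud, g, f)
        assert e0.coordinates.shape == (20, 3)
        z = f(e0.coordinates[:, 0], e0.coordinates[:, 1])
        assert np.max(np.abs(e0.coordinates[:, 2] - z)) < 1e-6

    def test_depth_uniform_spacing(self):
        g = ArrayGeometry("depth", 1, 6, 5.0)
        x = np.linspace(-12.5, 12.5, 200)
        cloud = VoxelCloud(
            np.column_stack([x, np.zeros(200), np.zeros(200)]), np.ones(200)
        )
        f = fit_line(cloud)
        e0 = initial_depth_estimate(cloud, g, f)
        gaps = np.diff(e0.coordinates[:, 0])
        assert np.allclose(gaps, gaps[0], atol=1e-9)
        assert e0.coordinates[:, 0].min() == pytest.approx(-12.5)

    def test_rotation_equivariance_through_pipeline(self):
        """Rigidly rotating the input cloud rigidly rotates the initial estimate."""
        cond = SimCondition(ArrayGeometry("grid", 4, 4, 10.0), "none")
        s = make_scenario(cond, 3)
        rng = np.random.default_rng(8)
        motion = rigid_motion(rng)
        res1 = gridfit(s.cloud, cond.geometry, FitConfig(k_corr=3e3), return_details=True)
        moved = VoxelCloud(motion(s.cloud.coordinates), s.cloud.intensities)
        res2 = gridfit(moved, cond.geometry, FitConfig(k_corr=3e3), return_details=True)
        # compare as unordered sets: PCA axes may relabel rows/columns
        a = np.sort(np.round(motion(res1.e0.coordinates), 4).view("f8,f8,f8"), axis=0)
        b = np.sort(np.round(res2.e0.coordinates, 4).view("f8,f8,f8"), axis=0)
        assert np.allclose(
            np.array(a.tolist()).reshape(-1, 3), np.array(b.tolist()).reshape(-1, 3), atol=1e-2
        )


class TestFirstFit:
    def test_surface_constraint_satisfied(self):
        cond = SimCondition(ArrayGeometry("grid", 4, 4, 10.0), "none")
        s = make_scenario(cond, 1)
        aligned, _ = pca_align(s.cloud.normalize())
        f = fit_surface(aligned)
        e0 = initial_grid_estimate(aligned, cond.geometry, f)
        model = _placed_model(cond.geometry, e0, None, FitConfig().weights)
        e_first, _, _ = first_fit(model, aligned, f, FitConfig(k_corr=3e3))
        z = f(e_first.coordinates[:, 0], e_first.coordinates[:, 1])
        assert np.max(np.abs(e_first.coordinates[:, 2] - z)) < 1.0  # eps_step1

    def test_recovers_noise_free_grid_roughly(self):
        cond = SimCondition(ArrayGeometry("grid", 4, 4, 10.0), "none")
        s = make_scenario(cond, 2)
        res = gridfit(s.cloud, cond.geometry, FitConfig(k_corr=3e3), return_details=True)
        rep = localization_error(s.truth, res.e_first_fit)
        assert rep.d_loc_max < 0.2

    def test_zero_attraction_stays_at_projected_start(self):
        """With k_corr = 0 nothing pulls the lattice: the minimizer keeps e0."""
        cond = SimCondition(ArrayGeometry("grid", 4, 4, 10.0), "none")
        s = make_scenario(cond, 4)
        aligned, _ = pca_align(s.cloud.normalize())
        f = fit_surface(aligned)
        e0 = initial_grid_estimate(aligned, cond.geometry, f)
        model = _placed_model(cond.geometry, e0, None, FitConfig().weights)
        e_first, _, _ = first_fit(model, aligned, f, FitConfig(k_corr=0.0, k_trans=1.0))
        # the minimizer only rebalances translation against residual lattice
        # strain in e0; without attraction it cannot drift toward the voxels
        assert np.max(np.linalg.norm(e_first.coordinates - e0.coordinates, axis=1)) < 0.05 * 10.0


class TestSecondFit:
    def test_feasibility_and_accuracy_noise_free(self):
        cond = SimCondition(ArrayGeometry("grid", 4, 4, 10.0), "none")
        s = make_scenario(cond, 5)
        res = gridfit(s.cloud, cond.geometry, FitConfig(k_corr=3e3), return_details=True)
        rep = localization_error(s.truth, res.electrodes)
        assert rep.d_loc_med <= 0.05
        d = res.diagnostics
        assert d.feasible
        assert d.max_neighbor_strain < 0.10 + 1e-6

    def test_fixed_corners_pinned(self):
        cond = SimCondition(ArrayGeometry("grid", 4, 4, 10.0), "none")
        s = make_scenario(cond, 6)
        g = cond.geometry
        corners = np.array([0, 3, 12, 15])
        fixed = s.truth.coordinates[corners]
        out = gridfit(s.cloud, g, FitConfig(k_corr=3e3), fixed=fixed, fixed_index=corners)
        err = np.linalg.norm(out.coordinates[corners] - fixed, axis=1)
        assert np.max(err) < 0.01

    def test_infeasible_fixed_rejected(self):
        cond = SimCondition(ArrayGeometry("grid", 4, 4, 10.0), "none")
        s = make_scenario(cond, 7)
        fixed = np.array([[0.0, 0, 0], [100.0, 0, 0]])  # 100 mm apart on a 10 mm lattice
        with pytest.raises(InfeasibleFixedError):
            gridfit(
                s.cloud,
                cond.geometry,
                FitConfig(k_corr=3e3),
                fixed=fixed,
                fixed_index=np.array([0, 1]),
            )


class TestEndToEnd:
    def test_depth_noise_free_quarter_mm(self):
        cond = SimCondition(ArrayGeometry("depth", 1, 6, 5.0), "none")
        s = make_scenario(cond, 8)
        out = gridfit(s.cloud, cond.geometry)
        rep = localization_error(s.truth, out)
        assert rep.d_loc_max * cond.geometry.ied < 0.25  # mm

    def test_grid_medium_noise_within_bound(self):
        cond = SimCondition(ArrayGeometry("grid", 4, 8, 10.0), "medium")
        s = make_scenario(cond, 9)
        out = gridfit(s.cloud, cond.geometry)
        assert localization_error(s.truth, out).d_loc_med < 0.08

    def test_determinism(self):
        cond = SimCondition(ArrayGeometry("strip", 1, 6, 5.0), "high")
        s = make_scenario(cond, 10)
        a = gridfit(s.cloud, cond.geometry)
        b = gridfit(s.cloud, cond.geometry)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_energy_rigid_invariance(self):
        """Moving cloud + model together leaves the fitted solution equivariant."""
        cond = SimCondition(ArrayGeometry("depth", 1, 8, 3.0), "low")
        s = make_scenario(cond, 11)
        rng = np.random.default_rng(12)
        motion = rigid_motion(rng)
        out1 = gridfit(s.cloud, cond.geometry)
        moved = VoxelCloud(motion(s.cloud.coordinates), s.cloud.intensities)
        out2 = gridfit(moved, cond.geometry)
        rep = localization_error(
            out2, out2.with_coordinates(motion(out1.coordinates))
        )
        assert rep.d_loc_max < 0.02


class TestCalibration:
    def test_bad_candidate_rejected_and_interpolation_exact(self):
        conds = [SimCondition(ArrayGeometry("depth", 1, 8, 3.0), "medium")]
        from gridfit.simulate import generate_suite

        suite = generate_suite(conds, 3, 77)
        table = calibrate_kcorr(suite, [1e3, 1e7])
        g = conds[0].geometry
        assert table.lookup(g, False) == 1e3  # exact at the calibrated geometry
        row = table.table.iloc[0]
        assert row.median_error < 0.08

    def test_empty_suite_rejected(self):
        with pytest.raises(ValueError):
            calibrate_kcorr([], [1e3, 1e4])
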