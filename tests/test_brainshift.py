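"""Envelope construction, anchor projections, CEPA/Springs, depth correction."""

from __future__ import annotations

import numpy as np
import pytest

from gridfit import ArrayGeometry, ElectrodeSet
from gridfit.brainshift import (
    ProjectionConfig,
    compute_sce,
    correct_depth_shift,
    project_cepa,
    project_normal_grid,
    project_normal_sce,
    project_springs,
)
from gridfit.energies import energy_roughness
from gridfit.mesh import MeshQuery
from gridfit.metrics import local_deformation
from gridfit.simulate import make_phantom_surface


class TestComputeSce:
    def test_convex_sphere_maps_to_itself(self):
        """Closing a convex set returns it, up to voxelization."""
        pial = make_phantom_surface("sphere", size=40.0)
        sce = compute_sce(pial, closing_radius=50.0, voxel_size=2.0)
        r = np.linalg.norm(sce.vertices, axis=1)
        assert sce.is_watertight
        assert np.all(np.abs(r - 40.0) < 2.5)

    def test_envelope_encloses_pial(self, sphere_sce):
        pial = make_phantom_surface(
            "gyral", size=50.0, gyral_amplitude=2.0, gyral_wavelength=25.0
        )
        q = MeshQuery(sphere_sce)
        signed = q.signed_distance(pial.vertices[::50])
        assert np.all(signed < 2.0)  # inside or within one voxel of the envelope

    def test_sulcal_groove_bridged(self):
        """Deepening grooves (crowns untouched) barely moves the envelope."""

        def grooved(depth):
            base = make_phantom_surface("gyral", size=50.0, gyral_amplitude=1.0)
            v = base.vertices
            r = np.linalg.norm(v, axis=1)
            unit = v / r[:, None]
            wobble = np.sin(2 * np.pi * v[:, 0] / 25.0) * np.sin(2 * np.pi * v[:, 1] / 25.0)
            carve = depth * np.minimum(wobble, 0.0)  # only lowers, never raises
            return type(base)(unit * (r + carve)[:, None], base.faces)

        sce_a = compute_sce(grooved(0.0), 50.0, 2.0)
        sce_b = compute_sce(grooved(4.0), 50.0, 2.0)
        qa, qb = MeshQuery(sce_a), MeshQuery(sce_b)
        dirs = np.random.default_rng(0).normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ra = [np.abs(qa.ray_intersections(np.zeros(3), d)).max() for d in dirs]
        rb = [np.abs(qb.ray_intersections(np.zeros(3), d)).max() for d in dirs]
        assert np.max(np.abs(np.array(ra) - np.array(rb))) < 2.5


class TestNormalProjections:
    def test_flat_grid_drops_orthogonally(self):
        """Grid hovering 5 mm over a plane projects straight down."""
        plane = make_phantom_surface("plane", size=60.0)
        g = ArrayGeometry("grid", 3, 3, 10.0)
        ys, xs = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        coords = np.column_stack(
            [xs.ravel() * 10.0 - 10, ys.ravel() * 10.0 - 10, np.full(9, 5.0)]
        )
        anchors = project_normal_grid(ElectrodeSet(coords, g), plane)
        disp = coords - anchors.coordinates
        assert np.allclose(disp[:, :2], 0.0, atol=1e-6)
        assert np.allclose(disp[:, 2], 5.0, atol=1e-6)

    def test_sphere_projection_is_radial(self):
        sphere = make_phantom_surface("sphere", size=50.0)
        g = ArrayGeometry("strip", 1, 2, 10.0)
        coords = np.array([[0.0, 0.0, 60.0], [0.0, 42.0, 0.0]])
        anchors = project_normal_sce(ElectrodeSet(coords, g), sphere, radius=15.0)
        r = np.linalg.norm(anchors.coordinates, axis=1)
        assert np.allclose(r, 50.0, atol=0.5)
        # direction preserved = radial motion
        cos = np.einsum("ij,ij->i", anchors.coordinates, coords) / (
            r * np.linalg.norm(coords, axis=1)
        )
        assert np.all(cos > 0.9999)

    def test_point_on_surface_stays(self, sphere_sce):
        q = MeshQuery(sphere_sce)
        on, _, _ = q.closest_point(np.array([[0.0, 0.0, 55.0]]))
        g = ArrayGeometry("strip", 1, 2, 10.0)
        coords = np.vstack([on, on + [10, 0, 0]])
        anchors = project_normal_sce(ElectrodeSet(coords, g), sphere_sce, 15.0)
        assert np.linalg.norm(anchors.coordinates[0] - on[0]) < 0.5

    def test_strip_rejected_by_grid_method(self, sphere_sce):
        g = ArrayGeometry("strip", 1, 4, 10.0)
        coords = np.column_stack([np.arange(4) * 10.0, np.zeros(4), np.full(4, 55.0)])
        with pytest.raises(ValueError):
            project_normal_grid(ElectrodeSet(coords, g), sphere_sce)


class TestConstrainedProjections:
    def test_on_surface_input_with_self_anchors_unmoved(self, sphere_sce, shifted_grid_on_sphere):
        truth, _ = shifted_grid_on_sphere
        q = MeshQuery(sphere_sce)
        on_surface, _, _ = q.closest_point(truth.coordinates)
        coords = ElectrodeSet(on_surface, truth.geometry, provenance="gridfit")
        from gridfit.brainshift import AnchorMethod, AnchorSet

        anchors = [AnchorSet(on_surface.copy(), AnchorMethod.EXTERNAL)]
        out = project_cepa(coords, sphere_sce, anchors=anchors)
        assert np.max(np.linalg.norm(out.coordinates - on_surface, axis=1)) < 0.5

    def test_all_projectors_land_on_envelope(self, sphere_sce, shifted_grid_on_sphere):
        _, shifted = shifted_grid_on_sphere
        q = MeshQuery(sphere_sce)
        eps = ProjectionConfig().eps
        for out in (
            project_cepa(shifted, sphere_sce),
            project_springs(shifted, sphere_sce),
            project_normal_grid(shifted, sphere_sce).coordinates,
            project_normal_sce(shifted, sphere_sce, 15.0).coordinates,
        ):
            xyz = getattr(out, "coordinates", out)
            assert np.max(q.distance(xyz)) <= eps + 1e-9

    def test_expansion_ordering(self, sphere_sce, shifted_grid_on_sphere):
        """Springs expands least, the averaged-normal projection most."""
        _, shifted = shifted_grid_on_sphere
        g = shifted.geometry
        s_springs = local_deformation(project_springs(shifted, sphere_sce)).mean()
        s_cepa = local_deformation(project_cepa(shifted, sphere_sce)).mean()
        nsce = project_normal_sce(shifted, sphere_sce, 15.0)
        s_nsce = local_deformation(ElectrodeSet(nsce.coordinates, g)).mean()
        assert s_springs <= s_cepa <= s_nsce

    def test_roughness_not_above_orthogonal_methods(self, sphere_sce, shifted_grid_on_sphere):
        _, shifted = shifted_grid_on_sphere
        g = shifted.geometry
        er_cepa = energy_roughness(project_cepa(shifted, sphere_sce).coordinates, g)
        er_ng = energy_roughness(project_normal_grid(shifted, sphere_sce).coordinates, g)
        er_ns = energy_roughness(project_normal_sce(shifted, sphere_sce, 15.0).coordinates, g)
        assert er_cepa <= max(er_ng, er_ns)

    def test_springs_near_rigid(self, sphere_sce, shifted_grid_on_sphere):
        """Springs keeps inter-electrode distances close to the input's."""
        _, shifted = shifted_grid_on_sphere
        out = project_springs(shifted, sphere_sce)
        from gridfit.metrics import first_neighbor_pairs

        p = first_neighbor_pairs(shifted.geometry)
        d_in = np.linalg.norm(shifted.coordinates[p[:, 0]] - shifted.coordinates[p[:, 1]], axis=1)
        d_out = np.linalg.norm(out.coordinates[p[:, 0]] - out.coordinates[p[:, 1]], axis=1)
        assert np.max(np.abs(d_out - d_in) / d_in) < 0.10


class TestDepthShift:
    def _geometry(self, n):
        return ArrayGeometry("depth", 1, n, 3.0)

    def test_coincident_contact_inherits_translation(self):
        depth = ElectrodeSet(np.zeros((1, 3)), self._geometry(1))
        pre = np.zeros((1, 3))
        post = pre - np.array([[1.0, 0.0, 0.0]])  # t = pre - post = (1,0,0)
        out, flags = correct_depth_shift(depth, pre, post)
        assert np.allclose(out.coordinates[0], [1.0, 0.0, 0.0])
        assert not flags[0]

    def test_far_contact_unmoved_and_flagged(self):
        depth = ElectrodeSet(np.array([[300.0, 0, 0]]), self._geometry(1))
        pre = np.zeros((1, 3))
        post = pre - np.array([[1.0, 0.0, 0.0]])
        out, flags = correct_depth_shift(depth, pre, post)
        assert np.allclose(out.coordinates[0], [300.0, 0, 0])
        assert flags[0]

    def test_symmetric_translations_cancel(self):
        depth = ElectrodeSet(np.zeros((1, 3)), self._geometry(1))
        pre = np.array([[5.0, 0, 0], [-5.0, 0, 0]])
        post = pre - np.array([[1.0, 0, 0], [-1.0, 0, 0]])  # t and -t
        out, _ = correct_depth_shift(depth, pre, post)
        assert np.allclose(out.coordinates[0], 0.0, atol=1e-12)
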