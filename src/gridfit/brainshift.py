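"""Brain-shift compensation: projection of subdural arrays to the smooth
cortical envelope (SCE) and correction of co-implanted depth electrodes.

Post-implantation CT localizes contacts where the shifted brain put them,
up to 10-20 mm away from the pre-implantation MRI cortex.  Grids and strips
are known to lie on the brain surface, so compensation projects their
coordinates back to the SCE.  Four projectors are provided:

* ``project_springs`` - spring-mesh relaxation (translation + strong
  deformation penalty) constrained to the envelope;
* ``project_normal_grid`` - per-contact orthogonal projection along the
  local grid-plane normal (grids only);
* ``project_normal_sce`` - projection along the locally averaged envelope
  normal;
* ``project_cepa`` - the combined algorithm: spring mesh + anchor sets
  from the orthogonal methods + a spatial-roughness penalty, minimizing

      EProj = kTrans*ETrans + kDef*EDef + kAnch/NAnch * sum_u EAnch_u
              + kRough*ERough

  subject to every contact lying on the envelope (within eps = 0.1 mm).

Depth electrodes implanted together with grids inherit a weighted average
of the grid translation field (Gaussian weights in current distance and in
translation magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.measure import marching_cubes

from .arrays import ArrayGeometry, ArrayModel, ArrayType, build_grid_model
from .data import ElectrodeSet
from .energies import (
    LAPLACIAN_1D,
    LAPLACIAN_2D,
    anchor_energy,
    deformation_energy,
    roughness_energy,
    translation_energy,
)
from .mesh import MeshQuery, SurfaceMesh

__all__ = [
    "AnchorMethod",
    "AnchorSet",
    "ProjectionConfig",
    "ProjectionError",
    "compute_sce",
    "project_normal_grid",
    "project_normal_sce",
    "project_cepa",
    "project_springs",
    "correct_depth_shift",
    "projection_model",
]


class ProjectionError(RuntimeError):
    pass


class AnchorMethod(str, Enum):
    NORMAL_GRID = "normal_grid"
    NORMAL_SCE = "normal_sce"
    EXTERNAL = "external"


@dataclass
class AnchorSet:
    """Per-contact target coordinates on the envelope from one method."""

    coordinates: np.ndarray
    method: AnchorMethod
    fallback_mask: np.ndarray | None = None  # contacts that used nearest-vertex

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))


@dataclass(frozen=True)
class ProjectionConfig:
    """Weights and tolerances of the projection cost.

    Defaults: kTrans=1, kDef=kAnch=kRough=100 (combined method);
    the Springs baseline uses kTrans=1, kDef=1000 with anchors and
    roughness off.  eps is the on-surface tolerance (0.1 mm).  sigma_r and
    sigma_d regularize the depth-shift weight functions (5 mm / 30 mm).
    """

    k_trans: float = 1.0
    k_def: float = 100.0
    k_anch: float = 100.0
    k_rough: float = 100.0
    k_def_springs: float = 1000.0
    eps: float = 0.1
    normal_sce_radius: float = 15.0
    sigma_r: float = 5.0
    sigma_d: float = 30.0
    tol: float = 1e-6
    max_iterations: int = 300
    kernel2d: np.ndarray = field(default_factory=lambda: LAPLACIAN_2D.copy())
    kernel1d: np.ndarray = field(default_factory=lambda: LAPLACIAN_1D.copy())

    def __post_init__(self) -> None:
        for name in ("k_trans", "k_def", "k_anch", "k_rough", "k_def_springs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.eps <= 0 or self.normal_sce_radius <= 0:
            raise ValueError("eps and radii must be positive")


# ---------------------------------------------------------------------------
# smooth cortical envelope

def compute_sce(
    pial: SurfaceMesh,
    closing_radius: float = 50.0,
    voxel_size: float = 2.0,
    smooth_iterations: int = 10,
) -> SurfaceMesh:
    """Smooth cortical envelope by morphological closing of the pial surface.

    The pial interior is rasterized at ``voxel_size``, closed with a
    spherical structuring element of ``closing_radius`` (sulcal grooves
    narrower than the element are bridged, the convex outline is kept), and
    the outer isosurface is extracted with marching cubes.  Closing is done
    on Euclidean distance fields, so the element is a true sphere and the
    isosurface can be pulled at exactly ``closing_radius`` from the dilated
    set, giving a smooth watertight envelope that encloses the pial surface.
    """
    verts = pial.vertices
    lo = verts.min(axis=0) - 2 * voxel_size
    hi = verts.max(axis=0) + 2 * voxel_size
    pad = int(np.ceil(closing_radius / voxel_size)) + 2
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1 + 2 * pad
    origin = lo - pad * voxel_size

    # rasterize faces by subsampling each triangle
    occ = np.zeros(shape, dtype=bool)
    tris = verts[pial.faces]
    # sampling density ~ half-voxel along the longest edge
    edge = np.linalg.norm(tris[:, 1] - tris[:, 0], axis=1).max()
    n_sub = max(2, int(np.ceil(2 * edge / voxel_size)))
    bary_u, bary_v = np.meshgrid(np.linspace(0, 1, n_sub), np.linspace(0, 1, n_sub))
    keep = bary_u + bary_v <= 1.0
    bu, bv = bary_u[keep], bary_v[keep]
    samples = (
        tris[:, None, 0] * (1 - bu - bv)[None, :, None]
        + tris[:, None, 1] * bu[None, :, None]
        + tris[:, None, 2] * bv[None, :, None]
    ).reshape(-1, 3)
    idx = np.round((samples - origin) / voxel_size).astype(int)
    idx = idx[np.all((idx >= 0) & (idx < shape), axis=1)]
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    solid = ndimage.binary_fill_holes(occ)
    if solid.sum() <= occ.sum():
        raise ProjectionError("pial mesh does not enclose a volume (open surface?)")

    # closing via two distance transforms (true Euclidean ball)
    dist_to_solid = ndimage.distance_transform_edt(~solid, sampling=voxel_size)
    dilated = dist_to_solid <= closing_radius
    dist_inside = ndimage.distance_transform_edt(dilated, sampling=voxel_size)
    # erosion isosurface: points at depth == closing_radius inside the dilation
    v, f, _, _ = marching_cubes(dist_inside, level=closing_radius, spacing=(voxel_size,) * 3)
    mesh = SurfaceMesh(v + origin, f[:, ::-1]).trimesh  # flip for outward orientation
    # keep the largest component and lightly relax marching-cubes staircase
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: len(m.faces))
    if smooth_iterations:
        import trimesh.smoothing as sm

        sm.filter_taubin(mesh, iterations=smooth_iterations)
    mesh.fix_normals()
    return SurfaceMesh.from_trimesh(mesh)


# ---------------------------------------------------------------------------
# anchor projections

def _neighbor_normal(coords: np.ndarray, geometry: ArrayGeometry, j: int) -> np.ndarray:
    """Unit normal of the plane fit to contact j and its lattice neighbors."""
    nr, nc = geometry.n_rows, geometry.n_cols
    r, c = divmod(j, nc)
    nbrs = [j]
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < nr and 0 <= cc < nc:
            nbrs.append(rr * nc + cc)
    pts = coords[nbrs]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def project_normal_grid(coords: ElectrodeSet, sce: SurfaceMesh) -> AnchorSet:
    """Orthogonal projection along each contact's local grid-plane normal.

    Grids only: the normal comes from a plane fit to the contact and its
    first lattice neighbors; both ray directions are cast and the nearest
    envelope crossing wins.  Contacts whose ray misses fall back to the
    nearest surface point (flagged).
    """
    if coords.geometry.array_type is not ArrayType.GRID:
        raise ValueError("the grid-normal projection is only available for grids")
    q = MeshQuery(sce)
    out = np.empty_like(coords.coordinates)
    fallback = np.zeros(coords.n_elec, dtype=bool)
    for j, e in enumerate(coords.coordinates):
        n = _neighbor_normal(coords.coordinates, coords.geometry, j)
        hit = q.first_hit(e, n)
        if hit is None:
            hit, _, _ = q.closest_point(e)
            hit = hit[0]
            fallback[j] = True
        out[j] = hit
    return AnchorSet(out, AnchorMethod.NORMAL_GRID, fallback)


def project_normal_sce(
    coords: ElectrodeSet, sce: SurfaceMesh, radius: float = 15.0
) -> AnchorSet:
    """Orthogonal projection along the locally averaged envelope normal.

    The direction is the mean outward vertex normal of the envelope within
    ``radius`` of the contact (radius doubled once when empty); the contact
    is cast along +-direction to the nearest crossing, with nearest-vertex
    fallback.
    """
    q = MeshQuery(sce)
    out = np.empty_like(coords.coordinates)
    fallback = np.zeros(coords.n_elec, dtype=bool)
    for j, e in enumerate(coords.coordinates):
        n = q.average_normal(e, radius)
        if n is None:
            n = q.average_normal(e, 2 * radius)
        hit = q.first_hit(e, n) if n is not None else None
        if hit is None:
            hit, _, _ = q.closest_point(e)
            hit = hit[0]
            fallback[j] = True
        out[j] = hit
    return AnchorSet(out, AnchorMethod.NORMAL_SCE, fallback)


# ---------------------------------------------------------------------------
# constrained projection (CEPA / Springs)

def projection_model(geometry: ArrayGeometry, coords: np.ndarray) -> ArrayModel:
    """Spring mesh over the contacts for the projection cost.

    Grids use the standard first/second/diagonal lattice mesh (contacts and
    structural points coincide); strips use the contact chain with first and
    second neighbors.  Both the translation reference and the spring rest
    lengths come from the input (CT-space) configuration: the deformation
    term measures expansion between the initial and final projection
    states, not against the manufactured lattice.
    """
    if geometry.array_type is ArrayType.GRID:
        model = build_grid_model(geometry)
    else:
        from .arrays import build_depth_model

        chain = ArrayGeometry(ArrayType.DEPTH, 1, geometry.n_elec, geometry.ied)
        model = build_depth_model(chain)
        model = ArrayModel(
            geometry=geometry,
            points=model.points,
            initial_points=model.initial_points,
            electrode_index=model.electrode_index,
            connections=model.connections,
            rest_lengths=model.rest_lengths,
            lattice_shape=model.lattice_shape,
        )
    model = model.with_points(np.asarray(coords, dtype=float), as_initial=True)
    pairs = model.connection_pairs
    model.rest_lengths = np.linalg.norm(
        model.points[pairs[:, 0]] - model.points[pairs[:, 1]], axis=1
    )
    return model


def _minimize_on_surface(
    coords0: np.ndarray,
    energy_and_grad,
    sce: SurfaceMesh,
    config: ProjectionConfig,
) -> tuple[np.ndarray, bool]:
    """Penalty-ramp minimization of a smooth cost over on-envelope contacts.

    The on-surface constraint is handled by an increasing quadratic penalty
    mu * sum dist(e_j, SCE)^2 (exact gradient via the closest point), after
    which the final iterate is snapped to the nearest surface point when
    within 2*eps; a larger residual raises ``ProjectionError``.
    """
    q = MeshQuery(sce)
    x = np.asarray(coords0, dtype=float).ravel().copy()
    n = x.size // 3

    for mu in (1e2, 1e3, 1e4):
        def fun(z, mu=mu):
            pts = z.reshape(n, 3)
            e, g = energy_and_grad(pts)
            closest, dist, _ = q.closest_point(pts)
            e += mu * float(np.sum(dist**2))
            g = g + 2.0 * mu * (pts - closest)
            return e, g.ravel()

        res = minimize(
            fun,
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.max_iterations, "ftol": config.tol * 1e-3, "gtol": 1e-10},
        )
        x = res.x
    pts = x.reshape(n, 3)
    closest, dist, _ = q.closest_point(pts)
    if np.any(dist > 2 * config.eps):
        raise ProjectionError(
            f"projection left a contact {dist.max():.2f} mm off the envelope"
        )
    # snap: exact feasibility
    pts = closest
    return pts, True


def _assert_on_surface(points: np.ndarray, sce: SurfaceMesh, eps: float) -> None:
    dist = MeshQuery(sce).distance(points)
    if np.any(dist > eps):
        raise ProjectionError(f"contact {int(np.argmax(dist))} is {dist.max():.3f} mm off the envelope")


def project_cepa(
    coords: ElectrodeSet,
    sce: SurfaceMesh,
    anchors: list[AnchorSet] | None = None,
    config: ProjectionConfig | None = None,
    model: ArrayModel | None = None,
) -> ElectrodeSet:
    """Combined projection: springs + anchors + roughness, on the envelope.

    Anchors default to the grid-normal and envelope-normal projections for
    grids, and the envelope-normal projection alone for strips; they are
    computed once from the input (CT-space) coordinates and treated as
    fixed data during the minimization.
    """
    config = config or ProjectionConfig()
    geometry = coords.geometry
    if geometry.array_type is ArrayType.DEPTH:
        raise ValueError("depth arrays are corrected via correct_depth_shift")
    if anchors is None:
        anchors = [project_normal_sce(coords, sce, config.normal_sce_radius)]
        if geometry.array_type is ArrayType.GRID:
            anchors.insert(0, project_normal_grid(coords, sce))
    if not anchors:
        raise ValueError("CEPA needs at least one anchor set")
    model = model or projection_model(geometry, coords.coordinates)
    n_anch = len(anchors)
    anchor_xyz = [np.asarray(a.coordinates, dtype=float) for a in anchors]

    def energy_and_grad(pts):
        e_t, g_t = translation_energy(pts, model.initial_points, grad=True)
        e_d, g_d = deformation_energy(
            pts, model.connection_pairs, model.alphas, model.rest_lengths, grad=True
        )
        e = config.k_trans * e_t + config.k_def * e_d
        g = config.k_trans * g_t + config.k_def * g_d
        for a in anchor_xyz:
            e_a, g_a = anchor_energy(pts, a, grad=True)
            e += config.k_anch / n_anch * e_a
            g += config.k_anch / n_anch * g_a
        e_r, g_r = roughness_energy(
            pts, geometry, kernel2d=config.kernel2d, kernel1d=config.kernel1d, grad=True
        )
        e += config.k_rough * e_r
        g += config.k_rough * g_r
        return e, g

    pts, _ = _minimize_on_surface(coords.coordinates, energy_and_grad, sce, config)
    _assert_on_surface(pts, sce, config.eps)
    return coords.with_coordinates(pts, provenance="projected")


def project_springs(
    coords: ElectrodeSet,
    sce: SurfaceMesh,
    config: ProjectionConfig | None = None,
    model: ArrayModel | None = None,
) -> ElectrodeSet:
    """Spring-mesh baseline: anchors and roughness off, kDef = 1000.

    Produces near-rigid projections whose inter-electrode distances barely
    change - smooth but insensitive to how far each contact traveled.
    """
    config = config or ProjectionConfig()
    geometry = coords.geometry
    model = model or projection_model(geometry, coords.coordinates)

    def energy_and_grad(pts):
        e_t, g_t = translation_energy(pts, model.initial_points, grad=True)
        e_d, g_d = deformation_energy(
            pts, model.connection_pairs, model.alphas, model.rest_lengths, grad=True
        )
        return (
            config.k_trans * e_t + config.k_def_springs * e_d,
            config.k_trans * g_t + config.k_def_springs * g_d,
        )

    pts, _ = _minimize_on_surface(coords.coordinates, energy_and_grad, sce, config)
    _assert_on_surface(pts, sce, config.eps)
    return coords.with_coordinates(pts, provenance="projected")


# ---------------------------------------------------------------------------
# depth-electrode shift correction

def correct_depth_shift(
    depth_coords: ElectrodeSet,
    grid_pre: np.ndarray,
    grid_post: np.ndarray,
    config: ProjectionConfig | None = None,
) -> tuple[ElectrodeSet, np.ndarray]:
    """Translate co-implanted depth contacts by the grids' shift field.

    For depth contact j and grid/strip contact k with translation
    t_k = e0_k - e_k (CT position minus projected position):

        kappa_jk  = exp(-||e_j - e_k||^2 / (2 sigma_r^2))
        kappa'_jk = exp(-||e_j - e_k||^2 / (2 sigma_d^2))
        t_j = sum_k kappa_jk kappa'_jk t_k / sum_k kappa_jk

    Contacts far from every grid (weight sum below the numeric floor) stay
    put and are flagged.  Returns (corrected set, flags).
    """
    config = config or ProjectionConfig()
    pre = np.atleast_2d(np.asarray(grid_pre, dtype=float))
    post = np.atleast_2d(np.asarray(grid_post, dtype=float))
    if pre.shape != post.shape:
        raise ValueError("grid_pre and grid_post must match")
    t_k = pre - post
    out = depth_coords.coordinates.copy()
    flagged = np.zeros(depth_coords.n_elec, dtype=bool)
    for j, e in enumerate(depth_coords.coordinates):
        d2 = np.sum((e - pre) ** 2, axis=1)
        kappa = np.exp(-d2 / (2.0 * config.sigma_r**2))
        kappa_p = np.exp(-d2 / (2.0 * config.sigma_d**2))
        denom = kappa.sum()
        if denom < 1e-12:
            flagged[j] = True
            continue
        out[j] = e + (kappa * kappa_p) @ t_k / denom
    corrected = depth_coords.with_coordinates(out, provenance="projected")
    return corrected, flagged
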