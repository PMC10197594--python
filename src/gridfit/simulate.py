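"""Synthetic CT-artifact scenarios with ground truth.

Emulates post-implantation CT appearance of electrode arrays so the fitting
and projection algorithms can be exercised and calibrated without patient
data: grids and strips are draped near-isometrically on curved phantom
surfaces, depth arrays follow straight or curved trajectories, each contact
becomes a blob of voxels at CT resolution (0.5 mm by default) with
center-peaked intensity, and noise spatially displaces voxels in random
directions (sigma = 0.1 / 0.2 / 0.4 mm for the low / medium / high levels).
Overlap conditions add distractor voxels from a foreign contact pair or a
cable running over the array; the ground truth never includes them.

Everything is reproducible: a scenario is a pure function of its condition
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import trimesh
from scipy.optimize import minimize

from .arrays import ArrayGeometry, ArrayType
from .data import ElectrodeSet, VoxelCloud
from .mesh import MeshQuery, SurfaceMesh

__all__ = [
    "NOISE_LEVELS",
    "SimCondition",
    "Scenario",
    "Placement",
    "make_phantom_surface",
    "place_array",
    "voxelize_contacts",
    "add_noise",
    "add_overlap",
    "make_scenario",
    "generate_suite",
]

#: displacement scale (mm) per named noise level
NOISE_LEVELS: dict[str, float] = {"none": 0.0, "low": 0.1, "medium": 0.2, "high": 0.4}

#: default CT artifact blob radius per array type (mm); grid/strip contacts
#: are large discs whose metal artifact blooms wide, depth contacts are
#: narrow cylinders
CONTACT_RADIUS: dict[str, float] = {"grid": 1.0, "strip": 1.0, "depth": 0.8}

DEFAULT_VOXEL_SIZE = 0.5  # mm, CT resampling resolution


@dataclass(frozen=True)
class SimCondition:
    """One cell of the simulation design."""

    geometry: ArrayGeometry
    noise_level: str = "low"
    overlap: bool = False
    curved: bool = False  # depth trajectories only

    @property
    def noise_sigma(self) -> float:
        return NOISE_LEVELS[self.noise_level]

    @property
    def label(self) -> str:
        g = self.geometry
        parts = [
            f"{g.array_type.value}{g.n_rows}x{g.n_cols}",
            f"ied{g.ied:g}",
            f"noise-{self.noise_level}",
        ]
        if g.array_type is ArrayType.DEPTH:
            parts.append("curved" if self.curved else "straight")
        else:
            parts.append("overlap" if self.overlap else "clean")
        return "_".join(parts)


@dataclass
class Scenario:
    """Ground-truth contacts + generated voxel cloud for one implantation."""

    truth: ElectrodeSet
    cloud: VoxelCloud
    condition: SimCondition
    seed: int
    surface: SurfaceMesh | None = None


@dataclass(frozen=True)
class Placement:
    """Pose of an array on/inside a phantom.

    ``direction`` aims from the phantom center at the patch center (grids,
    strips, spheres); ``rotation`` spins the lattice about that axis.
    Depth trajectories use ``direction`` as the insertion axis from
    ``entry`` and ``curvature`` (1/mm) to bend them.
    """

    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    rotation: float = 0.0
    entry: np.ndarray = field(default_factory=lambda: np.zeros(3))
    curvature: float = 0.0


# ---------------------------------------------------------------------------
# phantom surfaces

def make_phantom_surface(
    kind: Literal["plane", "sphere", "gyral"],
    size: float = 60.0,
    curvature: float = 0.0,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    gyral_amplitude: float = 2.0,
    gyral_wavelength: float = 25.0,
) -> SurfaceMesh:
    """Simple cortical stand-ins: a plane patch, a sphere, or a corrugated sphere.

    ``size`` is the sphere radius or the plane half-extent (mm).  ``gyral``
    superimposes a radial sinusoidal corrugation mimicking gyral crowns and
    sulcal grooves; amplitude 0 degenerates to the sphere.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if kind == "plane":
        n = max(int(2 * size / max(voxel_size * 4, 1.0)), 8)
        xs = np.linspace(-size, size, n)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + n, a + 1])
                faces.append([a + 1, a + n, a + n + 1])
        return SurfaceMesh(verts, np.array(faces))
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=size)
    if kind == "sphere":
        return SurfaceMesh.from_trimesh(mesh)
    if kind == "gyral":
        v = np.asarray(mesh.vertices)
        r = np.linalg.norm(v, axis=1)
        unit = v / r[:, None]
        wobble = np.sin(2 * np.pi * v[:, 0] / gyral_wavelength) * np.sin(
            2 * np.pi * v[:, 1] / gyral_wavelength
        )
        r_new = r + gyral_amplitude * wobble
        return SurfaceMesh(unit * r_new[:, None], np.asarray(mesh.faces))
    raise ValueError(f"unknown phantom kind {kind!r}")


# ---------------------------------------------------------------------------
# array placement

def _tangent_basis(direction: np.ndarray, rotation: float) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(d, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(d, t1)
    c, s = np.cos(rotation), np.sin(rotation)
    return c * t1 + s * t2, -s * t1 + c * t2


def _drape_on_sphere(
    geometry: ArrayGeometry, radius: float, pose: Placement
) -> np.ndarray:
    """Near-isometric draping of a lattice on a sphere.

    Initial positions come from the azimuthal-equidistant (exponential) map
    at the patch center; a spring relaxation constrained to the sphere then
    pulls every first-neighbor distance to D (and diagonals to D*sqrt(2)),
    leaving residual strain well below 0.5%.
    """
    nr, nc, D = geometry.n_rows, geometry.n_cols, geometry.ied
    t1, t2 = _tangent_basis(pose.direction, pose.rotation)
    n = pose.direction / np.linalg.norm(pose.direction)
    ys, xs = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    a = (xs.ravel() - (nc - 1) / 2.0) * D
    b = (ys.ravel() - (nr - 1) / 2.0) * D
    s = np.hypot(a, b)
    with np.errstate(invalid="ignore"):
        dirs = (a[:, None] * t1 + b[:, None] * t2) / np.where(s > 0, s, 1.0)[:, None]
    pts = radius * (
        np.cos(s / radius)[:, None] * n + np.sin(s / radius)[:, None] * dirs
    )
    pts[s == 0] = radius * n

    if nr == 1 or nc == 1:
        # chains: arc-step placement along a great circle is already exact
        k = np.arange(max(nr, nc)) - (max(nr, nc) - 1) / 2.0
        arc = 2.0 * radius * np.arcsin(D / (2.0 * radius))
        ang = k * arc / radius
        t = t1 if nc >= nr else t2
        return radius * (np.cos(ang)[:, None] * n + np.sin(ang)[:, None] * t)

    # spring relaxation on the sphere (points parametrized by radial projection)
    first, diag = [], []
    def idx(r, c):
        return r * nc + c
    for r in range(nr):
        for c in range(nc):
            if c + 1 < nc:
                first.append((idx(r, c), idx(r, c + 1)))
            if r + 1 < nr:
                first.append((idx(r, c), idx(r + 1, c)))
            if r + 1 < nr and c + 1 < nc:
                diag.append((idx(r, c), idx(r + 1, c + 1)))
                diag.append((idx(r, c + 1), idx(r + 1, c)))
    first = np.array(first)
    diag = np.array(diag)
    d_diag = D * np.sqrt(2.0)

    def energy(x):
        q = x.reshape(-1, 3)
        rn = np.linalg.norm(q, axis=1, keepdims=True)
        p = radius * q / rn
        e = 0.0
        g = np.zeros_like(p)
        # diagonals only prevent shear; a small weight keeps first-neighbor
        # strain within the 0.5% draping budget
        for pairs, rest, w in ((first, D, 1.0), (diag, d_diag, 0.01)):
            vec = p[pairs[:, 0]] - p[pairs[:, 1]]
            d = np.linalg.norm(vec, axis=1)
            e += w * np.sum((d - rest) ** 2)
            coef = (2.0 * w * (d - rest) / np.where(d > 0, d, 1.0))[:, None]
            np.add.at(g, pairs[:, 0], coef * vec)
            np.add.at(g, pairs[:, 1], -coef * vec)
        # chain rule through the radial projection p(q)
        gq = radius * (g / rn - q * np.sum(g * q, axis=1, keepdims=True) / rn**3)
        return e, gq.ravel()

    res = minimize(energy, pts.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-13})
    q = res.x.reshape(-1, 3)
    return radius * q / np.linalg.norm(q, axis=1, keepdims=True)


def _depth_trajectory(geometry: ArrayGeometry, pose: Placement) -> np.ndarray:
    """Contacts at exact chord spacing D along a straight or curved path."""
    n, D = geometry.n_elec, geometry.ied
    d = pose.direction / np.linalg.norm(pose.direction)
    t1, _ = _tangent_basis(d, pose.rotation)

    def curve(t):
        return pose.entry + t * d + pose.curvature * t * t * t1

    pts = [curve(0.0)]
    t = 0.0
    for _ in range(n - 1):
        lo, hi = t, t + 2.0 * D
        while np.linalg.norm(curve(hi) - pts[-1]) < D:
            hi += D
        for _ in range(60):  # bisection on the chord length
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(curve(mid) - pts[-1]) < D:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        pts.append(curve(t))
    return np.array(pts)


def place_array(
    geometry: ArrayGeometry,
    surface: SurfaceMesh | None,
    pose: Placement,
    sphere_radius: float | None = None,
) -> ElectrodeSet:
    """Ground-truth contact coordinates for one implantation.

    Grids/strips are draped on the phantom (``sphere_radius`` enables the
    fast analytic sphere path; otherwise draped points are projected onto
    the mesh); depths follow the pose's trajectory and need no surface.
    """
    if geometry.array_type is ArrayType.DEPTH:
        return ElectrodeSet(_depth_trajectory(geometry, pose), geometry, provenance="initial")
    if sphere_radius is not None:
        pts = _drape_on_sphere(geometry, sphere_radius, pose)
    elif surface is not None:
        # estimate an effective radius from the patch, drape, then snap
        center = surface.vertices.mean(axis=0)
        r_eff = float(np.median(np.linalg.norm(surface.vertices - center, axis=1)))
        pts = center + _drape_on_sphere(geometry, r_eff, pose)
        pts, _, _ = MeshQuery(surface).closest_point(pts)
    else:
        raise ValueError("grids/strips need a surface or sphere_radius")
    span = max(geometry.n_rows, geometry.n_cols) * geometry.ied
    if sphere_radius is not None and span > np.pi * sphere_radius:
        raise ValueError("array larger than the phantom patch")
    return ElectrodeSet(pts, geometry, provenance="initial")


# ---------------------------------------------------------------------------
# CT artifact synthesis

def _ball_voxels(center: np.ndarray, radius: float, voxel_size: float):
    """Voxel-lattice points (centers at integer multiples of voxel_size)
    within ``radius`` of ``center``, with center distances."""
    lo = np.floor((center - radius) / voxel_size).astype(int)
    hi = np.ceil((center + radius) / voxel_size).astype(int)
    axes = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    gi, gj, gk = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gi.ravel(), gj.ravel(), gk.ravel()]) * voxel_size
    d = np.linalg.norm(pts - center, axis=1)
    keep = d <= radius
    return pts[keep], d[keep]


def voxelize_contacts(
    truth: ElectrodeSet,
    contact_radius: float | None = None,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    intensity_profile: Literal["gaussian", "flat"] = "gaussian",
) -> VoxelCloud:
    """Render each contact as a ball of voxels with center-peaked intensity.

    The Gaussian profile (scale radius/2) mimics the bright metal core and
    dimmer halo of a CT artifact; overlapping balls keep the maximum
    intensity.  Output intensities are scaled so the maximum is 1.
    """
    radius = contact_radius if contact_radius is not None else CONTACT_RADIUS[
        truth.geometry.array_type.value
    ]
    if radius < voxel_size / 2.0:
        raise ValueError("contact radius below half a voxel produces empty artifacts")
    acc: dict[tuple[int, int, int], float] = {}
    for center in truth.coordinates:
        pts, d = _ball_voxels(center, radius, voxel_size)
        if intensity_profile == "gaussian":
            w = np.exp(-(d**2) / (2.0 * (radius / 2.0) ** 2))
        else:
            w = np.ones_like(d)
        for p, wi in zip(pts, w):
            key = tuple(np.round(p / voxel_size).astype(int))
            if wi > acc.get(key, 0.0):
                acc[key] = float(wi)
    keys = np.array(list(acc.keys()), dtype=float) * voxel_size
    vals = np.array(list(acc.values()))
    return VoxelCloud(keys, vals / vals.max())


def add_noise(cloud: VoxelCloud, sigma: float, seed: int | np.random.Generator) -> VoxelCloud:
    """Displace each voxel in a uniformly random direction by |N(0, sigma)| mm."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return replace(cloud, coordinates=cloud.coordinates.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cloud.n_voxels
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    mags = np.abs(rng.normal(scale=sigma, size=n))
    return replace(cloud, coordinates=cloud.coordinates + mags[:, None] * dirs)


def add_overlap(
    scenario: Scenario,
    overlap_kind: Literal["electrode_pair", "cable"] = "electrode_pair",
    rng: np.random.Generator | None = None,
    height: float = 2.0,
) -> Scenario:
    """Append distractor voxels from foreign hardware over the array.

    ``electrode_pair`` drops two extra contacts (spacing D) hovering
    ``height`` mm above a random spot over the array, as when another strip
    crosses it; ``cable`` lays a thin tube of voxels across the array.  The
    ground truth is unchanged - the distractors are pure clutter.
    """
    geometry = scenario.truth.geometry
    if geometry.array_type is ArrayType.DEPTH:
        raise ValueError("overlap distractors are defined for grids and strips")
    rng = rng or np.random.default_rng(scenario.seed + 1)
    coords = scenario.truth.coordinates
    center = coords.mean(axis=0)
    # outward normal of the array patch from its best-fit plane
    u, s, vt = np.linalg.svd(coords - center)
    normal = vt[2]
    if np.dot(center, normal) < 0:  # point away from the phantom center
        normal = -normal
    spot = coords[rng.integers(len(coords))]
    above = spot + height * normal
    D = geometry.ied
    tangent = vt[0] * np.cos(rng.uniform(0, 2 * np.pi)) + vt[1] * np.sin(
        rng.uniform(0, 2 * np.pi)
    )
    radius = CONTACT_RADIUS[geometry.array_type.value]
    if overlap_kind == "electrode_pair":
        pts = np.array([above - tangent * D / 2.0, above + tangent * D / 2.0])
        extra_geom = ArrayGeometry(ArrayType.STRIP, 1, 2, D)
        extra = voxelize_contacts(
            ElectrodeSet(pts, extra_geom), contact_radius=radius
        )
    elif overlap_kind == "cable":
        span = max(geometry.n_rows, geometry.n_cols) * D
        ts = np.arange(-span / 2, span / 2, 0.25)
        samples = above + ts[:, None] * tangent
        acc: dict[tuple[int, int, int], float] = {}
        for c in samples:
            p, d = _ball_voxels(c, 0.6, DEFAULT_VOXEL_SIZE)
            for q, dd in zip(p, d):
                key = tuple(np.round(q / DEFAULT_VOXEL_SIZE).astype(int))
                w = float(np.exp(-(dd**2) / (2 * 0.3**2)))
                if w > acc.get(key, 0.0):
                    acc[key] = w
        extra = VoxelCloud(
            np.array(list(acc.keys()), dtype=float) * DEFAULT_VOXEL_SIZE,
            np.array(list(acc.values())),
        )
    else:
        raise ValueError(f"unknown overlap kind {overlap_kind!r}")
    # emulate the user's coarse voxel selection: clutter survives only where
    # it overlaps the selected array region, so distractor tails running far
    # off the array are clipped at 1.5 IED from the nearest contact
    from scipy.spatial import cKDTree

    dmin, _ = cKDTree(coords).query(extra.coordinates)
    keep = dmin <= 1.5 * D
    if not keep.any():
        return scenario
    merged = VoxelCloud(
        np.vstack([scenario.cloud.coordinates, extra.coordinates[keep]]),
        np.concatenate([scenario.cloud.intensities, 0.8 * extra.intensities[keep]]),
    )
    return replace(scenario, cloud=merged)


# ---------------------------------------------------------------------------
# scenario + suite assembly

def make_scenario(condition: SimCondition, seed: int) -> Scenario:
    """One reproducible implantation: phantom, pose, artifacts, noise, clutter."""
    rng = np.random.default_rng(seed)
    geometry = condition.geometry
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    rotation = rng.uniform(0, 2 * np.pi)

    if geometry.array_type is ArrayType.DEPTH:
        curvature = rng.uniform(0.002, 0.006) if condition.curved else 0.0
        pose = Placement(
            direction=direction,
            rotation=rotation,
            entry=rng.uniform(-20, 20, size=3),
            curvature=curvature,
        )
        truth = place_array(geometry, None, pose)
        surface = None
    else:
        radius = rng.uniform(50.0, 80.0)
        pose = Placement(direction=direction, rotation=rotation)
        truth = place_array(geometry, None, pose, sphere_radius=radius)
        surface = None  # the analytic sphere is not meshed per scenario (speed)

    cloud = voxelize_contacts(truth)
    cloud = add_noise(cloud, condition.noise_sigma, rng)
    scenario = Scenario(truth=truth, cloud=cloud, condition=condition, seed=seed, surface=surface)
    if condition.overlap:
        kind = "electrode_pair" if rng.random() < 0.7 else "cable"
        scenario = add_overlap(scenario, kind, rng)
    return scenario


def generate_suite(
    conditions: list[SimCondition],
    n_per_condition: int,
    base_seed: int,
) -> list[Scenario]:
    """Deterministic expansion of a condition list into scenarios.

    Seeds derive from ``base_seed`` through a SeedSequence spawn tree, so
    the suite is bit-reproducible and scenario i of condition j never
    collides with another cell of the design.
    """
    if n_per_condition < 1:
        raise ValueError("need at least one replicate per condition")
    scenarios = []
    for ci, cond in enumerate(conditions):
        for ri in range(n_per_condition):
            ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(ci, ri))
            seed = int(ss.generate_state(1)[0] % (2**31))
            scenarios.append(make_scenario(cond, seed))
    return scenarios


def suite_manifest(scenarios: list[Scenario]) -> list[dict]:
    """Seed/condition records sufficient to regenerate every scenario."""
    return [
        {
            "label": s.condition.label,
            "seed": s.seed,
            "array_type": s.condition.geometry.array_type.value,
            "n_rows": s.condition.geometry.n_rows,
            "n_cols": s.condition.geometry.n_cols,
            "ied_mm": s.condition.geometry.ied,
            "noise_level": s.condition.noise_level,
            "overlap": s.condition.overlap,
            "curved": s.condition.curved,
            "n_voxels": s.cloud.n_voxels,
        }
        for s in scenarios
    ]
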