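"""Structural models of intracranial electrode arrays.

Grids, strips, and depth electrodes are represented as spring-mesh lattices:
a set of structural points ``m`` connected to their first, second, and
diagonal neighbors, a subset of which (``e``) are the physical contacts.
The mesh rest lengths encode the manufactured geometry (inter-electrode
distance D, thickness T) and are what the deformation energy and the
hard deformation constraints are measured against.

Models are built in a canonical frame: bottom layer in the z = 0 plane,
x along columns, y along rows, centered at the origin.  Placement in
scanner space is a rigid transform applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ArrayType",
    "NeighborClass",
    "ArrayGeometry",
    "Connection",
    "ArrayModel",
    "ConnectionWeights",
    "build_grid_model",
    "build_strip_model",
    "build_depth_model",
    "build_model",
    "extrude_to_3d",
    "connection_ratio",
    "default_thickness",
    "hexahedron_volumes",
]

_TETS = np.array(
    [[0, 1, 2, 6], [0, 2, 3, 6], [0, 3, 7, 6], [0, 7, 4, 6], [0, 4, 5, 6], [0, 5, 1, 6]]
)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product over the last axis (faster than np.cross for small arrays)."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def hexahedron_volumes(points: np.ndarray, cuboids: np.ndarray, grad: bool = False):
    """Volumes of 8-vertex cells split into 6 tetrahedra around the 0-6 diagonal.

    Vertex order: bottom ring (0..3, counterclockwise), top ring (4..7,
    vertically above).  The fixed diagonal convention makes the volume of a
    deformed cell well defined and smooth in the vertex coordinates.
    Fully vectorized over cells and tetrahedra (this sits inside the
    penalty optimizer's inner loop).
    """
    vt = points[cuboids][:, _TETS]  # (C, 6, 4, 3)
    a, b, c, d = vt[:, :, 0], vt[:, :, 1], vt[:, :, 2], vt[:, :, 3]
    ab, ac, ad = b - a, c - a, d - a
    cr = _cross(ac, ad)
    vols = np.einsum("ctd,ctd->c", ab, cr) / 6.0
    if not grad:
        return vols
    gb = cr / 6.0
    gc = _cross(ad, ab) / 6.0
    gd = _cross(ab, ac) / 6.0
    ga = -(gb + gc + gd)
    grads = np.zeros((cuboids.shape[0], 8, 3))
    for ti in range(_TETS.shape[0]):
        grads[:, _TETS[ti, 0]] += ga[:, ti]
        grads[:, _TETS[ti, 1]] += gb[:, ti]
        grads[:, _TETS[ti, 2]] += gc[:, ti]
        grads[:, _TETS[ti, 3]] += gd[:, ti]
    return vols, grads


class ArrayType(str, Enum):
    GRID = "grid"
    STRIP = "strip"
    DEPTH = "depth"


class NeighborClass(str, Enum):
    FIRST = "first"
    SECOND = "second"
    DIAGONAL = "diagonal"


@dataclass(frozen=True)
class ConnectionWeights:
    """Spring weights (alpha) per neighbor class, each in (0, 1].

    First neighbors carry the primary IED constraint; second and diagonal
    links provide shear/bending stiffness.
    """

    first: float = 1.0
    second: float = 0.5
    diagonal: float = 0.5

    def __post_init__(self) -> None:
        for name in ("first", "second", "diagonal"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"alpha_{name} must be in (0, 1], got {v}")

    def of(self, klass: NeighborClass) -> float:
        return getattr(self, klass.value)


@dataclass(frozen=True)
class ArrayGeometry:
    """Geometry descriptor of a rectangular array or contact chain.

    Parameters
    ----------
    array_type : grid, strip, or depth.
    n_rows, n_cols : lattice dimensions; strips and depths have a
        narrowest dimension of 1 (strips may have 2).
    ied : center-to-center inter-electrode distance D in mm.
    thickness : physical slab thickness T in mm, used only by 3D models;
        defaults to ``default_thickness(ied)``.
    """

    array_type: ArrayType
    n_rows: int
    n_cols: int
    ied: float
    thickness: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "array_type", ArrayType(self.array_type))
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be positive")
        if self.ied <= 0:
            raise ValueError("ied must be positive")
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.array_type is ArrayType.DEPTH and min(self.n_rows, self.n_cols) != 1:
            raise ValueError("depth arrays are single chains (min dimension 1)")
        if self.array_type is ArrayType.STRIP and min(self.n_rows, self.n_cols) > 2:
            raise ValueError("strips have a narrowest dimension of at most 2")

    @property
    def n_elec(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def thickness_mm(self) -> float:
        return self.thickness if self.thickness is not None else default_thickness(self.ied)

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayGeometry":
        """Build from a config mapping with keys type/rows/cols/ied_mm[/thickness_mm]."""
        return cls(
            array_type=ArrayType(d["type"]),
            n_rows=int(d["rows"]),
            n_cols=int(d["cols"]),
            ied=float(d["ied_mm"]),
            thickness=float(d["thickness_mm"]) if d.get("thickness_mm") else None,
        )


def default_thickness(ied: float) -> float:
    """Default slab thickness: half the IED, clamped to [0.5, 2.5] mm."""
    return float(np.clip(0.5 * ied, 0.5, 2.5))


@dataclass(frozen=True)
class Connection:
    j: int
    k: int
    neighbor_class: NeighborClass
    alpha: float


@dataclass
class ArrayModel:
    """Spring-mesh model: structural points, contacts, weighted connections.

    ``points`` is the current configuration m, ``initial_points`` the
    translation reference m0 (both NMod x 3, mm).  ``rest_lengths`` d0 are
    the connection lengths of the canonical (manufactured) model and do not
    change when the model is placed or refit.  ``electrode_index`` maps the
    ordered contacts e (row-major, row 1 col 1 first) into the point set.
    """

    geometry: ArrayGeometry
    points: np.ndarray
    initial_points: np.ndarray
    electrode_index: np.ndarray
    connections: list[Connection]
    rest_lengths: np.ndarray
    cuboids: np.ndarray = field(default_factory=lambda: np.empty((0, 8), dtype=int))
    cuboid_volumes0: np.ndarray = field(default_factory=lambda: np.empty(0))
    layer: np.ndarray | None = None  # 0 = bottom, 1 = top (3D models)
    lattice_shape: tuple[int, int] = (0, 0)  # structural lattice (rows, cols)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.initial_points = np.asarray(self.initial_points, dtype=float)
        self.electrode_index = np.asarray(self.electrode_index, dtype=int)
        if self.points.shape != self.initial_points.shape:
            raise ValueError("points and initial_points must have equal shape")
        if len(set(self.electrode_index.tolist())) != self.electrode_index.size:
            raise ValueError("electrode_index has duplicates")
        if self.electrode_index.size != self.geometry.n_elec:
            raise ValueError("electrode_index must have exactly NElec entries")
        seen = set()
        for c in self.connections:
            if not (0 <= c.j < self.n_points and 0 <= c.k < self.n_points):
                raise ValueError("connection references an invalid point")
            if c.j >= c.k:
                raise ValueError("connections must be stored with j < k")
            if (c.j, c.k) in seen:
                raise ValueError("duplicate connection")
            if not 0.0 < c.alpha <= 1.0:
                raise ValueError("stored alpha must be in (0, 1]")
            seen.add((c.j, c.k))

    # -- convenience views ------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    @property
    def is_3d(self) -> bool:
        return self.layer is not None

    @property
    def electrode_points(self) -> np.ndarray:
        return self.points[self.electrode_index]

    @property
    def connection_pairs(self) -> np.ndarray:
        """(NConn, 2) int array of point index pairs."""
        if not self.connections:
            return np.empty((0, 2), dtype=int)
        return np.array([(c.j, c.k) for c in self.connections], dtype=int)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([c.alpha for c in self.connections], dtype=float)

    def with_points(self, points: np.ndarray, *, as_initial: bool = False) -> "ArrayModel":
        """Copy of the model with a new current (and optionally initial) configuration."""
        pts = np.asarray(points, dtype=float)
        if pts.shape != self.points.shape:
            raise ValueError("replacement points must match model shape")
        return replace(
            self,
            points=pts.copy(),
            initial_points=pts.copy() if as_initial else self.initial_points.copy(),
            connections=list(self.connections),
        )


# ---------------------------------------------------------------------------
# lattice construction helpers

def _lattice_points(n_rows: int, n_cols: int, spacing: float) -> np.ndarray:
    """Row-major lattice in the z=0 plane, centered at the origin."""
    ys, xs = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    pts = np.column_stack(
        [
            xs.ravel() * spacing - (n_cols - 1) * spacing / 2.0,
            ys.ravel() * spacing - (n_rows - 1) * spacing / 2.0,
            np.zeros(n_rows * n_cols),
        ]
    )
    return pts


_FIRST_OFFSETS = ((0, 1), (1, 0))
_SECOND_OFFSETS = ((0, 2), (2, 0))
_DIAG_OFFSETS = ((1, 1), (1, -1))


def _lattice_connections(
    n_rows: int,
    n_cols: int,
    weights: ConnectionWeights,
    classes: Sequence[NeighborClass],
) -> list[Connection]:
    """Classify lattice point pairs by integer offset into neighbor classes."""
    def idx(r: int, c: int) -> int:
        return r * n_cols + c

    offsets = {
        NeighborClass.FIRST: _FIRST_OFFSETS,
        NeighborClass.SECOND: _SECOND_OFFSETS,
        NeighborClass.DIAGONAL: _DIAG_OFFSETS,
    }
    conns: list[Connection] = []
    for klass in classes:
        for dr, dc in offsets[klass]:
            for r in range(n_rows):
                for c in range(n_cols):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                        j, k = sorted((idx(r, c), idx(r2, c2)))
                        conns.append(Connection(j, k, klass, weights.of(klass)))
    return conns


def _finalize(
    geometry: ArrayGeometry,
    points: np.ndarray,
    electrode_index: np.ndarray,
    connections: list[Connection],
    lattice_shape: tuple[int, int],
) -> ArrayModel:
    d0 = np.linalg.norm(points[[c.j for c in connections]] - points[[c.k for c in connections]], axis=1)
    return ArrayModel(
        geometry=geometry,
        points=points.copy(),
        initial_points=points.copy(),
        electrode_index=electrode_index,
        connections=connections,
        rest_lengths=d0,
        lattice_shape=lattice_shape,
    )


# ---------------------------------------------------------------------------
# public builders

def build_grid_model(
    geometry: ArrayGeometry, weights: ConnectionWeights | None = None
) -> ArrayModel:
    """2D grid model: e = m, first + second + diagonal neighbor springs.

    Points form an n_rows x n_cols lattice at spacing D in the z=0 plane.
    """
    if geometry.array_type is not ArrayType.GRID:
        raise ValueError("build_grid_model requires grid geometry")
    if geometry.n_rows < 2 or geometry.n_cols < 2:
        raise ValueError("grid models need at least 2 rows and 2 columns")
    weights = weights or ConnectionWeights()
    pts = _lattice_points(geometry.n_rows, geometry.n_cols, geometry.ied)
    conns = _lattice_connections(
        geometry.n_rows,
        geometry.n_cols,
        weights,
        (NeighborClass.FIRST, NeighborClass.SECOND, NeighborClass.DIAGONAL),
    )
    return _finalize(
        geometry,
        pts,
        np.arange(geometry.n_elec),
        conns,
        (geometry.n_rows, geometry.n_cols),
    )


def build_strip_model(
    geometry: ArrayGeometry, weights: ConnectionWeights | None = None
) -> ArrayModel:
    """Strip model: D/2 lattice extending the narrow dimension by D/2 per side.

    The physical contacts are the central subset of the structural lattice
    at spacing D, so NMod > NElec; the extra points give the thin strip
    bending structure.
    """
    if geometry.array_type is not ArrayType.STRIP:
        raise ValueError("build_strip_model requires strip geometry")
    n_narrow, n_long = sorted((geometry.n_rows, geometry.n_cols))
    if n_long < 2:
        raise ValueError("strip needs at least 2 contacts along its length")
    weights = weights or ConnectionWeights()
    # structural lattice at D/2: long dimension spans the contacts,
    # narrow dimension extended by D/2 (one lattice step) on each side
    lat_cols = 2 * n_long - 1
    lat_rows = 2 * n_narrow + 1
    half = geometry.ied / 2.0
    pts = _lattice_points(lat_rows, lat_cols, half)
    conns = _lattice_connections(
        lat_rows,
        lat_cols,
        weights,
        (NeighborClass.FIRST, NeighborClass.SECOND, NeighborClass.DIAGONAL),
    )
    # contacts: central rows (offset 1 from the extension), every other column
    elec = []
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            rr, cc = (r, c) if geometry.n_rows <= geometry.n_cols else (c, r)
            elec.append((1 + 2 * rr) * lat_cols + 2 * cc)
    return _finalize(geometry, pts, np.array(elec), conns, (lat_rows, lat_cols))


def build_depth_model(
    geometry: ArrayGeometry, weights: ConnectionWeights | None = None
) -> ArrayModel:
    """Depth model: collinear chain at spacing D, first + second springs."""
    if geometry.array_type is not ArrayType.DEPTH:
        raise ValueError("build_depth_model requires depth geometry")
    n = geometry.n_elec
    if n < 2:
        raise ValueError("depth chains need at least 2 contacts")
    weights = weights or ConnectionWeights()
    pts = _lattice_points(1, n, geometry.ied)
    conns = _lattice_connections(1, n, weights, (NeighborClass.FIRST, NeighborClass.SECOND))
    return _finalize(geometry, pts, np.arange(n), conns, (1, n))


def build_model(geometry: ArrayGeometry, weights: ConnectionWeights | None = None) -> ArrayModel:
    """Dispatch to the builder matching the geometry's array type."""
    builder = {
        ArrayType.GRID: build_grid_model,
        ArrayType.STRIP: build_strip_model,
        ArrayType.DEPTH: build_depth_model,
    }[geometry.array_type]
    return builder(geometry, weights)


# ---------------------------------------------------------------------------
# 3D extrusion

def _point_normals(points: np.ndarray, lattice_shape: tuple[int, int]) -> np.ndarray:
    """Per-point unit normals of a (possibly curved) lattice configuration."""
    rows, cols = lattice_shape
    grid = points.reshape(rows, cols, 3)
    # tangents by central/one-sided differences along rows and columns
    du = np.gradient(grid, axis=1)
    dv = np.gradient(grid, axis=0) if rows > 1 else None
    if dv is None:
        # chain: pick any vector orthogonal to the tangent
        t = du.reshape(-1, 3)
        ref = np.where(np.abs(t[:, [0]]) < 0.9 * np.linalg.norm(t, axis=1, keepdims=True),
                       [1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        n = np.cross(t, ref)
    else:
        n = np.cross(du, dv).reshape(-1, 3)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    n = n / norms
    # orient consistently with the mean normal
    mean_n = n.mean(axis=0)
    if np.linalg.norm(mean_n) > 0:
        n[np.dot(n, mean_n) < 0] *= -1
    return n


def extrude_to_3d(
    model2d: ArrayModel,
    thickness: float | None = None,
    weights: ConnectionWeights | None = None,
) -> ArrayModel:
    """Stack a second structural layer at distance T above a 2D grid/strip model.

    The bottom layer keeps the 2D configuration (and the contacts); the top
    layer is offset along the local lattice normal.  Within each layer and
    across layers, points are joined by first and diagonal springs (no second
    neighbors).  Rest lengths and cuboid volumes are recorded from the
    *constructed* (possibly curved) slab: the 3D model is created from the
    coarse-fit solution, and deformation in the refinement step is measured
    against that construction-time state.  One rectangular cuboid per
    first-neighbor lattice cell tiles the slab; its volume conservation is
    the refinement step's incompressibility constraint.
    """
    if model2d.geometry.array_type is ArrayType.DEPTH:
        raise ValueError("depth models are not extruded; 2D chains are used throughout")
    if model2d.is_3d:
        raise ValueError("model is already 3D")
    weights = weights or ConnectionWeights()
    T = thickness if thickness is not None else model2d.geometry.thickness_mm
    if T <= 0:
        raise ValueError("thickness must be positive")

    rows, cols = model2d.lattice_shape
    n2 = model2d.n_points
    normals = _point_normals(model2d.points, model2d.lattice_shape)
    bottom = model2d.points
    top = bottom + T * normals
    points = np.vstack([bottom, top])

    def idx(layer: int, r: int, c: int) -> int:
        return layer * n2 + r * cols + c

    spacing = model2d.rest_lengths.min()  # lattice pitch (D or D/2)
    conns: list[Connection] = []
    seen: set[tuple[int, int]] = set()

    def add(a: int, b: int, klass: NeighborClass) -> None:
        j, k = sorted((a, b))
        if (j, k) not in seen:
            seen.add((j, k))
            conns.append(Connection(j, k, klass, weights.of(klass)))

    # within-layer first + diagonal
    for layer in (0, 1):
        for r in range(rows):
            for c in range(cols):
                for dr, dc in _FIRST_OFFSETS:
                    if r + dr < rows and 0 <= c + dc < cols:
                        add(idx(layer, r, c), idx(layer, r + dr, c + dc), NeighborClass.FIRST)
                for dr, dc in _DIAG_OFFSETS:
                    if r + dr < rows and 0 <= c + dc < cols:
                        add(idx(layer, r, c), idx(layer, r + dr, c + dc), NeighborClass.DIAGONAL)
    # across layers: vertical (first) and slanted (diagonal)
    for r in range(rows):
        for c in range(cols):
            add(idx(0, r, c), idx(1, r, c), NeighborClass.FIRST)
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    add(idx(0, r, c), idx(1, r2, c2), NeighborClass.DIAGONAL)

    # rest lengths from the constructed configuration (flat model in, flat
    # rest state out; curved coarse-fit in, curved rest state out)
    pairs = np.array([(c.j, c.k) for c in conns], dtype=int)
    d0 = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)

    # cuboids: one per lattice cell, vertex order (bottom ring, top ring)
    cuboids = []
    for r in range(rows - 1):
        for c in range(cols - 1):
            cuboids.append(
                [
                    idx(0, r, c), idx(0, r, c + 1), idx(0, r + 1, c + 1), idx(0, r + 1, c),
                    idx(1, r, c), idx(1, r, c + 1), idx(1, r + 1, c + 1), idx(1, r + 1, c),
                ]
            )
    cuboids_arr = np.array(cuboids, dtype=int) if cuboids else np.empty((0, 8), dtype=int)
    vol0 = (
        hexahedron_volumes(points, cuboids_arr)
        if len(cuboids)
        else np.empty(0)
    )

    model = ArrayModel(
        geometry=model2d.geometry,
        points=points,
        initial_points=points.copy(),
        electrode_index=model2d.electrode_index.copy(),
        connections=conns,
        rest_lengths=d0,
        cuboids=cuboids_arr,
        cuboid_volumes0=vol0,
        layer=np.repeat([0, 1], n2),
        lattice_shape=(rows, cols),
    )
    return model


# ---------------------------------------------------------------------------

def connection_ratio(model: ArrayModel) -> np.ndarray:
    """Per-electrode connection ratio u (Gaussian-term weights).

    u_j = (number of springs touching contact j) / (maximum over contacts);
    interior contacts get u = 1, edge and corner contacts less.  This
    counterbalances the deformation energy, which grips interior contacts
    through more springs than border ones.
    """
    if model.n_connections == 0:
        raise ValueError("model has no connections")
    counts = np.zeros(model.n_points)
    pairs = model.connection_pairs
    np.add.at(counts, pairs[:, 0], 1.0)
    np.add.at(counts, pairs[:, 1], 1.0)
    u = counts[model.electrode_index]
    return u / u.max()
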