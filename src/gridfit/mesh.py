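"""Triangulated surfaces and geometric queries against them.

``SurfaceMesh`` is a thin container over vertices/faces (mm) used for pial
surfaces, smooth cortical envelopes, and simulation phantoms.  ``MeshQuery``
provides the closest-point, ray-intersection, and containment primitives the
projection algorithms need, implemented with a k-d tree over face centroids
plus exact point-triangle tests and a vectorized Moller-Trumbore ray caster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = ["SurfaceMesh", "MeshQuery"]


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (V x 3 mm) and faces (F x 3 indices)."""

    vertices: np.ndarray
    faces: np.ndarray
    _trimesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), _trimesh=mesh)

    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @property
    def vertex_normals(self) -> np.ndarray:
        """Outward unit vertex normals (area-weighted face-normal average)."""
        return np.asarray(self.trimesh.vertex_normals)

    @property
    def is_watertight(self) -> bool:
        return bool(self.trimesh.is_watertight)

    def query(self) -> "MeshQuery":
        return MeshQuery(self)


class MeshQuery:
    """Closest-point / ray / containment queries against one mesh.

    Closest points are found exactly on a candidate set of faces selected
    by a k-d tree over face centroids (k nearest, default 24); for the
    well-shaped meshes used here (icospheres, marching-cubes envelopes)
    the true nearest face is always within that candidate set.
    """

    def __init__(self, surface: SurfaceMesh, k_candidates: int = 24):
        self.surface = surface
        self._triangles = surface.vertices[surface.faces]  # (F, 3, 3)
        self._centroids = self._triangles.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._k = min(k_candidates, len(surface.faces))
        tm = surface.trimesh
        self._face_normals = np.asarray(tm.face_normals)
        self._vertex_tree = cKDTree(surface.vertices)

    # -- closest point ----------------------------------------------------
    def closest_point(self, points: np.ndarray):
        """Exact nearest surface point for each query.

        Returns (closest, distance, face_index).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(pts, k=self._k)
        cand = np.atleast_2d(cand)
        nq, k = cand.shape
        tris = self._triangles[cand.ravel()]  # (nq*k, 3, 3)
        rep = np.repeat(pts, k, axis=0)
        near = trimesh.triangles.closest_point(tris, rep).reshape(nq, k, 3)
        d2 = np.sum((near - pts[:, None, :]) ** 2, axis=2)
        best = np.argmin(d2, axis=1)
        rows = np.arange(nq)
        closest = near[rows, best]
        dist = np.sqrt(d2[rows, best])
        face = cand[rows, best]
        return closest, dist, face

    def distance(self, points: np.ndarray) -> np.ndarray:
        return self.closest_point(points)[1]

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive outside, negative inside (watertight meshes)."""
        _, dist, _ = self.closest_point(points)
        inside = self.contains(points)
        return np.where(inside, -dist, dist)

    # -- rays -------------------------------------------------------------
    def ray_intersections(self, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
        """All signed ray parameters t with origin + t*direction on the surface.

        Moller-Trumbore against every face (meshes here are small enough
        that brute force beats tree construction).  Returns a sorted array
        of t values (may be empty).
        """
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        v0 = self._triangles[:, 0]
        e1 = self._triangles[:, 1] - v0
        e2 = self._triangles[:, 2] - v0
        h = np.cross(d, e2)
        a = np.einsum("ij,ij->i", e1, h)
        mask = np.abs(a) > 1e-12
        f = np.zeros_like(a)
        f[mask] = 1.0 / a[mask]
        s = o - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", q, e2)
        hit = mask & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
        return np.sort(t[hit])

    def first_hit(self, origin: np.ndarray, direction: np.ndarray):
        """Nearest intersection along +-direction, or None.

        Both ray directions are searched and the hit with the smallest
        absolute ray parameter wins (the geometrically nearest crossing).
        """
        ts = self.ray_intersections(origin, direction)
        if ts.size == 0:
            return None
        t = ts[np.argmin(np.abs(ts))]
        return np.asarray(origin, dtype=float) + t * np.asarray(direction, dtype=float)

    # -- containment ------------------------------------------------------
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Ray-parity containment test (watertight meshes)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # fixed irrational direction avoids edge-grazing degeneracies
        d = np.array([0.5773502691896258, 0.5773502691896258, 0.5773502691896258])
        out = np.zeros(len(pts), dtype=bool)
        for i, p in enumerate(pts):
            ts = self.ray_intersections(p, d)
            out[i] = (ts > 1e-9).sum() % 2 == 1
        return out

    # -- normals ----------------------------------------------------------
    def average_normal(self, point: np.ndarray, radius: float) -> np.ndarray | None:
        """Mean outward vertex normal within ``radius`` of a point.

        Returns None when no vertex lies within the radius.
        """
        idx = self._vertex_tree.query_ball_point(np.asarray(point, dtype=float), radius)
        if not idx:
            return None
        n = self.surface.vertex_normals[idx].mean(axis=0)
        norm = np.linalg.norm(n)
        return n / norm if norm > 0 else None
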