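"""Evaluation and diagnostic quantities for localized/projected arrays.

Localization error is reported normalized by the inter-electrode distance
D: d_loc_med (median per-contact error / D) and d_loc_max (maximum / D).
Batch accuracy is 1 - median(d_loc_med) over arrays, after rejecting arrays
whose d_loc_med exceeds the batch median by five standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arrays import ArrayGeometry
from .data import ElectrodeSet
from .mesh import MeshQuery, SurfaceMesh

__all__ = [
    "EvaluationReport",
    "localization_error",
    "batch_accuracy",
    "accuracy_to_mean_error",
    "ied_mad",
    "projection_distance",
    "local_deformation",
    "estimated_hfa",
    "anatomical_labels",
    "first_neighbor_pairs",
]


@dataclass
class EvaluationReport:
    """Per-array localization evaluation."""

    d_loc_med: float
    d_loc_max: float
    per_contact_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    outlier: bool = False

    def __post_init__(self) -> None:
        if self.d_loc_med > self.d_loc_max + 1e-12:
            raise ValueError("median error cannot exceed maximum error")

    @property
    def accuracy(self) -> float:
        return 1.0 - self.d_loc_med


def first_neighbor_pairs(geometry: ArrayGeometry) -> np.ndarray:
    """Index pairs of orthogonally adjacent contacts (row-major ordering)."""
    nr, nc = geometry.n_rows, geometry.n_cols
    pairs = []
    for r in range(nr):
        for c in range(nc):
            if c + 1 < nc:
                pairs.append((r * nc + c, r * nc + c + 1))
            if r + 1 < nr:
                pairs.append((r * nc + c, (r + 1) * nc + c))
    return np.array(pairs, dtype=int)


def _symmetry_orders(geometry: ArrayGeometry) -> list[np.ndarray]:
    """Contact reorderings under the indistinguishable array symmetries.

    A voxel cloud carries no labeling, so a fit can return any of the
    rectangle's orientation symmetries (8 for grids, 2 for chains, 4 for
    square grids' full group restricted to rectangle: rotations of 180 deg
    plus flips).  Evaluation against ground truth picks the best relabeling.
    """
    nr, nc = geometry.n_rows, geometry.n_cols
    base = np.arange(nr * nc).reshape(nr, nc)
    mats = [base, base[::-1], base[:, ::-1], base[::-1, ::-1]]
    if nr == nc:
        t = base.T
        mats += [t, t[::-1], t[:, ::-1], t[::-1, ::-1]]
    return [m.ravel() for m in mats]


def localization_error(
    truth: ElectrodeSet,
    fitted: ElectrodeSet,
    resolve_symmetry: bool = True,
) -> EvaluationReport:
    """Normalized median/maximum contact error of a fitted array.

    d_loc_med = median_j ||truth_j - fitted_j|| / D, d_loc_max the maximum.
    With ``resolve_symmetry`` (default) the fitted contacts may be
    relabeled by any orientation symmetry of the array before comparison,
    because an unlabeled voxel cloud cannot disambiguate them; coordinates
    are never moved.
    """
    if truth.geometry.n_elec != fitted.geometry.n_elec:
        raise ValueError("truth and fitted sets have different cardinality")
    D = truth.geometry.ied
    orders = _symmetry_orders(truth.geometry) if resolve_symmetry else [np.arange(truth.n_elec)]
    best = None
    for order in orders:
        err = np.linalg.norm(truth.coordinates - fitted.coordinates[order], axis=1) / D
        med = float(np.median(err))
        if best is None or med < best[0]:
            best = (med, float(err.max()), err)
    med, mx, err = best
    return EvaluationReport(d_loc_med=med, d_loc_max=mx, per_contact_errors=err)


def batch_accuracy(
    reports: list[EvaluationReport], sd_reject: float = 5.0
) -> tuple[float, int]:
    """Batch accuracy with outlier rejection.

    Arrays whose d_loc_med exceeds the batch median by ``sd_reject``
    standard deviations (single pass) are excluded and flagged; accuracy is
    1 - median(d_loc_med) over the survivors.  Returns (accuracy,
    n_rejected).
    """
    if not reports:
        raise ValueError("no reports")
    vals = np.array([r.d_loc_med for r in reports])
    med, sd = np.median(vals), np.std(vals)
    keep = vals <= med + sd_reject * sd
    for r, k in zip(reports, keep):
        r.outlier = not k
    if not keep.any():
        raise ValueError("all arrays rejected")
    return float(1.0 - np.median(vals[keep])), int((~keep).sum())


def accuracy_to_mean_error(accuracy: float, ied: float) -> float:
    """Convert batch accuracy to a distance error in mm: (1 - accuracy) * D."""
    return (1.0 - accuracy) * ied


def ied_mad(coords: ElectrodeSet) -> float:
    """Mean absolute deviation of the first-neighbor inter-electrode distances.

    A precision/regularity diagnostic: 0 for a perfectly regular lattice,
    insensitive to rigid motion.
    """
    pairs = first_neighbor_pairs(coords.geometry)
    if pairs.size == 0:
        raise ValueError("geometry has no first-neighbor pairs")
    d = np.linalg.norm(
        coords.coordinates[pairs[:, 0]] - coords.coordinates[pairs[:, 1]], axis=1
    )
    return float(np.mean(np.abs(d - d.mean())))


def projection_distance(
    pre: ElectrodeSet, post: ElectrodeSet, brain_center: np.ndarray
) -> np.ndarray:
    """Per-contact displacement normalized by the distance to the brain center.

    dProj_j = ||e0_j - e_j|| / ||e0_j - center||; scale-invariant, 0 when
    the projection leaves a contact unmoved.
    """
    center = np.asarray(brain_center, dtype=float)
    disp = np.linalg.norm(pre.coordinates - post.coordinates, axis=1)
    ref = np.linalg.norm(pre.coordinates - center, axis=1)
    if np.any(ref <= 0):
        raise ValueError("a contact coincides with the brain center")
    return disp / ref


def local_deformation(coords: ElectrodeSet) -> np.ndarray:
    """Per-contact mean first-neighbor distance in units of D.

    s_j = (1 / (D * NNeig)) * sum_k ||e_j - e_k||; exactly 1 everywhere for
    an undeformed array, > 1 where the lattice expanded locally.
    """
    geometry = coords.geometry
    pairs = first_neighbor_pairs(geometry)
    if pairs.size == 0:
        raise ValueError("geometry has no first neighbors")
    d = np.linalg.norm(coords.coordinates[pairs[:, 0]] - coords.coordinates[pairs[:, 1]], axis=1)
    total = np.zeros(geometry.n_elec)
    count = np.zeros(geometry.n_elec)
    np.add.at(total, pairs[:, 0], d)
    np.add.at(total, pairs[:, 1], d)
    np.add.at(count, pairs[:, 0], 1.0)
    np.add.at(count, pairs[:, 1], 1.0)
    return total / (geometry.ied * count)


def estimated_hfa(
    coords: ElectrodeSet, pial: SurfaceMesh, floor: float = 0.5
) -> np.ndarray:
    """Expected high-frequency-activity score from cortex proximity.

    Neural high-frequency power recorded by a subdural contact decays with
    its distance to the pial surface, so -log(distance + floor) gives a
    per-contact expected-intensity pattern (natural log; ``floor`` in mm
    avoids the singularity at contact-on-cortex).  Only the ranking and
    relative differences are meaningful.
    """
    d = MeshQuery(pial).distance(coords.coordinates)
    return -np.log(d + floor)


def anatomical_labels(
    coords: ElectrodeSet,
    label_volume: np.ndarray,
    affine: np.ndarray,
    radius: float = 3.0,
) -> list[dict[int, float]]:
    """Probabilistic anatomical labels within a sphere around each contact.

    For each contact, the fraction of voxels of every label value inside
    the ``radius``-mm sphere (voxel centers, in the volume's world frame).
    Fractions sum to 1; background (0) is a label like any other.
    """
    inv = np.linalg.inv(affine)
    vol = np.asarray(label_volume)
    # voxel extent of the sphere along each axis
    scale = np.linalg.norm(affine[:3, :3], axis=0)
    out: list[dict[int, float]] = []
    for e in coords.coordinates:
        vc = (inv @ np.append(e, 1.0))[:3]
        lo = np.floor(vc - radius / scale).astype(int)
        hi = np.ceil(vc + radius / scale).astype(int)
        if np.any(hi < 0) or np.any(lo >= vol.shape):
            raise ValueError(f"contact at {e} outside the label volume")
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array(vol.shape) - 1)
        axes = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
        gi, gj, gk = np.meshgrid(*axes, indexing="ij")
        idx = np.column_stack([gi.ravel(), gj.ravel(), gk.ravel()])
        world = (affine @ np.column_stack([idx, np.ones(len(idx))]).T).T[:, :3]
        inside = np.linalg.norm(world - e, axis=1) <= radius
        if not inside.any():
            raise ValueError(f"no voxels within {radius} mm of contact at {e}")
        labels = vol[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        uniq, counts = np.unique(labels, return_counts=True)
        frac = counts / counts.sum()
        out.append({int(k): float(v) for k, v in zip(uniq, frac)})
    return out
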