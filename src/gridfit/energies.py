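"""Energy terms of the array-fitting and projection cost functions.

The fit cost is

    E_Fit = kTrans * ETrans + kDef * EDef - kCorr * ECorr

where ETrans penalizes translation of the structural points away from their
initial placement, EDef the relative strain of the spring mesh, and ECorr
(entering with a minus sign, hence maximized) rewards proximity of the
contacts to high-intensity CT voxels through Gaussian kernels of width sigma.

The projection cost adds quadratic anchor attraction and a roughness term,
the mean squared discrete Laplacian of the inter-electrode-distance
deformation field, which favors spatially smooth deformations.

Every term has a hand-derived analytic gradient; the test suite checks all
of them against brute-force double-loop implementations and finite
differences.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve, convolve2d

from .arrays import ArrayGeometry, ArrayModel
from .data import VoxelCloud

__all__ = [
    "translation_energy",
    "deformation_energy",
    "correlation_energy",
    "energy_translation",
    "energy_deformation",
    "energy_correlation",
    "total_energy",
    "energy_anchor",
    "anchor_energy",
    "energy_roughness",
    "roughness_energy",
    "LAPLACIAN_2D",
    "LAPLACIAN_1D",
]

#: nine-point Laplacian stencil used for grid roughness (config-overridable)
LAPLACIAN_2D = np.array([[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]])
#: three-point stencil for strips and narrow grids
LAPLACIAN_1D = np.array([1.0, -2.0, 1.0])


# ---------------------------------------------------------------------------
# low-level terms (array in, scalar [+ gradient] out)

def translation_energy(
    points: np.ndarray, initial_points: np.ndarray, grad: bool = False
):
    """Mean squared displacement of the structural points from m0 (mm^2)."""
    diff = points - initial_points
    n = points.shape[0]
    e = float(np.sum(diff * diff)) / n
    if not grad:
        return e
    return e, (2.0 / n) * diff


def deformation_energy(
    points: np.ndarray,
    pairs: np.ndarray,
    alphas: np.ndarray,
    rest_lengths: np.ndarray,
    grad: bool = False,
):
    """Mean weighted squared relative strain of the spring connections.

    Zero for any rigid motion of the whole mesh; dimensionless.
    """
    n_conn = pairs.shape[0]
    if n_conn == 0:
        return (0.0, np.zeros_like(points)) if grad else 0.0
    vec = points[pairs[:, 0]] - points[pairs[:, 1]]
    d = np.linalg.norm(vec, axis=1)
    strain = (rest_lengths - d) / rest_lengths
    e = float(np.sum(alphas * strain * strain)) / n_conn
    if not grad:
        return e
    # dE/dd = -2 alpha strain / d0 ; dd/dp_j = vec/d
    safe_d = np.where(d > 0, d, 1.0)
    coef = (-2.0 * alphas * strain / rest_lengths / n_conn / safe_d)[:, None]
    g = np.zeros_like(points)
    np.add.at(g, pairs[:, 0], coef * vec)
    np.add.at(g, pairs[:, 1], -coef * vec)
    return e, g


def correlation_energy(
    electrodes: np.ndarray,
    voxels: np.ndarray,
    weights: np.ndarray,
    sigma: float,
    u: np.ndarray,
    n_mod: int,
    grad: bool = False,
):
    """Gaussian co-registration term between contacts and CT voxels.

    E = 1/(NMod W sigma sqrt(2 pi)) * sum_n sum_j w_n u_j exp(-|v_n-e_j|^2 / 2 sigma^2)

    Intensity-weighted so bright artifact cores dominate; normalized by the
    total intensity W, so rescaling all intensities leaves E unchanged.
    The gradient is returned with respect to the electrode coordinates.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    W = float(weights.sum())
    if W <= 0:
        raise ValueError("cloud has zero total intensity")
    c = 1.0 / (n_mod * W * sigma * np.sqrt(2.0 * np.pi))
    diff = voxels[None, :, :] - electrodes[:, None, :]  # (J, N, 3)
    r2 = np.einsum("jnd,jnd->jn", diff, diff)
    g = np.exp(-r2 / (2.0 * sigma * sigma))
    per_elec = g @ weights  # (J,)
    e = float(c * np.dot(u, per_elec))
    if not grad:
        return e
    # dE/de_j = c u_j / sigma^2 * sum_n w_n g_jn (v_n - e_j)
    wg = g * weights[None, :]
    grad_e = (c / (sigma * sigma)) * u[:, None] * np.einsum("jn,jnd->jd", wg, diff)
    return e, grad_e


def anchor_energy(coords: np.ndarray, anchors: np.ndarray, grad: bool = False):
    """Mean squared distance between contacts and one anchor set (mm^2)."""
    if coords.shape != anchors.shape:
        raise ValueError("coords and anchors must have matching shape")
    n = coords.shape[0]
    diff = coords - anchors
    e = float(np.sum(diff * diff)) / n
    if not grad:
        return e
    return e, (2.0 / n) * diff


# ---------------------------------------------------------------------------
# roughness

def _distance_matrices(coords: np.ndarray, n_rows: int, n_cols: int):
    """Horizontal/vertical first-neighbor distance matrices of a grid layout."""
    e = coords.reshape(n_rows, n_cols, 3)
    dh = np.linalg.norm(e[:, 1:] - e[:, :-1], axis=2)  # (rows, cols-1)
    dv = np.linalg.norm(e[1:, :] - e[:-1, :], axis=2)  # (rows-1, cols)
    return dh, dv


def roughness_energy(
    coords: np.ndarray,
    geometry: ArrayGeometry,
    rest_ied: float | None = None,
    kernel2d: np.ndarray = LAPLACIAN_2D,
    kernel1d: np.ndarray = LAPLACIAN_1D,
    grad: bool = False,
):
    """Mean squared Laplacian of the deformation field G = D0 - D.

    Uses the 2D nine-point stencil for grids with at least 4 rows and
    columns, and the 1D [1 -2 1] stencil along the longest dimension for
    strips and 2-3-row grids.  Uniform deformation (constant G) has zero
    Laplacian, so only spatially *inhomogeneous* deformation is penalized.
    NAdj is the number of adjacent contact pairs.
    """
    n_rows, n_cols = geometry.n_rows, geometry.n_cols
    D = rest_ied if rest_ied is not None else geometry.ied
    coords = coords.reshape(-1, 3)
    if n_rows > n_cols:  # normalize layout: rows <= cols
        coords = coords.reshape(n_rows, n_cols, 3).transpose(1, 0, 2).reshape(-1, 3)
        n_rows, n_cols = n_cols, n_rows
    n_adj = n_rows * (n_cols - 1) + (n_rows - 1) * n_cols
    if n_adj < 3:
        return (0.0, np.zeros_like(coords)) if grad else 0.0

    dh, dv = _distance_matrices(coords, n_rows, n_cols)
    gh, gv = D - dh, D - dv

    grad_gh = np.zeros_like(gh)
    grad_gv = np.zeros_like(gv)
    e = 0.0
    if n_rows >= 4:
        lh = convolve2d(gh, kernel2d, mode="valid")
        lv = convolve2d(gv, kernel2d, mode="valid")
        e = (np.sum(lh * lh) + np.sum(lv * lv)) / n_adj
        if grad:
            flip = kernel2d[::-1, ::-1]
            grad_gh = convolve2d(lh, flip, mode="full") * (2.0 / n_adj)
            grad_gv = convolve2d(lv, flip, mode="full") * (2.0 / n_adj)
    else:
        # 1D stencil row-wise along the longest dimension
        if gh.shape[1] >= kernel1d.size:
            lh = np.stack([convolve(row, kernel1d, mode="valid") for row in gh])
            e = np.sum(lh * lh) / n_adj
            if grad:
                flip1 = kernel1d[::-1]
                grad_gh = np.stack(
                    [convolve(row, flip1, mode="full") for row in lh]
                ) * (2.0 / n_adj)
    if not grad:
        return float(e)

    # chain rule back to coordinates: dG/dD = -1, dD/de = unit vectors
    g = np.zeros((n_rows * n_cols, 3))
    e3 = coords.reshape(n_rows, n_cols, 3)

    def accumulate(gmat, a_idx, b_idx, dmat):
        vec = e3.reshape(n_rows, n_cols, 3)
        diff = vec[a_idx] - vec[b_idx]
        safe = np.where(dmat > 0, dmat, 1.0)[..., None]
        contrib = -gmat[..., None] * diff / safe
        flat = g.reshape(n_rows, n_cols, 3)
        np.add.at(flat, a_idx, contrib)
        np.add.at(flat, b_idx, -contrib)

    rows_h = np.arange(n_rows)[:, None], np.arange(1, n_cols)[None, :]
    rows_h0 = np.arange(n_rows)[:, None], np.arange(n_cols - 1)[None, :]
    accumulate(grad_gh, rows_h, rows_h0, dh)
    rows_v = np.arange(1, n_rows)[:, None], np.arange(n_cols)[None, :]
    rows_v0 = np.arange(n_rows - 1)[:, None], np.arange(n_cols)[None, :]
    accumulate(grad_gv, rows_v, rows_v0, dv)

    if geometry.n_rows > geometry.n_cols:  # undo the layout transpose
        g = g.reshape(n_rows, n_cols, 3).transpose(1, 0, 2).reshape(-1, 3)
    return float(e), g


# ---------------------------------------------------------------------------
# model-level wrappers

def energy_translation(model: ArrayModel) -> float:
    """ETrans of a model's current configuration (mm^2)."""
    return translation_energy(model.points, model.initial_points)


def energy_deformation(model: ArrayModel) -> float:
    """EDef of a model's current configuration (dimensionless)."""
    return deformation_energy(
        model.points, model.connection_pairs, model.alphas, model.rest_lengths
    )


def energy_correlation(
    model: ArrayModel, cloud: VoxelCloud, sigma: float, u: np.ndarray
) -> float:
    """ECorr between the model's contacts and a voxel cloud."""
    return correlation_energy(
        model.electrode_points,
        cloud.coordinates,
        cloud.intensities,
        sigma,
        np.asarray(u, dtype=float),
        model.n_points,
    )


def total_energy(
    model: ArrayModel, cloud: VoxelCloud, config, u: np.ndarray, sigma: float | None = None
) -> float:
    """E_Fit = kTrans ETrans + kDef EDef - kCorr ECorr.

    ``sigma`` defaults to the first-step Gaussian width of ``config``.
    """
    s = sigma if sigma is not None else config.sigma_step1
    return (
        config.k_trans * energy_translation(model)
        + config.k_def * energy_deformation(model)
        - config.k_corr * energy_correlation(model, cloud, s, u)
    )


def energy_anchor(coords: np.ndarray, anchors) -> float:
    """EAnch for one anchor set: mean squared contact-to-anchor distance."""
    anchor_xyz = getattr(anchors, "coordinates", anchors)
    return anchor_energy(np.asarray(coords, dtype=float), np.asarray(anchor_xyz, dtype=float))


def energy_roughness(coords, geometry: ArrayGeometry, rest_ied: float | None = None) -> float:
    """ERough of an electrode layout (see :func:`roughness_energy`)."""
    xyz = getattr(coords, "coordinates", coords)
    return roughness_energy(np.asarray(xyz, dtype=float), geometry, rest_ied)
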