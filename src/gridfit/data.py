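"""Core data containers: thresholded CT voxel clouds and electrode sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .arrays import ArrayGeometry

__all__ = ["VoxelCloud", "ElectrodeSet"]


@dataclass
class VoxelCloud:
    """Thresholded CT voxels representing one electrode array.

    ``coordinates`` are world-frame mm positions v_n of the NVox voxel
    centers; ``intensities`` the CT values w_n, min-max normalized to [0, 1]
    so that high-intensity metal-artifact cores dominate the co-registration
    energy regardless of scanner calibration.
    """

    coordinates: np.ndarray
    intensities: np.ndarray
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (NVox, 3)")
        if self.intensities.shape[0] != self.coordinates.shape[0]:
            raise ValueError("one intensity per voxel required")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_voxels(self) -> int:
        return self.coordinates.shape[0]

    @property
    def total_weight(self) -> float:
        """W = sum of voxel intensities."""
        return float(self.intensities.sum())

    def normalize(self) -> "VoxelCloud":
        """Linear min-max rescale of intensities to [0, 1]."""
        w = self.intensities
        lo, hi = w.min(), w.max()
        if hi == lo:
            norm = np.ones_like(w)
        else:
            norm = (w - lo) / (hi - lo)
        return replace(self, intensities=norm, normalized=True)

    def check_against(self, geometry: ArrayGeometry) -> None:
        """Warn when the cloud is sparser than the array it should represent."""
        if self.n_voxels < geometry.n_elec:
            warnings.warn(
                f"cloud has {self.n_voxels} voxels for {geometry.n_elec} contacts; "
                "fit proceeds but information is missing",
                stacklevel=2,
            )

    def transformed(self, func) -> "VoxelCloud":
        return replace(self, coordinates=np.asarray(func(self.coordinates), dtype=float))


@dataclass
class ElectrodeSet:
    """Ordered contact coordinates of one array (row-major, row 1 col 1 first)."""

    coordinates: np.ndarray
    geometry: ArrayGeometry
    labels: list[str] | None = None
    provenance: str = "initial"

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.shape != (self.geometry.n_elec, 3):
            raise ValueError(
                f"expected ({self.geometry.n_elec}, 3) coordinates, got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None and len(self.labels) != self.geometry.n_elec:
            raise ValueError("one label per contact required")

    @property
    def n_elec(self) -> int:
        return self.geometry.n_elec

    def with_coordinates(self, coords: np.ndarray, provenance: str | None = None) -> "ElectrodeSet":
        return replace(
            self,
            coordinates=np.asarray(coords, dtype=float),
            provenance=provenance or self.provenance,
        )

    def default_labels(self, prefix: str = "E") -> list[str]:
        return [f"{prefix}{i + 1}" for i in range(self.n_elec)]
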