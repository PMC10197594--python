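"""Readers/writers for volumes, surfaces, electrode tables, and configs.

All world coordinates are millimetres in the co-registered scanner frame;
voxel indices are 0-based and never leave this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .arrays import ArrayGeometry
from .data import ElectrodeSet, VoxelCloud
from .mesh import SurfaceMesh

__all__ = [
    "VolumeImage",
    "extract_voxel_cloud",
    "read_volume",
    "read_surface",
    "write_surface",
    "read_electrodes",
    "write_electrodes",
    "read_cloud_tsv",
    "write_cloud_tsv",
    "load_config",
]

ELECTRODE_COLUMNS = ["name", "x", "y", "z", "group", "array_type", "n_rows",
                     "n_cols", "ied_mm", "provenance", "projection_method"]


@dataclass
class VolumeImage:
    """3D intensity lattice with a voxel-to-world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        ijk1 = np.column_stack([indices, np.ones(len(indices))])
        return (self.affine @ ijk1.T).T[:, :3]


def read_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asanyarray(img.dataobj), img.affine)


def extract_voxel_cloud(
    ct: VolumeImage,
    brain_mask: VolumeImage,
    threshold: float,
    morph_iterations: int = 0,
    selection: VolumeImage | None = None,
) -> VoxelCloud:
    """Threshold the masked CT into an electrode-artifact voxel cloud.

    The brain mask removes the skull; ``morph_iterations`` erodes it
    (positive) or dilates it (negative) to trim residual bone or recover
    contacts at the brain edge.  Voxels above ``threshold`` (after an
    optional user selection mask) become the cloud, mapped through the
    affine to mm, with intensities min-max normalized to [0, 1].
    """
    if ct.data.shape != brain_mask.data.shape:
        raise ValueError("CT and mask must share a lattice")
    if not np.allclose(ct.affine, brain_mask.affine, atol=1e-4):
        raise ValueError("CT and mask affines differ; images are not co-registered")
    mask = brain_mask.data > 0
    if morph_iterations > 0:
        mask = ndimage.binary_erosion(mask, iterations=morph_iterations)
    elif morph_iterations < 0:
        mask = ndimage.binary_dilation(mask, iterations=-morph_iterations)
    keep = mask & (ct.data > threshold)
    if selection is not None:
        if selection.data.shape != ct.data.shape:
            raise ValueError("selection mask must share the CT lattice")
        keep &= selection.data > 0
    idx = np.column_stack(np.nonzero(keep))
    if idx.size == 0:
        raise ValueError("no voxels above threshold inside the mask")
    coords = ct.world_coordinates(idx)
    intensities = ct.data[keep].astype(float)
    return VoxelCloud(coords, intensities).normalize()


# ---------------------------------------------------------------------------
# surfaces

def read_surface(path: str | Path) -> SurfaceMesh:
    """Read a FreeSurfer binary surface or GIfTI mesh (world mm frame).

    FreeSurfer surfaces are shifted by the c_ras offset so vertices land in
    the volume's scanner coordinates.
    """
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        verts = faces = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = np.asarray(da.data, dtype=float)
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(da.data, dtype=int)
        if verts is None or faces is None:
            raise ValueError(f"{path} lacks pointset/triangle arrays")
        return SurfaceMesh(verts, faces)
    if path.suffix == ".ply":
        import trimesh

        mesh = trimesh.load(str(path), process=False)
        return SurfaceMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    # FreeSurfer binary geometry
    verts, faces, meta = nib.freesurfer.read_geometry(str(path), read_metadata=True)
    cras = np.asarray(meta.get("cras", np.zeros(3)), dtype=float)
    return SurfaceMesh(np.asarray(verts, dtype=float) + cras, np.asarray(faces, dtype=int))


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write GIfTI (.gii) or PLY (.ply)."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif path.suffix == ".ply":
        mesh.trimesh.export(str(path))
    else:
        raise ValueError(f"unsupported surface format {path.suffix!r}")


# ---------------------------------------------------------------------------
# electrode tables

def write_electrodes(
    electrodes: ElectrodeSet,
    path: str | Path,
    group: str = "array1",
    projection_method: str = "n/a",
) -> None:
    """Write a BIDS-iEEG-style TSV (full float precision, row-major order)."""
    g = electrodes.geometry
    names = electrodes.labels or electrodes.default_labels()
    df = pd.DataFrame(
        {
            "name": names,
            "x": electrodes.coordinates[:, 0],
            "y": electrodes.coordinates[:, 1],
            "z": electrodes.coordinates[:, 2],
            "group": group,
            "array_type": g.array_type.value,
            "n_rows": g.n_rows,
            "n_cols": g.n_cols,
            "ied_mm": g.ied,
            "provenance": electrodes.provenance,
            "projection_method": projection_method,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_electrodes(path: str | Path) -> ElectrodeSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ELECTRODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"electrode table {path} lacks columns {missing}")
    geometry = ArrayGeometry(
        array_type=str(df.array_type.iloc[0]),
        n_rows=int(df.n_rows.iloc[0]),
        n_cols=int(df.n_cols.iloc[0]),
        ied=float(df.ied_mm.iloc[0]),
    )
    return ElectrodeSet(
        df[["x", "y", "z"]].to_numpy(dtype=float),
        geometry,
        labels=df.name.astype(str).tolist(),
        provenance=str(df.provenance.iloc[0]),
    )


# ---------------------------------------------------------------------------
# voxel cloud TSV

def write_cloud_tsv(cloud: VoxelCloud, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_mm": cloud.coordinates[:, 0],
            "y_mm": cloud.coordinates[:, 1],
            "z_mm": cloud.coordinates[:, 2],
            "intensity": cloud.intensities,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cloud_tsv(path: str | Path) -> VoxelCloud:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["x_mm", "y_mm", "z_mm", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cloud table {path} lacks columns {missing}")
    return VoxelCloud(df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
                      df.intensity.to_numpy(dtype=float))


def load_config(path: str | Path) -> dict:
    """YAML or JSON config mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
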