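"""NIfTI volume handling: grids, masks, coordinate conversion, cluster labeling.

All stages of the pipeline exchange :class:`StatVolume` objects — a 3-D
scalar field living on a :class:`VolumeGrid` that carries the voxel-to-mm
affine.  Voxel indices are 0-based; millimetre coordinates follow the NIfTI
affine convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "StatVolume",
    "BrainMask",
    "read_nifti",
    "write_nifti",
    "label_clusters",
    "mm_to_voxel",
    "voxel_to_mm",
    "CLUSTER_TABLE_COLUMNS",
]

#: statistic kinds a StatVolume may carry
VALID_KINDS = frozenset(
    {"contrast", "t", "z", "logodds", "posterior_mean", "posterior_var"}
)

CLUSTER_TABLE_COLUMNS = [
    "cluster_id",
    "size_voxels",
    "peak_value",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
    "fwe_p",
]


class VolumeGrid:
    """A 3-D voxel grid with an affine mapping voxel indices to mm space."""

    __slots__ = ("shape", "affine")

    def __init__(self, shape, affine):
        shape = tuple(int(s) for s in shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if not np.all(np.isfinite(affine)):
            raise ValueError("affine contains non-finite entries")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is singular")
        self.shape = shape
        self.affine = affine

    @classmethod
    def from_spacing(cls, shape, voxel_size_mm, origin_mm=(0.0, 0.0, 0.0)):
        """Axis-aligned grid with the given voxel sizes and mm origin."""
        vs = np.asarray(voxel_size_mm, dtype=float)
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValueError("voxel_size_mm must be 3 positive reals")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vs)
        affine[:3, 3] = origin_mm
        return cls(shape, affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel size: column norms of the affine's 3x3 block."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def __eq__(self, other):
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )

    def __repr__(self):
        vs = np.round(self.voxel_size_mm, 3)
        return f"VolumeGrid(shape={self.shape}, voxel_size_mm={tuple(vs)})"


@dataclass
class StatVolume:
    """A scalar field on a voxel grid, tagged with what statistic it holds."""

    grid: VolumeGrid
    values: np.ndarray
    kind: str = "contrast"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {sorted(VALID_KINDS)}")

    def copy(self) -> "StatVolume":
        return StatVolume(self.grid, self.values.copy(), self.kind)


@dataclass
class BrainMask:
    """Boolean in-brain indicator on a grid; ``V`` is the search-volume size."""

    grid: VolumeGrid
    inside: np.ndarray

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.inside.any():
            raise ValueError("mask is empty (V = 0)")

    @property
    def V(self) -> int:
        return int(self.inside.sum())


def read_nifti(path, kind: str = "contrast") -> StatVolume:
    """Load a single-volume NIfTI-1/2 image as a :class:`StatVolume`.

    4-D files are rejected unless the trailing dimension is a singleton
    (each subject must contribute exactly one image).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected 3-D volume, got shape {data.shape} in {path}"
        )
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)):
        raise ValueError(f"non-finite affine in {path}")
    return StatVolume(VolumeGrid(data.shape, affine), data, kind)


def write_nifti(vol: StatVolume, path) -> None:
    """Write a :class:`StatVolume` to disk as float32 NIfTI-1.

    NaN payloads (out-of-mask convention) pass through unchanged.
    """
    data = np.asarray(vol.values, dtype=np.float32)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_data_dtype(np.float32)
    img.to_filename(str(path))


_CONNECTIVITY_ORDER = {6: 1, 18: 2, 26: 3}


def label_clusters(binary, connectivity: int = 18, grid: VolumeGrid | None = None,
                   values: np.ndarray | None = None):
    """Label connected components of a binary 3-D map.

    Returns ``(labels, table)`` where ``labels`` assigns 1..K with clusters
    ordered by descending size then lexicographic peak voxel index, and
    ``table`` is a DataFrame with one row per cluster
    (columns :data:`CLUSTER_TABLE_COLUMNS`; ``fwe_p`` is NaN here — cluster
    inference fills it in).  ``values`` (if given) defines the peak; without
    it the lexicographically smallest voxel of the cluster is the peak and
    its value is reported as 1.0.
    """
    if connectivity not in _CONNECTIVITY_ORDER:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 3:
        raise ValueError("binary map must be 3-D")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_ORDER[connectivity])
    raw_labels, n = ndimage.label(binary, structure=structure)

    entries = []
    for lab in range(1, n + 1):
        idx = np.argwhere(raw_labels == lab)
        # lexicographic voxel order for deterministic peaks/ties
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        idx = idx[order]
        if values is not None:
            vals = values[idx[:, 0], idx[:, 1], idx[:, 2]]
            peak_pos = idx[int(np.argmax(vals))]
            peak_val = float(np.max(vals))
        else:
            peak_pos = idx[0]
            peak_val = 1.0
        entries.append((len(idx), tuple(peak_pos), peak_val, lab))

    entries.sort(key=lambda e: (-e[0], e[1]))

    labels = np.zeros_like(raw_labels)
    rows = []
    for new_id, (size, peak_vox, peak_val, old_lab) in enumerate(entries, start=1):
        labels[raw_labels == old_lab] = new_id
        if grid is not None:
            peak_mm = voxel_to_mm(peak_vox, grid)
        else:
            peak_mm = tuple(float(p) for p in peak_vox)
        rows.append(
            {
                "cluster_id": new_id,
                "size_voxels": int(size),
                "peak_value": peak_val,
                "peak_x_mm": peak_mm[0],
                "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2],
                "fwe_p": np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    return labels, table


def voxel_to_mm(voxel, grid: VolumeGrid):
    """Map a 0-based voxel index to mm coordinates through the affine."""
    v = np.asarray(voxel, dtype=float)
    return tuple((grid.affine @ np.append(v, 1.0))[:3])


def mm_to_voxel(coord_mm, grid: VolumeGrid):
    """Map a mm coordinate to the nearest voxel index.

    Rounds half away from zero; raises if the rounded index falls outside
    the grid.
    """
    hom = np.append(np.asarray(coord_mm, dtype=float), 1.0)
    v = (np.linalg.inv(grid.affine) @ hom)[:3]
    rounded = np.sign(v) * np.floor(np.abs(v) + 0.5)
    idx = tuple(int(r) for r in rounded)
    for a, (i, s) in enumerate(zip(idx, grid.shape)):
        if not 0 <= i < s:
            raise ValueError(
                f"mm coordinate {tuple(coord_mm)} maps to voxel {idx}, outside "
                f"grid axis {a} of extent {s}"
            )
    return idx
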