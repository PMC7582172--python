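"""Core containers and NIfTI/TSV I/O helpers.

Voxel sets are represented throughout as sorted 1-D arrays of flat (C-order)
indices into a fixed 3-D grid; a :class:`BoldRun` stores the 4-D data array
together with its repetition time and voxel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class BoldRun:
    """One subject's 4-D BOLD run.

    data : float array, shape (X, Y, Z, T)
    tr_seconds : sampling interval of the time axis
    voxel_size_mm : isotropic voxel edge length
    """

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: float = 2.15
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise GeometryError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if self.tr_seconds <= 0:
            raise GeometryError("TR must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    def flat(self) -> np.ndarray:
        """View of the data as (n_voxels, T)."""
        return self.data.reshape(-1, self.data.shape[3])

    def copy(self) -> "BoldRun":
        return BoldRun(self.data.copy(), self.tr_seconds, self.voxel_size_mm, self.subject_id)


def mask_to_indices(mask: np.ndarray) -> np.ndarray:
    """Flat indices of the True voxels of a 3-D boolean mask."""
    return np.flatnonzero(mask.ravel())


def indices_to_mask(indices: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(int(np.prod(grid_shape)), dtype=bool)
    mask[np.asarray(indices, dtype=np.intp)] = True
    return mask.reshape(grid_shape)


def block_indices(origin, shape, grid_shape) -> np.ndarray:
    """Flat indices of an axis-aligned voxel block; errors if outside the grid."""
    origin = tuple(int(v) for v in origin)
    shape = tuple(int(v) for v in shape)
    for o, s, g in zip(origin, shape, grid_shape):
        if o < 0 or s <= 0 or o + s > g:
            raise GeometryError(f"block origin={origin} shape={shape} outside grid {grid_shape}")
    xs, ys, zs = (np.arange(o, o + s) for o, s in zip(origin, shape))
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    return np.ravel_multi_index((grid[:, 0], grid[:, 1], grid[:, 2]), grid_shape)


# ---------------------------------------------------------------------------
# I/O


def write_bold(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms((run.voxel_size_mm,) * 3 + (run.tr_seconds,))
    nib.save(img, str(path))


def read_bold(path, subject_id: str = "") -> BoldRun:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return BoldRun(
        np.asarray(img.dataobj, dtype=np.float64),
        tr_seconds=float(zooms[3]),
        voxel_size_mm=float(zooms[0]),
        subject_id=subject_id,
    )


def write_mask(mask: np.ndarray, voxel_size_mm: float, path) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.int16), affine), str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_labels(label_volume: np.ndarray, voxel_size_mm: float, path) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(label_volume.astype(np.int16), affine), str(path))


def read_motion_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if list(table.columns) != MOTION_COLUMNS:
        raise FormatError(f"motion table must have columns {MOTION_COLUMNS}, got {list(table.columns)}")
    return table
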