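"""Parcel and voxel functional connectivity (Fisher-z Pearson correlation)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .core import BoldRun
from .errors import ValidationError

logger = logging.getLogger(__name__)

R_CLAMP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """Fisher-z connectivity between all parcel pairs of one subject.

    The diagonal is undefined (NaN); rows/columns of zero-variance parcels are
    NaN as well.
    """

    subject_id: str
    parcel_names: list
    z: np.ndarray

    def value(self, a: str, b: str) -> float:
        i, j = self.parcel_names.index(a), self.parcel_names.index(b)
        return float(self.z[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.parcel_names, columns=self.parcel_names)


@dataclass
class SeedVoxelMap:
    """Per-voxel Fisher-z FC of one seed within one search space."""

    subject_id: str
    seed_name: str
    space_name: str
    voxels: np.ndarray     # flat indices, defines the search space
    z: np.ndarray          # same length as voxels

    def __post_init__(self) -> None:
        if len(self.voxels) != len(self.z):
            raise ValidationError("voxel and value arrays must align")


def parcel_mean_timecourse(run: BoldRun, voxels: np.ndarray) -> np.ndarray:
    """Unweighted mean over the parcel's voxels at each timepoint."""
    voxels = np.asarray(voxels, dtype=np.intp)
    if voxels.size == 0:
        raise ValidationError("empty voxel set")
    n_vox = int(np.prod(run.grid_shape))
    if voxels.min() < 0 or voxels.max() >= n_vox:
        raise ValidationError("voxel indices outside grid")
    return run.flat()[voxels].mean(axis=0)


def fisher_z(r):
    """z = atanh(r); |r| within 1e-7 of 1 is clamped (with a warning)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValidationError("correlation outside [-1, 1]")
    clipped = np.clip(r, -R_CLAMP, R_CLAMP)
    if np.any(np.abs(r) > R_CLAMP):
        logger.warning("correlation at +/-1 clamped before Fisher transform")
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def parcel_fc_matrix(run: BoldRun, atlas: ParcelAtlas) -> FCMatrix:
    """Pearson correlation of every parcel-pair's mean timecourses, Fisher-z'd."""
    names = list(atlas.parcels)
    tcs = np.vstack([parcel_mean_timecourse(run, atlas.parcels[n]) for n in names])
    sd = tcs.std(axis=1)
    valid = sd > 1e-12
    if not valid.all():
        logger.warning("zero-variance parcel timecourse(s): %s",
                       [n for n, v in zip(names, valid) if not v])
    z = np.full((len(names), len(names)), np.nan)
    if valid.any():
        r = np.corrcoef(tcs[valid])
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)   # enforce exact symmetry
        np.fill_diagonal(r, 0.0)   # diagonal is masked below, keep it off the clamp path
        z[np.ix_(valid, valid)] = fisher_z(r)
    np.fill_diagonal(z, np.nan)
    return FCMatrix(subject_id=run.subject_id, parcel_names=names, z=z)


def category_fc(fc: FCMatrix, seed, target: str, category_of: dict) -> float:
    """Mean Fisher-z over all seed-parcel x target-parcel pairs.

    ``seed`` is a category label or an explicit list of parcel names; seed and
    target parcel sets must be disjoint.
    """
    if isinstance(seed, str):
        seed_names = [n for n in fc.parcel_names if category_of.get(n) == seed]
    else:
        seed_names = list(seed)
    target_names = [n for n in fc.parcel_names if category_of.get(n) == target]
    if not seed_names or not target_names:
        raise ValidationError(f"empty seed ({seed!r}) or target ({target!r}) parcel set")
    if set(seed_names) & set(target_names):
        raise ValidationError("seed and target parcel sets overlap")
    idx = {n: i for i, n in enumerate(fc.parcel_names)}
    vals = [fc.z[idx[s], idx[t]] for s in seed_names for t in target_names]
    return float(np.mean(vals))


def seed_to_voxel_fc(run: BoldRun, seed_voxels: np.ndarray, search_space: np.ndarray,
                     subject_id: str = "", seed_name: str = "seed",
                     space_name: str = "space") -> SeedVoxelMap:
    """FC between the mean timecourse over the union of seed voxels and every
    voxel of the search space (size-weighted seed mean)."""
    search_space = np.asarray(search_space, dtype=np.intp)
    if search_space.size == 0:
        raise ValidationError("empty search space")
    seed_tc = parcel_mean_timecourse(run, np.unique(seed_voxels))
    seed_tc = seed_tc - seed_tc.mean()
    seed_norm = np.linalg.norm(seed_tc)
    if seed_norm == 0:
        raise ValidationError("zero-variance seed timecourse")

    vox = run.flat()[search_space]
    vox = vox - vox.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(vox, axis=1)
    zero = norms <= 1e-12
    if zero.any():
        logger.warning("%d zero-variance voxel(s) in search space; z set to 0", zero.sum())
    norms[zero] = 1.0
    r = (vox @ seed_tc) / (norms * seed_norm)
    r[zero] = 0.0
    z = fisher_z(np.clip(r, -1.0, 1.0))
    return SeedVoxelMap(subject_id or run.subject_id, seed_name, space_name,
                        voxels=search_space, z=z)
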