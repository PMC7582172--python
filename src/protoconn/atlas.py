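"""Parcel atlas finalization: overlap resolution, tissue exclusion, inventory.

A finalized :class:`ParcelAtlas` holds pairwise-disjoint, gray-matter-restricted
parcels grouped into categories, plus the anatomical search spaces (VTC,
frontal, temporal) used by the voxel-wise analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import mask_to_indices
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ParcelAtlas:
    grid_shape: tuple[int, int, int]
    parcels: dict                 # name -> sorted flat voxel indices, disjoint
    category_of: dict             # name -> category label
    search_spaces: dict = field(default_factory=dict)
    voxel_size_mm: float = 2.15

    def __post_init__(self) -> None:
        for name, voxels in self.parcels.items():
            if len(voxels) == 0:
                raise ValidationError(f"parcel {name!r} is empty")
            if name not in self.category_of:
                raise ValidationError(f"parcel {name!r} has no category")
        all_vox = np.concatenate(list(self.parcels.values())) if self.parcels else np.array([])
        if len(np.unique(all_vox)) != len(all_vox):
            raise ValidationError("finalized parcels must be pairwise disjoint")

    @property
    def categories(self) -> list:
        seen = []
        for name in self.parcels:
            cat = self.category_of[name]
            if cat not in seen:
                seen.append(cat)
        return seen

    def parcels_in_category(self, category: str) -> list:
        return [n for n in self.parcels if self.category_of[n] == category]

    def category_voxels(self, category: str) -> np.ndarray:
        names = self.parcels_in_category(category)
        if not names:
            raise ValidationError(f"no parcels in category {category!r}")
        return np.unique(np.concatenate([self.parcels[n] for n in names]))

    def label_volume(self) -> np.ndarray:
        """Integer label volume; parcel i (1-based, insertion order) marks its voxels."""
        vol = np.zeros(int(np.prod(self.grid_shape)), dtype=np.int16)
        for i, (name, voxels) in enumerate(self.parcels.items(), start=1):
            vol[voxels] = i
        return vol.reshape(self.grid_shape)


def resolve_parcel_overlaps(raw_parcels: dict) -> dict:
    """Assign every multiply-claimed voxel to the claimant with the smallest
    ORIGINAL size (ties broken by lexicographically first name); one pass."""
    if not raw_parcels:
        raise ValidationError("no parcels to resolve")
    order = sorted(raw_parcels, key=lambda n: (len(raw_parcels[n]), n))
    taken: set = set()
    resolved = {}
    for name in order:
        voxels = np.asarray(raw_parcels[name], dtype=np.intp)
        keep = voxels[~np.isin(voxels, list(taken))] if taken else voxels
        resolved[name] = np.sort(keep)
        taken.update(voxels.tolist())
    # preserve the caller's parcel order
    return {name: resolved[name] for name in raw_parcels}


def apply_tissue_exclusion(parcels: dict, gray_mask: np.ndarray, white_mask: np.ndarray,
                           cerebellum_mask: np.ndarray) -> dict:
    """Restrict parcels to gray matter and remove WM/cerebellum voxels; empty
    parcels are dropped with a warning, all-empty is a pipeline error."""
    allowed = mask_to_indices(gray_mask & ~white_mask & ~cerebellum_mask)
    out = {}
    for name, voxels in parcels.items():
        kept = np.intersect1d(np.asarray(voxels, dtype=np.intp), allowed)
        if kept.size == 0:
            logger.warning("parcel %r emptied by tissue exclusion; dropped", name)
            continue
        out[name] = kept
    if not out:
        raise PipelineError("tissue exclusion removed every parcel")
    return out


def finalize_atlas(raw_parcels: dict, category_of: dict, masks: dict,
                   search_spaces: dict | None = None,
                   grid_shape=None, voxel_size_mm: float = 2.15) -> ParcelAtlas:
    """Overlap resolution, then tissue exclusion, then validation.

    Search spaces are restricted to usable gray matter; if both a VTC and a
    temporal space are declared the temporal one must not intersect VTC (the
    temporal analysis is restricted to regions superior to VTC).
    """
    resolved = resolve_parcel_overlaps(raw_parcels)
    final = apply_tissue_exclusion(resolved, masks["gray"], masks["white"],
                                   masks["cerebellum"])
    grid_shape = tuple(grid_shape) if grid_shape is not None else masks["gray"].shape
    spaces = {}
    if search_spaces:
        allowed = mask_to_indices(masks["gray"] & ~masks["white"] & ~masks["cerebellum"])
        for name, voxels in search_spaces.items():
            spaces[name] = np.intersect1d(np.asarray(voxels, dtype=np.intp), allowed)
        if "VTC" in spaces and "temporal" in spaces:
            if np.intersect1d(spaces["VTC"], spaces["temporal"]).size:
                raise ValidationError("temporal search space must exclude VTC")
    return ParcelAtlas(grid_shape=grid_shape, parcels=final,
                       category_of={n: category_of[n] for n in final},
                       search_spaces=spaces, voxel_size_mm=voxel_size_mm)


def finalize_synthetic_atlas(synthetic) -> ParcelAtlas:
    """Convenience: finalize a :class:`~protoconn.synthetic.SyntheticAtlas`."""
    return finalize_atlas(synthetic.raw_parcels, synthetic.category_of,
                          synthetic.masks, synthetic.search_spaces,
                          synthetic.grid_shape, synthetic.voxel_size_mm)


def category_inventory(atlas: ParcelAtlas) -> pd.DataFrame:
    """One row per category: parcel count and total voxel count."""
    rows = [(cat,
             len(atlas.parcels_in_category(cat)),
             int(sum(len(atlas.parcels[n]) for n in atlas.parcels_in_category(cat))))
            for cat in atlas.categories]
    return pd.DataFrame(rows, columns=["category", "n_parcels", "n_voxels"])
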