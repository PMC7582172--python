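"""Percentile-threshold Dice sweep over seed-to-voxel FC maps.

For each percentile p of the in-search-space Fisher-z distribution, the map is
binarized at the p-th percentile threshold (strict >) and the suprathreshold
voxel set is compared against each candidate region with the Sorensen-Dice
coefficient 2|A∩B|/(|A|+|B|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import SeedVoxelMap
from .errors import ValidationError
from .stats import StatResult, attach_fdr, paired_ttest

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = tuple(range(50, 100, 5))   # 50, 55, ..., 95


@dataclass
class DiceSweepResult:
    subject_id: str
    seed: str
    space: str
    percentiles: tuple
    dice: pd.DataFrame         # index percentile, columns region names
    thresholds: np.ndarray     # z threshold per percentile
    counts: np.ndarray         # suprathreshold voxel count per percentile

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.percentiles):
            for region in self.dice.columns:
                rows.append((self.subject_id, p, region, self.dice.loc[p, region],
                             self.thresholds[i], self.counts[i]))
        return pd.DataFrame(rows, columns=["subject_id", "percentile", "region",
                                           "dice", "threshold", "n_voxels"])


def percentile_threshold(seed_map: SeedVoxelMap, p: float):
    """Threshold = p-th percentile (linear interpolation) of the map's z values;
    the suprathreshold set uses strict inequality."""
    if not 0 < p < 100:
        raise ValidationError("percentile must lie in (0, 100)")
    if len(seed_map.z) == 0:
        raise ValidationError("empty seed-to-voxel map")
    threshold = float(np.percentile(seed_map.z, p))
    supra = seed_map.voxels[seed_map.z > threshold]
    return threshold, supra


def dice_coefficient(a, b, union_formula: bool = False) -> float:
    """Sorensen-Dice 2|A∩B|/(|A|+|B|); both-empty gives 0 with a warning.

    ``union_formula`` selects the literal 2|A∩B|/|A∪B| variant for sensitivity
    analysis (it equals 2 for identical nonempty sets).
    """
    a = np.unique(np.asarray(a, dtype=np.intp))
    b = np.unique(np.asarray(b, dtype=np.intp))
    if a.size == 0 and b.size == 0:
        logger.warning("Dice of two empty sets defined as 0")
        return 0.0
    inter = np.intersect1d(a, b, assume_unique=True).size
    if union_formula:
        union = np.union1d(a, b).size
        return 2.0 * inter / union
    return 2.0 * inter / (a.size + b.size)


def run_dice_sweep(seed_map: SeedVoxelMap, regions: dict,
                   percentiles=DEFAULT_PERCENTILES,
                   union_formula: bool = False) -> DiceSweepResult:
    """Dice for every percentile x region; thresholds and counts recorded."""
    space = set(seed_map.voxels.tolist())
    for name, voxels in regions.items():
        if not set(np.asarray(voxels).tolist()) <= space:
            raise ValidationError(f"region {name!r} extends outside the search space")
    percentiles = tuple(percentiles)
    thresholds = np.empty(len(percentiles))
    counts = np.empty(len(percentiles), dtype=int)
    table = pd.DataFrame(index=list(percentiles), columns=list(regions), dtype=float)
    for i, p in enumerate(percentiles):
        thr, supra = percentile_threshold(seed_map, p)
        thresholds[i] = thr
        counts[i] = supra.size
        for name, voxels in regions.items():
            table.loc[p, name] = dice_coefficient(supra, voxels, union_formula)
    return DiceSweepResult(seed_map.subject_id, seed_map.seed_name,
                           seed_map.space_name, percentiles, table,
                           thresholds, counts)


def group_dice_summary(results) -> pd.DataFrame:
    """Mean dice +/- sem across subjects per percentile x region."""
    long = pd.concat([r.to_long() for r in results], ignore_index=True)
    grouped = long.groupby(["percentile", "region"])["dice"]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "dice_mean", "sem": "dice_sem", "count": "n"})


def sweep_group_test(results, focal_region: str, other_regions,
                     fdr_method: str = "bh"):
    """Per percentile: paired t-test of the focal region's dice against the
    per-subject mean dice of the other regions, FDR-corrected across percentiles."""
    if len(results) < 2:
        raise ValidationError("need >= 2 subjects")
    other_regions = list(other_regions)
    if focal_region in other_regions:
        raise ValidationError("focal region must not be among the others")
    percentiles = results[0].percentiles
    tests = []
    for p in percentiles:
        focal = np.array([r.dice.loc[p, focal_region] for r in results])
        others = np.array([r.dice.loc[p, other_regions].mean() for r in results])
        if np.all(focal == others):
            # no per-subject difference anywhere: t = 0, no evidence
            tests.append(StatResult(name=f"dice_p{p}", statistic=0.0,
                                    df=(len(results) - 1,), p_raw=1.0,
                                    effect_name="cohen_d", effect=0.0))
        else:
            tests.append(paired_ttest(focal, others, name=f"dice_p{p}"))
    return attach_fdr(tests, fdr_method)
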