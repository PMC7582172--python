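"""Connectivity fingerprints and within/between-group pattern dissimilarity.

A fingerprint is one seed's profile of mean Fisher-z FC to a fixed ordered set
of target categories (four per analysis), optionally mean-centered so that it
expresses pattern *shape* rather than overall connectivity level.  Group
dissimilarity is the Euclidean distance between a subject's fingerprint and the
average fingerprint of a reference group (leave-one-out within group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, category_fc
from .errors import ValidationError
from .stats import StatResult, attach_fdr, independent_ttest


@dataclass
class Fingerprint:
    subject_id: str
    seed: str
    categories: tuple
    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.categories):
            raise ValidationError("one value per target category required")
        if self.centered and abs(self.values.sum()) > 1e-10:
            raise ValidationError("centered fingerprint must sum to 0")


@dataclass
class DissimilarityRecord:
    subject_id: str
    group: str
    comparison: str     # "within" | "between"
    distance: float


def fingerprint_from_fc(fc: FCMatrix, seed, target_categories, category_of: dict,
                        seed_label: str | None = None, centered: bool = True) -> Fingerprint:
    """Build a subject's (optionally mean-centered) category-level fingerprint."""
    values = np.array([category_fc(fc, seed, t, category_of) for t in target_categories])
    label = seed_label or (seed if isinstance(seed, str) else "+".join(seed))
    fp = Fingerprint(fc.subject_id, label, tuple(target_categories), values, centered=False)
    return mean_centered_fingerprint(fp) if centered else fp


def mean_centered_fingerprint(fp: Fingerprint) -> Fingerprint:
    """Subtract the mean over the (four) categories from each value."""
    if len(fp.categories) != 4:
        raise ValidationError("fingerprint analyses use exactly 4 target categories")
    return Fingerprint(fp.subject_id, fp.seed, fp.categories,
                       fp.values - fp.values.mean(), centered=True)


def group_fingerprint(fingerprints) -> tuple[np.ndarray, np.ndarray]:
    """Per-category mean and standard error across subjects."""
    if len(fingerprints) < 2:
        raise ValidationError("need >= 2 subjects")
    ref = fingerprints[0]
    for fp in fingerprints[1:]:
        if fp.seed != ref.seed or fp.categories != ref.categories:
            raise ValidationError("fingerprints mix seeds or category orders")
    stack = np.vstack([fp.values for fp in fingerprints])
    return stack.mean(axis=0), stack.std(axis=0, ddof=1) / np.sqrt(len(fingerprints))


def pattern_distance(subject: Fingerprint, references, leave_one_out: bool,
                     comparison: str, group: str = "") -> DissimilarityRecord:
    """Euclidean distance from a subject to the mean fingerprint of references.

    With ``leave_one_out`` the subject must be among the references and is
    excluded from the reference mean (within-group reading of "others").
    """
    if not references:
        raise ValidationError("reference list must be nonempty")
    refs = list(references)
    if leave_one_out:
        kept = [fp for fp in refs if fp.subject_id != subject.subject_id]
        if len(kept) == len(refs):
            raise ValidationError("leave_one_out requires the subject among references")
        refs = kept
        if not refs:
            raise ValidationError("no references remain after leaving subject out")
    mean_ref = np.vstack([fp.values for fp in refs]).mean(axis=0)
    dist = float(np.linalg.norm(subject.values - mean_ref))
    return DissimilarityRecord(subject.subject_id, group, comparison, dist)


def group_dissimilarity_table(fingerprints_by_group: dict, fdr_method: str = "bh"):
    """Within- and between-group distances plus the three group comparisons.

    Returns ``(records_df, tests)`` where tests are the independent t-tests
    within-g1 vs within-g2, within-g1 vs between-g1 and within-g2 vs between-g2
    (each subject's between distance is to the other group's mean), FDR-adjusted
    as one family.
    """
    if len(fingerprints_by_group) != 2:
        raise ValidationError("exactly two groups required")
    (g1, fps1), (g2, fps2) = fingerprints_by_group.items()
    if len(fps1) < 2 or len(fps2) < 2:
        raise ValidationError("each group needs >= 2 subjects")

    records = []
    dist = {g1: {"within": [], "between": []}, g2: {"within": [], "between": []}}
    for group, own, other in [(g1, fps1, fps2), (g2, fps2, fps1)]:
        for fp in own:
            w = pattern_distance(fp, own, leave_one_out=True, comparison="within",
                                 group=group)
            b = pattern_distance(fp, other, leave_one_out=False, comparison="between",
                                 group=group)
            records.extend([w, b])
            dist[group]["within"].append(w.distance)
            dist[group]["between"].append(b.distance)

    # each comparison pairs disjoint subject sets: a group's within-distances
    # are compared against the OTHER group's between-distances, so the
    # two-sample t-test's independence assumption holds
    tests = [
        independent_ttest(dist[g1]["within"], dist[g2]["within"],
                          name=f"within-{g1}_vs_within-{g2}"),
        independent_ttest(dist[g1]["within"], dist[g2]["between"],
                          name=f"within-{g1}_vs_between"),
        independent_ttest(dist[g2]["within"], dist[g1]["between"],
                          name=f"within-{g2}_vs_between"),
    ]
    attach_fdr(tests, fdr_method)
    records_df = pd.DataFrame(
        [(r.subject_id, r.group, r.comparison, r.distance) for r in records],
        columns=["subject_id", "group", "comparison", "distance"])
    return records_df, tests
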