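"""Per-arm z-score outlier flagging and Venn-region candidate selection.

A feature is flagged for a treatment group when enough of that group's
samples are expression outliers (|z| at or beyond the threshold, boundary
inclusive).  The default requirement is a single sample — the smallest
positive fraction — which reproduces an outlier-style screen on the small
progressing arms.  Candidate features for cross-resistance are those
flagged in both progressing arms, i.e. the union of the AI∩SERM/SERD
pair-only region and the CR∩AI∩SERM/SERD triple region of the three-set
Venn partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from crossres.cohort import (
    Cohort,
    ExpressionMatrix,
    REGIMEN_AI,
    RESPONSE_CR,
    RESPONSE_PD,
)

GROUP_CR = "CR"
GROUP_AI_PD = "AI_PD"
GROUP_SERM_SERD_PD = "SERM_SERD_PD"
GROUPS = (GROUP_CR, GROUP_AI_PD, GROUP_SERM_SERD_PD)

DEFAULT_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class GroupFeatureSets:
    sets: dict  # group -> frozenset of feature ids
    z_threshold: float
    min_fraction: float | None  # None = "at least one sample"

    def __getitem__(self, group):
        return self.sets[group]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint regions of the three-set diagram, keyed by member tuples."""

    regions: dict  # tuple of group names (sorted) -> frozenset
    group_names: tuple

    @property
    def counts(self) -> dict:
        return {k: len(v) for k, v in self.regions.items()}

    def union(self) -> frozenset:
        out = frozenset()
        for v in self.regions.values():
            out |= v
        return out


def response_groups(cohort: Cohort) -> dict:
    """Map each TR sample to CR / AI_PD / SERM_SERD_PD."""
    assignment = {}
    for row in cohort.clinical.itertuples(index=False):
        if row.response == RESPONSE_CR:
            assignment[row.sample_id] = GROUP_CR
        elif row.response == RESPONSE_PD:
            assignment[row.sample_id] = (
                GROUP_AI_PD if row.regimen == REGIMEN_AI else GROUP_SERM_SERD_PD
            )
    return assignment


def flag_features(
    matrix: ExpressionMatrix,
    group_assignment: dict,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_fraction: float | None = None,
) -> GroupFeatureSets:
    """Flag features per group by the |z| >= threshold outlier criterion.

    ``min_fraction=None`` (default) flags a feature for a group as soon as
    one sample in the group is an outlier; otherwise the outlier fraction
    must reach ``min_fraction``.  Missing values never count as outliers.
    """
    groups = sorted(set(group_assignment.values()))
    sample_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    missing = [s for s in group_assignment if s not in sample_index]
    # samples without expression (e.g. outside the RPPA subset) are skipped
    abs_z = np.abs(matrix.values)
    sets = {}
    for group in groups:
        rows = [sample_index[s] for s, g in group_assignment.items()
                if g == group and s in sample_index]
        if not rows:
            raise ValueError(f"group {group!r} has no samples in the matrix")
        with np.errstate(invalid="ignore"):
            hits = (abs_z[rows] >= z_threshold)
        hits = np.where(np.isnan(abs_z[rows]), False, hits)
        n_hit = hits.sum(axis=0)
        if min_fraction is None:
            keep = n_hit >= 1
        else:
            keep = (n_hit / len(rows)) >= min_fraction
        sets[group] = frozenset(
            fid for fid, k in zip(matrix.feature_ids, keep) if k
        )
    return GroupFeatureSets(sets=sets, z_threshold=z_threshold,
                            min_fraction=min_fraction)


def venn_partition(sets: GroupFeatureSets | dict) -> VennPartition:
    """Exact disjoint partition of the (up to) three input sets."""
    mapping = sets.sets if isinstance(sets, GroupFeatureSets) else dict(sets)
    names = tuple(sorted(mapping))
    regions = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = frozenset.intersection(
                *[frozenset(mapping[m]) for m in members]
            )
            outside = frozenset().union(
                *[frozenset(mapping[m]) for m in names if m not in members]
            ) if len(members) < len(names) else frozenset()
            regions[members] = inside - outside
    return VennPartition(regions=regions, group_names=names)


def candidate_region(partition: VennPartition) -> frozenset:
    """Features flagged in both progressing arms (pair-only + triple region).

    Equals AI_PD ∩ SERM_SERD_PD regardless of CR membership.
    """
    pair = tuple(sorted((GROUP_AI_PD, GROUP_SERM_SERD_PD)))
    triple = tuple(sorted(GROUPS))
    out = partition.regions.get(pair, frozenset())
    out |= partition.regions.get(triple, frozenset())
    return out
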