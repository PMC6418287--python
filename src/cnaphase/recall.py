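"""Pairwise shared-mutation counts and recall rates across tumor regions.

The recall rate of region A in region B is the fraction of A's somatic
mutations that are also detected in B: |A ∩ B| / |A|.  It is directional
(the denominator is the first region's burden), so the matrix is not
symmetric even though the shared counts are.  Averaging the off-diagonal
entries within a tumor versus across tumors summarises how much more
mutation sharing there is inside a clonally related tumor than between
independent ones.  A Jaccard variant (|A ∩ B| / |A ∪ B|) is available for
comparison with overlap-style reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RegionVariantSet:
    """The somatic mutation keys detected in one tumor region."""

    patient_id: str
    tumor_id: str
    region_id: str
    keys: frozenset[str] = field(default_factory=frozenset)


@dataclass
class RecallMatrix:
    regions: list[str]
    shared_counts: np.ndarray  # (n, n) ints, symmetric
    recall: np.ndarray  # (n, n) floats in [0, 1]; NaN where undefined

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.shared_counts, index=self.regions,
                            columns=self.regions)

    def recall_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.recall, index=self.regions, columns=self.regions)


def shared_count(a: RegionVariantSet, b: RegionVariantSet) -> int:
    """Number of mutation keys detected in both regions."""
    return len(a.keys & b.keys)


def recall_rate(a: RegionVariantSet, b: RegionVariantSet,
                metric: str = "recall") -> float:
    """Directional recall |A ∩ B| / |A| (or Jaccard |A ∩ B| / |A ∪ B|).

    Undefined (NaN) when the denominator set is empty; undefined values
    are excluded from averages rather than counted as zero.
    """
    inter = len(a.keys & b.keys)
    if metric == "recall":
        denom = len(a.keys)
    elif metric == "jaccard":
        denom = len(a.keys | b.keys)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return inter / denom if denom else math.nan


def recall_matrix(regions: list[RegionVariantSet],
                  metric: str = "recall") -> RecallMatrix:
    """All ordered pairwise recalls plus the symmetric shared-count matrix."""
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids")
    n = len(regions)
    counts = np.zeros((n, n), dtype=int)
    recalls = np.full((n, n), math.nan)
    for i, a in enumerate(regions):
        for j, b in enumerate(regions):
            counts[i, j] = shared_count(a, b)
            recalls[i, j] = recall_rate(a, b, metric=metric)
    return RecallMatrix(ids, counts, recalls)


def average_recalls(matrix: RecallMatrix,
                    tumor_of: dict[str, str]) -> tuple[float, float]:
    """Mean off-diagonal recall within tumors and across tumors.

    Returns ``(within_tumor_avg, cross_tumor_avg)``; either is NaN when no
    qualifying (defined) ordered pair exists.
    """
    missing = [r for r in matrix.regions if r not in tumor_of]
    if missing:
        raise ValueError(f"regions without a tumor assignment: {missing}")
    within, cross = [], []
    for i, a in enumerate(matrix.regions):
        for j, b in enumerate(matrix.regions):
            if i == j or math.isnan(matrix.recall[i, j]):
                continue
            (within if tumor_of[a] == tumor_of[b] else cross).append(
                matrix.recall[i, j])
    return (float(np.mean(within)) if within else math.nan,
            float(np.mean(cross)) if cross else math.nan)


def cross_pair_recall(matrix: RecallMatrix, tumor_of: dict[str, str],
                      tumor_a: str, tumor_b: str) -> tuple[float, int]:
    """Mean recall and total shared count over ordered region pairs that
    span the two given tumors (evidence for one tumor-pair origin call)."""
    vals, shared = [], 0
    for i, a in enumerate(matrix.regions):
        for j, b in enumerate(matrix.regions):
            if i == j:
                continue
            if {tumor_of[a], tumor_of[b]} == {tumor_a, tumor_b}:
                if not math.isnan(matrix.recall[i, j]):
                    vals.append(matrix.recall[i, j])
                if tumor_of[a] == tumor_a:  # count each unordered pair once
                    shared += int(matrix.shared_counts[i, j])
    return (float(np.mean(vals)) if vals else math.nan, shared)
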