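"""Cross-tissue peak-set comparison.

Two complementary summaries of how peak sets agree across tissues:
asymmetric overlap fractions (what share of set i's peaks touch set j),
and a symmetric Pearson correlation of binary membership over a union
atlas built by merging every set's peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalCollection, overlaps_any

__all__ = ["OverlapMatrix", "overlap_fraction", "overlap_matrix", "merge_union"]


@dataclass
class OverlapMatrix:
    labels: list[str]
    fraction: np.ndarray  # (i, j): share of set i's peaks overlapping set j
    correlation: np.ndarray  # symmetric membership correlation over the union atlas

    def fraction_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fraction, index=self.labels, columns=self.labels)

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.correlation, index=self.labels, columns=self.labels)


def overlap_fraction(
    a: IntervalCollection, b: IntervalCollection, min_overlap: int = 1
) -> float:
    """Fraction of a's peaks overlapping any peak of b (asymmetric)."""
    if len(a) == 0:
        raise ValueError(f"overlap fraction undefined: {a.label} is empty")
    hits = sum(1 for peak in a if overlaps_any(b, peak, min_overlap))
    return hits / len(a)


def merge_union(sets: Sequence[IntervalCollection]) -> list[GenomicInterval]:
    """Merge all sets' peaks into disjoint union regions (the atlas)."""
    everything = sorted(
        (iv for coll in sets for iv in coll),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    merged: list[GenomicInterval] = []
    for iv in everything:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def overlap_matrix(
    sets: Sequence[IntervalCollection], min_overlap: int = 1
) -> OverlapMatrix:
    """Pairwise overlap-fraction and membership-correlation matrices.

    The correlation entry (i, j) is the Pearson correlation between the
    binary vectors marking which union-atlas regions each set occupies.
    A zero-variance membership vector (a set occupying every atlas
    region, or none) makes Pearson undefined; by convention such pairs
    correlate 1 when the vectors are identical and 0 otherwise.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 peak sets")
    n = len(sets)
    fraction = np.ones((n, n))
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if i != j:
                fraction[i, j] = overlap_fraction(a, b, min_overlap)
    atlas = merge_union(sets)
    membership = np.zeros((n, len(atlas)))
    for i, coll in enumerate(sets):
        membership[i] = [
            1.0 if overlaps_any(coll, region, min_overlap) else 0.0
            for region in atlas
        ]
    with np.errstate(invalid="ignore"):
        correlation = np.corrcoef(membership)
    for i in range(n):
        for j in range(n):
            if np.isnan(correlation[i, j]):
                correlation[i, j] = float(
                    np.array_equal(membership[i], membership[j])
                )
    np.fill_diagonal(correlation, 1.0)
    return OverlapMatrix([s.label for s in sets], fraction, correlation)
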