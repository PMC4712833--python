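"""Chromatin-state classification of factor peaks.

Peaks are split into promoter-proximal (anchor within 1 kb of the nearest
TSS by default) and promoter-distal, then assigned a category from histone
mark overlap:

proximal
    active    — overlaps H3K4me3 and H3K27Ac
    bivalent  — overlaps H3K4me3 and H3K27me3
    other     — neither rule fires
distal (priority cascade)
    bivalent  — overlaps H3K27me3, H3K27Ac and H3K4me1
    active    — overlaps H3K27Ac and H3K4me1
    repressed — overlaps H3K27me3
    latent    — overlaps H3K4me1 only
    isolated  — overlaps none of the three
    other     — remaining combination (H3K27Ac without H3K4me1); folded
                into latent under ``strict_five``

A proximal peak can satisfy both the active and the bivalent rule; it is
labelled bivalent but tallied under both rules in the composition table,
so those two proximal fractions may sum past the proximal total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalCollection,
    TssIndex,
    TssRecord,
    overlaps_any,
)
from .nucleosome import CoverageTrack

__all__ = [
    "ChromatinCategory",
    "ClassifiedPeak",
    "ClassifiedPeakSet",
    "split_proximal_distal",
    "classify_proximal",
    "classify_distal",
    "classify_peaks",
    "class_composition",
    "peak_signal_matrix",
    "PROXIMAL_LABELS",
    "DISTAL_LABELS",
]

PROXIMAL_LABELS = ("active", "bivalent", "other")
DISTAL_LABELS = ("active", "bivalent", "isolated", "latent", "repressed", "other")


@dataclass(frozen=True)
class ChromatinCategory:
    locality: str  # proximal | distal
    label: str

    def __post_init__(self) -> None:
        if self.locality not in ("proximal", "distal"):
            raise ValueError(f"locality must be proximal/distal, got {self.locality}")
        valid = PROXIMAL_LABELS if self.locality == "proximal" else DISTAL_LABELS
        if self.label not in valid:
            raise ValueError(
                f"label {self.label!r} invalid for {self.locality} (one of {valid})"
            )

    def __str__(self) -> str:
        return f"{self.locality}-{self.label}"


@dataclass(frozen=True)
class ClassifiedPeak:
    peak: GenomicInterval
    category: ChromatinCategory
    gene_id: str
    tss_distance: int | None
    #: proximal peaks satisfying the active rule even when labelled bivalent
    also_active: bool = False


@dataclass
class ClassifiedPeakSet:
    peaks: list[ClassifiedPeak]
    provenance: dict[str, str]
    proximal_threshold: int = 1000

    def __len__(self) -> int:
        return len(self.peaks)

    def subset(self, locality: str) -> list[ClassifiedPeak]:
        return [p for p in self.peaks if p.category.locality == locality]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.peak.chrom for p in self.peaks],
                "start": [p.peak.start for p in self.peaks],
                "end": [p.peak.end for p in self.peaks],
                "locality": [p.category.locality for p in self.peaks],
                "category": [p.category.label for p in self.peaks],
                "gene_id": [p.gene_id for p in self.peaks],
                "tss_distance": [p.tss_distance for p in self.peaks],
            }
        )


def split_proximal_distal(
    peaks: IntervalCollection,
    tss: Sequence[TssRecord],
    threshold: int = 1000,
    anchor: str = "summit",
) -> tuple[list[tuple[GenomicInterval, str, int]], list[tuple[GenomicInterval, str, int]]]:
    """Partition peaks into proximal (|nearest-TSS distance| <= threshold)
    and distal; each entry carries (peak, nearest gene, signed distance)."""
    if not tss:
        raise ValueError("TSS table is empty")
    if len(peaks) == 0:
        warnings.warn("empty peak set: empty partition", stacklevel=2)
        return [], []
    index = TssIndex(tss)
    proximal, distal = [], []
    for peak in peaks:
        hit = index.nearest(peak.chrom, peak.anchor(anchor))
        if hit is None:
            distal.append((peak, "unassigned", None))
            continue
        rec, signed = hit
        (proximal if abs(signed) <= threshold else distal).append(
            (peak, rec.gene_id, signed)
        )
    return proximal, distal


def classify_proximal(
    peak: GenomicInterval,
    k4me3: IntervalCollection,
    k27ac: IntervalCollection,
    k27me3: IntervalCollection,
    min_overlap: int = 1,
) -> tuple[ChromatinCategory, bool]:
    """Proximal category; second value flags the active rule firing (kept
    so a bivalent-labelled peak still counts in the active tally)."""
    has_k4me3 = overlaps_any(k4me3, peak, min_overlap)
    active = has_k4me3 and overlaps_any(k27ac, peak, min_overlap)
    bivalent = has_k4me3 and overlaps_any(k27me3, peak, min_overlap)
    if bivalent:
        return ChromatinCategory("proximal", "bivalent"), active
    if active:
        return ChromatinCategory("proximal", "active"), True
    return ChromatinCategory("proximal", "other"), False


def classify_distal(
    peak: GenomicInterval,
    k4me1: IntervalCollection,
    k27ac: IntervalCollection,
    k27me3: IntervalCollection,
    min_overlap: int = 1,
    strict_five: bool = False,
) -> ChromatinCategory:
    """Distal category via the priority cascade (see module docstring)."""
    has_k4me1 = overlaps_any(k4me1, peak, min_overlap)
    has_k27ac = overlaps_any(k27ac, peak, min_overlap)
    has_k27me3 = overlaps_any(k27me3, peak, min_overlap)
    if has_k27me3 and has_k27ac and has_k4me1:
        label = "bivalent"
    elif has_k27ac and has_k4me1:
        label = "active"
    elif has_k27me3:
        label = "repressed"
    elif has_k4me1:
        label = "latent"
    elif not has_k27ac:
        label = "isolated"
    else:  # H3K27Ac without H3K4me1 fits no quoted rule
        label = "latent" if strict_five else "other"
    return ChromatinCategory("distal", label)


def classify_peaks(
    peaks: IntervalCollection,
    tss: Sequence[TssRecord],
    k4me3: IntervalCollection,
    k4me1: IntervalCollection,
    k27ac: IntervalCollection,
    k27me3: IntervalCollection,
    proximal_threshold: int = 1000,
    min_overlap: int = 1,
    anchor: str = "summit",
    strict_five: bool = False,
) -> ClassifiedPeakSet:
    """Full classification of a factor peak set against four marks."""
    proximal, distal = split_proximal_distal(
        peaks, tss, threshold=proximal_threshold, anchor=anchor
    )
    classified: list[ClassifiedPeak] = []
    for peak, gene, dist in proximal:
        category, also_active = classify_proximal(
            peak, k4me3, k27ac, k27me3, min_overlap
        )
        classified.append(ClassifiedPeak(peak, category, gene, dist, also_active))
    for peak, gene, dist in distal:
        category = classify_distal(
            peak, k4me1, k27ac, k27me3, min_overlap, strict_five=strict_five
        )
        classified.append(ClassifiedPeak(peak, category, gene, dist))
    provenance = {
        "peaks": peaks.label,
        "k4me3": k4me3.label,
        "k4me1": k4me1.label,
        "k27ac": k27ac.label,
        "k27me3": k27me3.label,
    }
    return ClassifiedPeakSet(classified, provenance, proximal_threshold)


def class_composition(classified: ClassifiedPeakSet) -> pd.DataFrame:
    """Per-category counts and fractions (of all peaks and of the locality).

    The proximal table also reports an ``active-rule`` row counting every
    proximal peak whose active rule fired, including bivalent-labelled
    ones, mirroring the non-additive active/bivalent percentages.
    """
    if len(classified) == 0:
        return pd.DataFrame(
            columns=["locality", "category", "count", "frac_total", "frac_locality"]
        )
    total = len(classified)
    rows = []
    for locality, labels in (("proximal", PROXIMAL_LABELS), ("distal", DISTAL_LABELS)):
        subset = classified.subset(locality)
        n_loc = len(subset)
        for label in labels:
            n = sum(1 for p in subset if p.category.label == label)
            if n == 0 and label == "other":
                continue
            rows.append(
                {
                    "locality": locality,
                    "category": label,
                    "count": n,
                    "frac_total": n / total,
                    "frac_locality": n / n_loc if n_loc else float("nan"),
                }
            )
        if locality == "proximal" and n_loc:
            n_active_rule = sum(1 for p in subset if p.also_active or p.category.label == "active")
            rows.append(
                {
                    "locality": "proximal",
                    "category": "active-rule",
                    "count": n_active_rule,
                    "frac_total": n_active_rule / total,
                    "frac_locality": n_active_rule / n_loc,
                }
            )
    return pd.DataFrame(rows)


def peak_signal_matrix(
    peaks: Sequence[GenomicInterval],
    track: CoverageTrack,
    flank: int = 10_000,
    bins: int = 100,
) -> np.ndarray:
    """Peak-centred signal matrix: row i is the per-bin mean coverage over
    [center - flank, center + flank) of peak i. Bins falling off the
    chromosome are NaN; an absent chromosome yields an all-NaN row."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    out = np.full((len(peaks), bins), np.nan)
    edges = np.linspace(-flank, flank, bins + 1)
    for i, peak in enumerate(peaks):
        if peak.chrom not in track.chroms():
            warnings.warn(
                f"chromosome {peak.chrom} absent from track {track.label}",
                stacklevel=2,
            )
            continue
        center = peak.anchor("midpoint")
        for b in range(bins):
            lo = center + int(round(edges[b]))
            hi = center + int(round(edges[b + 1]))
            out[i, b] = track.mean(peak.chrom, lo, hi)  # NaN when truncated
    return out
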