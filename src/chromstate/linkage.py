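"""Peak-to-gene linkage and intersection with differential expression.

Proximal peaks link to their nearest-TSS gene; distal peaks link to
every gene whose TSS lies within a window (default 100 kb, inclusive)
of the peak anchor — many-to-many, since one enhancer can serve several
genes. Linked gene lists are then intersected with up/down differential
calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classify import ClassifiedPeak, ClassifiedPeakSet
from .expression import DifferentialResult
from .intervals import TssIndex, TssRecord

__all__ = [
    "PeakGeneLink",
    "LinkedDEResult",
    "link_proximal",
    "link_distal",
    "intersect_links_with_de",
]


@dataclass(frozen=True)
class PeakGeneLink:
    peak: ClassifiedPeak
    gene_id: str
    link_type: str  # proximal_tss | distal_window
    distance: int  # signed strand-oriented distance, bases


@dataclass(frozen=True)
class LinkedDEResult:
    up_genes: list[str]
    down_genes: list[str]
    n_up: int
    n_down: int
    conflicting_genes: list[str]


def link_proximal(classified: ClassifiedPeakSet) -> list[PeakGeneLink]:
    """One link per proximal peak to its (already assigned) nearest gene."""
    return [
        PeakGeneLink(p, p.gene_id, "proximal_tss", p.tss_distance)
        for p in classified.subset("proximal")
        if p.gene_id != "unassigned"
    ]


def link_distal(
    classified: ClassifiedPeakSet,
    tss: Sequence[TssRecord],
    window: int = 100_000,
    anchor: str = "summit",
) -> list[PeakGeneLink]:
    """Links from each distal peak to every TSS within ``window`` bases of
    its anchor (inclusive boundary)."""
    if window < 0:
        raise ValueError("window must be >= 0")
    index = TssIndex(tss)
    links = []
    for p in classified.subset("distal"):
        pos = p.peak.anchor(anchor)
        for rec, signed in index.within(p.peak.chrom, pos, window):
            links.append(PeakGeneLink(p, rec.gene_id, "distal_window", signed))
    return links


def unique_genes(links: Sequence[PeakGeneLink]) -> list[str]:
    return sorted({lk.gene_id for lk in links})


def intersect_links_with_de(
    links: Sequence[PeakGeneLink],
    de: Sequence[DifferentialResult],
) -> LinkedDEResult:
    """Intersect linked genes with differential calls.

    Genes whose probes disagree in direction (both up and down calls) are
    flagged and excluded from both lists. A complete vocabulary mismatch
    between linked genes and DE genes raises, as it usually signals an
    id-space mix-up rather than a biological result.
    """
    linked = set(unique_genes(links))
    de_genes = {r.gene_id for r in de}
    if linked and de_genes and not (linked & de_genes):
        raise ValueError(
            "no overlap between linked gene ids and DE gene ids "
            "(gene id spaces probably differ)"
        )
    up = {r.gene_id for r in de if r.direction == "up"}
    down = {r.gene_id for r in de if r.direction == "down"}
    conflicting = sorted(linked & up & down)
    up_genes = sorted((linked & up) - set(conflicting))
    down_genes = sorted((linked & down) - set(conflicting))
    return LinkedDEResult(
        up_genes, down_genes, len(up_genes), len(down_genes), conflicting
    )
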