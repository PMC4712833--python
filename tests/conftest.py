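import numpy as np
import pytest

from chromstate.intervals import GenomicInterval, IntervalCollection, TssRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_collection(rng, n, chroms=("chr1", "chr2"), span=100_000, label="set"):
    """Random sorted interval collection for oracle comparisons."""
    intervals = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 500))
        intervals.append(GenomicInterval(chrom, start, start + length))
    return IntervalCollection(label, intervals)


def random_tss(rng, n, chroms=("chr1", "chr2"), span=100_000):
    return [
        TssRecord(
            f"g{i:04d}",
            chroms[rng.integers(0, len(chroms))],
            int(rng.integers(0, span)),
            "+" if rng.random() < 0.5 else "-",
        )
        for i in range(n)
    ]


def brute_force_overlaps(collection, probe, min_overlap=1):
    """Quadratic oracle for query_overlaps."""
    hits = [
        iv
        for iv in collection
        if iv.chrom == probe.chrom
        and min(iv.end, probe.end) - max(iv.start, probe.start) >= min_overlap
    ]
    return sorted(hits, key=lambda iv: (iv.start, iv.end))


def brute_force_nearest(tss_records, chrom, pos):
    """Exhaustive oracle for the nearest-TSS query."""
    candidates = [r for r in tss_records if r.chrom == chrom]
    if not candidates:
        return None
    best = min(candidates, key=lambda r: (abs(pos - r.tss), r.gene_id))
    signed = pos - best.tss
    if best.strand == "-":
        signed = -signed
    return best.gene_id, signed
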