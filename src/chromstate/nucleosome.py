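"""+1/-1 nucleosome calling around TSSs from a coverage track.

The caller smooths the coverage in a window around each TSS with a
moving average, takes the highest local maximum strictly downstream of
the TSS (strand-oriented) as the +1 nucleosome and strictly upstream as
the -1 nucleosome, and reports their separation. Two conditions are
compared gene-by-gene with a paired Wilcoxon signed-rank test on the
per-gene spacings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .intervals import BedParseError, TssRecord
from .stats import wilcoxon_signed_rank

__all__ = [
    "CoverageTrack",
    "NucleosomeCall",
    "NoCall",
    "SpacingComparison",
    "read_bedgraph",
    "write_bedgraph",
    "call_flanking_nucleosomes",
    "call_many",
    "compare_spacing",
]


class CoverageTrack:
    """Non-negative signal per fixed-width bin, per chromosome.

    ``data`` maps chromosome name to a float array of per-bin values;
    base position p falls in bin p // bin_width. Chromosome length is
    taken as n_bins * bin_width.
    """

    def __init__(self, data: dict[str, np.ndarray], bin_width: int = 10,
                 label: str = "coverage"):
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.bin_width = int(bin_width)
        self.label = label
        self.data = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{label}/{chrom}: negative coverage")
            self.data[chrom] = arr

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_width

    def slice_bins(self, chrom: str, lo: int, hi: int) -> np.ndarray | None:
        """Bin values covering base range [lo, hi); None if the range runs
        off the chromosome."""
        if chrom not in self.data:
            return None
        bw = self.bin_width
        b0, b1 = lo // bw, -(-hi // bw)
        arr = self.data[chrom]
        if lo < 0 or b1 > len(arr):
            return None
        return arr[b0:b1]

    def mean(self, chrom: str, lo: int, hi: int) -> float:
        """Per-base mean signal over [lo, hi); NaN when the range is not
        fully inside the chromosome."""
        if hi <= lo:
            raise ValueError("empty range")
        if chrom not in self.data:
            return float("nan")
        arr = self.data[chrom]
        bw = self.bin_width
        if lo < 0 or hi > len(arr) * bw:
            return float("nan")
        b0, b1 = lo // bw, (hi - 1) // bw
        if b0 == b1:
            return float(arr[b0])
        total = 0.0
        total += arr[b0] * ((b0 + 1) * bw - lo)
        total += arr[b1] * (hi - b1 * bw)
        if b1 > b0 + 1:
            total += float(arr[b0 + 1 : b1].sum()) * bw
        return total / (hi - lo)


def read_bedgraph(path: str | Path, bin_width: int = 10,
                  label: str | None = None) -> CoverageTrack:
    """Rasterize a 4-column bedGraph to fixed-width bins.

    Each bin holds the length-weighted mean of the records covering it,
    with uncovered bases contributing 0. Records may arrive unsorted;
    overlapping records are rejected as ambiguous, negative values as
    invalid.
    """
    path = Path(path)
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: bad coordinates/value") from exc
            if value < 0:
                raise BedParseError(f"line {lineno}: negative coverage value")
            if start < 0 or start >= end:
                raise BedParseError(f"line {lineno}: invalid interval")
            records.append((fields[0], start, end, value))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    lengths: dict[str, int] = {}
    prev_chrom, prev_end = None, 0
    for chrom, start, end, _ in records:
        if chrom == prev_chrom and start < prev_end:
            raise BedParseError(
                f"overlapping bedGraph records on {chrom} at {start}: ambiguous signal"
            )
        prev_chrom, prev_end = chrom, end
        lengths[chrom] = max(lengths.get(chrom, 0), end)
    data = {
        chrom: np.zeros(-(-length // bin_width)) for chrom, length in lengths.items()
    }
    for chrom, start, end, value in records:
        arr = data[chrom]
        b0, b1 = start // bin_width, (end - 1) // bin_width
        for b in range(b0, b1 + 1):
            lo = max(start, b * bin_width)
            hi = min(end, (b + 1) * bin_width)
            arr[b] += value * (hi - lo) / bin_width
    return CoverageTrack(data, bin_width, label or path.stem)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write one bedGraph record per non-zero bin (run-length merged)."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.chroms():
            arr = track.data[chrom]
            i = 0
            while i < len(arr):
                if arr[i] == 0:
                    i += 1
                    continue
                j = i
                while j + 1 < len(arr) and arr[j + 1] == arr[i]:
                    j += 1
                fh.write(f"{chrom}\t{i * bw}\t{(j + 1) * bw}\t{arr[i]:.6g}\n")
                i = j + 1


@dataclass(frozen=True)
class NucleosomeCall:
    gene_id: str
    minus1: int  # genome base position of the -1 nucleosome dyad estimate
    plus1: int  # genome base position of the +1 nucleosome dyad estimate
    distance: int  # plus1 - minus1 on the strand-oriented axis, > 0
    prominence_minus1: float
    prominence_plus1: float


@dataclass(frozen=True)
class NoCall:
    gene_id: str
    reason: str


@dataclass(frozen=True)
class SpacingComparison:
    median_a: float
    median_b: float
    n_pairs: int
    statistic: float
    pvalue: float


def call_flanking_nucleosomes(
    track: CoverageTrack,
    tss: TssRecord,
    search: int = 1000,
    smooth_bandwidth: int = 50,
    min_prominence: float = 0.1,
) -> NucleosomeCall | NoCall:
    """Call the +1 and -1 nucleosomes around one TSS.

    Coverage in [tss - search, tss + search) is smoothed by a moving
    average of width ``smooth_bandwidth`` bases. Local maxima with
    prominence >= min_prominence * (window max) are candidates; the
    highest candidate strictly downstream of the TSS on the gene's strand
    is +1, strictly upstream is -1. Either side lacking a candidate gives
    a no-call.
    """
    bw = track.bin_width
    lo, hi = tss.tss - search, tss.tss + search
    window = track.slice_bins(tss.chrom, lo, hi)
    if window is None:
        return NoCall(tss.gene_id, "window outside chromosome")
    k = max(1, int(round(smooth_bandwidth / bw)))
    if k % 2 == 0:
        k += 1
    smoothed = np.convolve(window, np.ones(k) / k, mode="same")
    peak_max = smoothed.max()
    if peak_max <= 0:
        return NoCall(tss.gene_id, "flat window")
    idx, props = find_peaks(smoothed, prominence=min_prominence * peak_max)
    if idx.size == 0:
        return NoCall(tss.gene_id, "no local maxima above prominence threshold")
    # genome base coordinate of each candidate (bin centre)
    win_start = (lo // bw) * bw
    coords = win_start + idx * bw + bw // 2
    offsets = coords - tss.tss
    if tss.strand == "-":
        offsets = -offsets
    up = idx[offsets < 0]
    down = idx[offsets > 0]
    if up.size == 0 or down.size == 0:
        side = "upstream" if up.size == 0 else "downstream"
        return NoCall(tss.gene_id, f"no {side} local maximum")
    prominences = dict(zip(idx.tolist(), props["prominences"].tolist()))
    i_minus = int(up[np.argmax(smoothed[up])])
    i_plus = int(down[np.argmax(smoothed[down])])
    pos_minus = int(win_start + i_minus * bw + bw // 2)
    pos_plus = int(win_start + i_plus * bw + bw // 2)
    distance = abs(pos_plus - pos_minus)
    return NucleosomeCall(
        tss.gene_id, pos_minus, pos_plus, distance,
        prominences[i_minus], prominences[i_plus],
    )


def call_many(
    track: CoverageTrack,
    tss_records: Sequence[TssRecord],
    search: int = 1000,
    smooth_bandwidth: int = 50,
    min_prominence: float = 0.1,
) -> tuple[list[NucleosomeCall], list[NoCall]]:
    """Apply :func:`call_flanking_nucleosomes` across a TSS table."""
    calls, nocalls = [], []
    for rec in tss_records:
        result = call_flanking_nucleosomes(
            track, rec, search, smooth_bandwidth, min_prominence
        )
        (calls if isinstance(result, NucleosomeCall) else nocalls).append(result)
    return calls, nocalls


def compare_spacing(
    calls_a: Iterable[NucleosomeCall],
    calls_b: Iterable[NucleosomeCall],
    mode: str = "auto",
) -> SpacingComparison:
    """Paired comparison of +1/-1 spacing between two conditions.

    Restricted to genes called in both conditions; medians are reported
    over that intersection and the Wilcoxon signed-rank test runs on the
    paired per-gene differences (zeros dropped; p = 1 when every pair is
    tied).
    """
    a = {c.gene_id: c.distance for c in calls_a}
    b = {c.gene_id: c.distance for c in calls_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 6:
        raise ValueError(
            f"only {len(shared)} genes called in both conditions; >= 6 required"
        )
    da = np.array([a[g] for g in shared], dtype=float)
    db = np.array([b[g] for g in shared], dtype=float)
    diffs = da - db
    if np.all(diffs == 0):
        return SpacingComparison(
            float(np.median(da)), float(np.median(db)), len(shared), 0.0, 1.0
        )
    res = wilcoxon_signed_rank(diffs, mode=mode)
    return SpacingComparison(
        float(np.median(da)), float(np.median(db)), len(shared),
        res.statistic, res.pvalue,
    )
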