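"""Genomic interval data model, BED/narrowPeak/TSS I/O and overlap queries.

All coordinates are 0-based half-open (BED convention). GTF-lite input,
which is 1-based inclusive, is converted at parse time so a single
convention holds everywhere downstream.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalCollection",
    "TssRecord",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_tss",
    "query_overlaps",
    "distance_to_nearest_tss",
    "UNASSIGNED",
]

#: Sentinel returned by :func:`distance_to_nearest_tss` when the probe's
#: chromosome carries no annotated TSS.
UNASSIGNED = ("unassigned", None)


class BedParseError(ValueError):
    """Raised for malformed BED/narrowPeak/TSS lines; names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome.

    ``summit_offset`` is the narrowPeak point-source offset from ``start``
    (column 10); ``anchor()`` prefers it over the midpoint.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)
    summit_offset: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside interval of "
                f"length {self.end - self.start}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None when no offset is recorded."""
        if self.summit_offset is None:
            return None
        return self.start + self.summit_offset

    def anchor(self, mode: str = "summit") -> int:
        """Representative point: the summit when present (mode='summit'),
        otherwise the midpoint."""
        if mode == "summit" and self.summit_offset is not None:
            return self.start + self.summit_offset
        if mode not in ("summit", "midpoint"):
            raise ValueError(f"unknown anchor mode {mode!r}")
        return self.midpoint

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class IntervalCollection:
    """A labelled, sorted set of intervals (one peak set / one mark)."""

    label: str
    intervals: list[GenomicInterval]
    genome: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        if self.genome is not None:
            for iv in self.intervals:
                limit = self.genome.get(iv.chrom)
                if limit is None:
                    raise ValueError(
                        f"{self.label}: chromosome {iv.chrom} absent from genome"
                    )
                if iv.end > limit:
                    raise ValueError(
                        f"{self.label}: interval {iv.chrom}:{iv.start}-{iv.end} "
                        f"extends past chromosome length {limit}"
                    )
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, iv
                )
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())


@dataclass(frozen=True)
class TssRecord:
    """Strand-oriented transcription start site of one gene/transcript."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: TSS must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


_DIALECT_MIN_FIELDS = {"bed3": 3, "bed6": 3, "narrowPeak": 10}


def _parse_bed_line(
    fields: list[str], dialect: str, lineno: int
) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
    if start >= end or start < 0:
        raise BedParseError(
            f"line {lineno}: invalid coordinates start={start} end={end}"
        )
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-numeric score") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    summit = None
    if dialect == "narrowPeak":
        try:
            offset = int(fields[9])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer summit offset") from exc
        if offset >= 0:  # -1 means "no summit" in the ENCODE convention
            if offset >= end - start:
                raise BedParseError(
                    f"line {lineno}: summit offset {offset} outside peak"
                )
            summit = offset
        score = float(fields[6])  # signalValue is the useful score column
    return GenomicInterval(
        fields[0], start, end, name=name, score=score, strand=strand,
        summit_offset=summit,
    )


def read_bed(
    path: str | Path,
    dialect: str = "bed6",
    label: str | None = None,
    genome: dict[str, int] | None = None,
) -> IntervalCollection:
    """Read a BED3/BED6/narrowPeak file into a sorted IntervalCollection.

    Comment (#), ``track`` and ``browser`` lines are skipped. Malformed
    coordinates raise :class:`BedParseError` naming the line.
    """
    if dialect not in _DIALECT_MIN_FIELDS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    min_fields = _DIALECT_MIN_FIELDS[dialect]
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) < min_fields:
                raise BedParseError(
                    f"line {lineno}: expected >= {min_fields} fields for "
                    f"{dialect}, got {len(fields)}"
                )
            intervals.append(_parse_bed_line(fields, dialect, lineno))
    return IntervalCollection(label or path.stem, intervals, genome=genome)


def write_bed(collection: IntervalCollection, path: str | Path) -> None:
    """Write a collection as BED6 (name/score default to '.'/0)."""
    with open(path, "w") as fh:
        for iv in collection:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{iv.name if iv.name is not None else '.'}\t"
                f"{iv.score if iv.score is not None else 0}\t{iv.strand}\n"
            )


def read_tss(path: str | Path, format: str = "tsv") -> list[TssRecord]:
    """Read a TSS table.

    ``tsv``: columns gene_id, chrom, tss (0-based), strand.
    ``gtf_lite``: 9-column GTF restricted to feature=transcript rows;
    1-based coordinates are converted, and for minus-strand transcripts the
    TSS is the last base of the feature.
    Duplicate (gene_id, tss) pairs collapse to one record.
    """
    if format not in ("tsv", "gtf_lite"):
        raise ValueError(f"unknown TSS format {format!r}")
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if format == "tsv":
                if len(fields) < 4:
                    raise BedParseError(
                        f"line {lineno}: TSS tsv needs gene_id, chrom, tss, strand"
                    )
                gene_id, chrom, tss_s, strand = fields[:4]
                if strand not in ("+", "-"):
                    raise BedParseError(f"line {lineno}: missing/invalid strand")
                records.append(TssRecord(gene_id, chrom, int(tss_s), strand))
            else:
                if len(fields) < 9:
                    raise BedParseError(f"line {lineno}: GTF needs 9 columns")
                if fields[2] != "transcript":
                    continue
                strand = fields[6]
                if strand not in ("+", "-"):
                    raise BedParseError(f"line {lineno}: missing/invalid strand")
                start1, end1 = int(fields[3]), int(fields[4])  # 1-based inclusive
                tss = start1 - 1 if strand == "+" else end1 - 1
                gene_id = _gtf_gene_id(fields[8], lineno)
                records.append(TssRecord(gene_id, fields[0], tss, strand))
    if not records:
        warnings.warn(f"no TSS records read from {path}", stacklevel=2)
    seen: set[tuple[str, int]] = set()
    unique = []
    for rec in records:
        key = (rec.gene_id, rec.tss)
        if key not in seen:
            seen.add(key)
            unique.append(rec)
    return unique


def _gtf_gene_id(attrs: str, lineno: int) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith("gene_id"):
            return part.split(None, 1)[1].strip().strip('"')
    raise BedParseError(f"line {lineno}: no gene_id attribute")


def query_overlaps(
    collection: IntervalCollection,
    probe: GenomicInterval,
    min_overlap: int = 1,
) -> list[GenomicInterval]:
    """Members of ``collection`` sharing >= min_overlap bases with ``probe``.

    Same-chromosome only; result ordered by start. Peak strand is ignored.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    hits = [
        node.data
        for node in collection._tree(probe.chrom).overlap(probe.start, probe.end)
        if node.data.overlap_length(probe) >= min_overlap
    ]
    hits.sort(key=lambda iv: (iv.start, iv.end))
    return hits


def overlaps_any(
    collection: IntervalCollection, probe: GenomicInterval, min_overlap: int = 1
) -> bool:
    """True if any member overlaps ``probe`` by >= min_overlap bases."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    for node in collection._tree(probe.chrom).overlap(probe.start, probe.end):
        if node.data.overlap_length(probe) >= min_overlap:
            return True
    return False


class TssIndex:
    """Sorted per-chromosome index for nearest-TSS queries."""

    def __init__(self, records: Sequence[TssRecord]):
        by_chrom: dict[str, list[TssRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._by_chrom = {
            chrom: sorted(recs, key=lambda r: (r.tss, r.gene_id))
            for chrom, recs in by_chrom.items()
        }
        self._positions = {
            chrom: [r.tss for r in recs] for chrom, recs in self._by_chrom.items()
        }

    def nearest(self, chrom: str, pos: int) -> tuple[TssRecord, int] | None:
        """Nearest TSS to ``pos``; ties by smaller |distance| then gene_id.

        Returns (record, signed strand-oriented distance) where positive
        means downstream of the TSS.
        """
        recs = self._by_chrom.get(chrom)
        if not recs:
            return None
        positions = self._positions[chrom]
        i = bisect_left(positions, pos)
        # candidates around the insertion point; equal-|distance| ties need
        # every record at the two candidate coordinates
        candidates: list[TssRecord] = []
        for j in (i - 1, i):
            if 0 <= j < len(recs):
                coord = positions[j]
                k = bisect_left(positions, coord)
                while k < len(recs) and positions[k] == coord:
                    candidates.append(recs[k])
                    k += 1
        best = min(candidates, key=lambda r: (abs(pos - r.tss), r.gene_id))
        signed = pos - best.tss
        if best.strand == "-":
            signed = -signed
        return best, signed

    def within(self, chrom: str, pos: int, window: int) -> list[tuple[TssRecord, int]]:
        """All TSSs with |pos - tss| <= window (inclusive), signed distances."""
        recs = self._by_chrom.get(chrom)
        if not recs:
            return []
        positions = self._positions[chrom]
        lo = bisect_left(positions, pos - window)
        out = []
        for j in range(lo, len(recs)):
            if positions[j] > pos + window:
                break
            rec = recs[j]
            signed = pos - rec.tss
            if rec.strand == "-":
                signed = -signed
            out.append((rec, signed))
        return out


def distance_to_nearest_tss(
    tss_records: Sequence[TssRecord] | TssIndex,
    probe: GenomicInterval,
    anchor: str = "summit",
) -> tuple[str, int | None]:
    """Nearest TSS to the probe's anchor point.

    Returns (gene_id, signed distance) with positive = downstream of the
    TSS on the gene's strand; :data:`UNASSIGNED` when the chromosome has no
    TSS. Ties break by smaller |distance| then lexicographic gene_id.
    """
    index = tss_records if isinstance(tss_records, TssIndex) else TssIndex(tss_records)
    hit = index.nearest(probe.chrom, probe.anchor(anchor))
    if hit is None:
        return UNASSIGNED
    rec, signed = hit
    return rec.gene_id, signed
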