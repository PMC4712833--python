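"""Ground-truth synthetic data for every pipeline stage.

Emulates the inputs of a factor ChIP-seq study on a small toy genome:
a TSS annotation, factor peaks with planted chromatin categories and the
histone-mark peak sets that force each category, coverage tracks with two
nucleosome-shaped bumps flanking each TSS at a planted spacing, and a
log2 expression matrix with planted differential effects on peak-linked
genes plus coherent cell-type signature blocks.

Every generator is a pure function of the config (seed included). The
single seed expands into independent per-stage streams through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` with stage 0 =
genome, 1 = peaks, 2 = coverage, 3 = expression, so one stage can be
regenerated without consuming another's randomness.

Peaks are laid out so each planted category is the classifier's unique
answer: proximal peaks sit on distinct TSSs (TSSs are >= 5 kb apart),
distal peaks sit in a dedicated zone >= 5 kb past the last TSS on slots
far enough apart that no mark planted for one peak can touch another.
The generator places marks by direct coordinate arithmetic and never
calls the overlap engine, so classifier agreement is evidence rather
than tautology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .intervals import GenomicInterval, IntervalCollection, TssRecord, write_bed
from .nucleosome import CoverageTrack, write_bedgraph

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_genome",
    "generate_peaks",
    "generate_coverage",
    "generate_expression",
    "write_bundle",
    "largest_remainder_counts",
]

#: categories in which marks are planted around each peak centre
_CATEGORY_MARKS = {
    ("proximal", "active"): ("k4me3", "k27ac"),
    ("proximal", "bivalent"): ("k4me3", "k27me3"),
    ("distal", "active"): ("k27ac", "k4me1"),
    ("distal", "bivalent"): ("k27me3", "k27ac", "k4me1"),
    ("distal", "repressed"): ("k27me3",),
    ("distal", "latent"): ("k4me1",),
    ("distal", "isolated"): (),
}


def _default_composition() -> dict[str, float]:
    # headline distal class mix with the small proximal remainder split
    return {
        "proximal-active": 0.01,
        "proximal-bivalent": 0.01,
        "distal-active": 0.13,
        "distal-bivalent": 0.01,
        "distal-isolated": 0.61,
        "distal-latent": 0.18,
        "distal-repressed": 0.05,
    }


def _default_spacing() -> dict[str, tuple[float, float]]:
    return {"wt": (589.0, 60.0), "mut": (482.0, 60.0)}


def _default_signatures() -> dict[str, float]:
    # photoreceptor programs drop while progenitor/proliferation programs rise
    return {"rod": -1.5, "cone": -1.0, "retinal_progenitor": 1.0, "g2m": 1.0}


@dataclass
class SyntheticConfig:
    """All knobs for the generator; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_lengths: list[int] | None = None
    n_genes: int = 200
    n_peaks: int = 400
    composition: dict[str, float] = field(default_factory=_default_composition)
    peak_width: int = 400
    mark_width: int = 800
    min_tss_spacing: int = 5000
    # nucleosome coverage model
    spacing_conditions: dict[str, tuple[float, float]] = field(
        default_factory=_default_spacing
    )
    spacing_min: float = 150.0
    bump_sd: float = 75.0
    bump_amplitude: float = 10.0
    coverage_noise: float = 1.0  # Poisson sampling depth; 0 disables noise
    bin_width: int = 10
    # expression model
    de_up_fraction: float = 0.25  # of eligible genes carrying a proximal peak
    de_down_fraction: float = 0.25
    de_effect_size: float = 1.5  # planted |log2 FC|
    de_noise_sd: float = 0.3
    # plant DE only on genes expressed above the filter floor, so the
    # planted truth survives the minimum-signal filter
    de_min_baseline: float = 6.5
    samples_per_group: int = 4
    baseline_mean: float = 7.0
    baseline_sd: float = 1.2
    signature_shifts: dict[str, float] = field(default_factory=_default_signatures)
    signature_size: int = 20

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, expected 1")
        if any(f < 0 or f > 1 for f in self.composition.values()):
            raise ValueError("composition fractions must lie in [0, 1]")
        if min(self.n_genes, self.n_peaks) < 1:
            raise ValueError("counts must be >= 1")
        if any(sd <= 0 for _, sd in self.spacing_conditions.values()):
            raise ValueError("spacing SDs must be > 0")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class GroundTruth:
    """Planted truth, keyed to emitted record names."""

    peak_category: dict[str, tuple[str, str]] = field(default_factory=dict)
    peak_gene: dict[str, str] = field(default_factory=dict)
    de_direction: dict[str, str] = field(default_factory=dict)
    spacing: dict[str, dict[str, float]] = field(default_factory=dict)
    signature_genes: dict[str, list[str]] = field(default_factory=dict)
    signature_shift: dict[str, float] = field(default_factory=dict)


def largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer counts summing to ``total`` via largest-remainder rounding;
    ties go to the lexicographically earlier key."""
    raw = {k: fractions[k] * total for k in fractions}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    leftover = total - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def generate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, int], list[TssRecord]]:
    """Toy genome and TSS table: TSSs >= min_tss_spacing apart with random
    strands, plus a distal zone per chromosome sized for the peak budget."""
    rng = config.rng(0)
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    n_distal_slots = -(-config.n_peaks // config.n_chromosomes)
    genome: dict[str, int] = {}
    records: list[TssRecord] = []
    gene_idx = 0
    for c, n in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        tss = 20_000 + int(rng.integers(0, 2001))
        last = tss
        for _ in range(n):
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(TssRecord(f"g{gene_idx:04d}", chrom, tss, strand))
            gene_idx += 1
            last = tss
            tss += config.min_tss_spacing + int(rng.integers(0, 2001))
        length = last + 10_000 + n_distal_slots * 3000 + 10_000
        if config.chrom_lengths is not None:
            stated = config.chrom_lengths[c]
            if stated < length:
                raise ValueError(
                    f"{chrom}: {n} genes at >= {config.min_tss_spacing} bp "
                    f"spacing plus the distal zone need {length} bp, "
                    f"got {stated}"
                )
            length = stated
        genome[chrom] = length
    return genome, records


def generate_peaks(
    config: SyntheticConfig,
    tss: Sequence[TssRecord],
    genome: dict[str, int],
    truth: GroundTruth | None = None,
) -> tuple[IntervalCollection, dict[str, IntervalCollection], GroundTruth]:
    """Factor peaks with planted categories plus the four mark peak sets."""
    rng = config.rng(1)
    truth = truth if truth is not None else GroundTruth()
    counts = largest_remainder_counts(config.composition, config.n_peaks)
    categories: list[tuple[str, str]] = []
    for key, n in sorted(counts.items()):
        locality, label = key.split("-")
        categories.extend([(locality, label)] * n)
    proximal = [c for c in categories if c[0] == "proximal"]
    distal = [c for c in categories if c[0] == "distal"]
    if len(proximal) > len(tss):
        raise ValueError(
            f"{len(proximal)} proximal peaks need as many distinct TSSs, "
            f"only {len(tss)} genes available"
        )
    half = config.peak_width // 2
    mark_half = config.mark_width // 2
    peaks: list[GenomicInterval] = []
    marks: dict[str, list[GenomicInterval]] = {
        "k4me3": [], "k4me1": [], "k27ac": [], "k27me3": []
    }

    def emit(name, chrom, center, locality, label, gene):
        peaks.append(
            GenomicInterval(
                chrom, center - half, center + half, name=name,
                summit_offset=half,
            )
        )
        for mark in _CATEGORY_MARKS[(locality, label)]:
            marks[mark].append(
                GenomicInterval(chrom, center - mark_half, center + mark_half,
                                name=f"{mark}_{name}")
            )
        truth.peak_category[name] = (locality, label)
        truth.peak_gene[name] = gene

    gene_order = rng.permutation(len(tss))
    proximal = [proximal[i] for i in rng.permutation(len(proximal))]
    for i, (locality, label) in enumerate(proximal):
        rec = tss[gene_order[i]]
        offset = int(rng.integers(-800, 801))
        emit(f"peak{i:05d}", rec.chrom, rec.tss + offset, locality, label,
             rec.gene_id)

    # distal zone: fixed slots past the last TSS of each chromosome
    zone_next: dict[str, int] = {}
    for chrom in genome:
        chrom_tss = [r.tss for r in tss if r.chrom == chrom]
        zone_next[chrom] = (max(chrom_tss) if chrom_tss else 10_000) + 10_000
    chroms = sorted(genome)
    distal = [distal[i] for i in rng.permutation(len(distal))]
    for i, (locality, label) in enumerate(distal):
        chrom = chroms[i % len(chroms)]
        center = zone_next[chrom] + 1500
        zone_next[chrom] += 3000
        emit(f"peak{len(proximal) + i:05d}", chrom, center, locality, label, "")

    factor = IntervalCollection("factor", peaks, genome=genome)
    mark_sets = {
        name: IntervalCollection(name, ivs, genome=genome)
        for name, ivs in marks.items()
    }
    return factor, mark_sets, truth


def generate_coverage(
    config: SyntheticConfig,
    tss: Sequence[TssRecord],
    genome: dict[str, int],
    truth: GroundTruth | None = None,
) -> tuple[dict[str, CoverageTrack], GroundTruth]:
    """Per-condition coverage with two Gaussian bumps flanking each TSS.

    Per gene and condition a spacing is drawn from Normal(median, SD)
    truncated above ``spacing_min``; bumps of SD ``bump_sd`` sit at
    TSS +/- spacing/2 (the strand only affects which bump is +1, not the
    genomic layout). Poisson sampling at depth ``coverage_noise`` adds
    count noise; depth 0 leaves the noiseless profile.
    """
    rng = config.rng(2)
    truth = truth if truth is not None else GroundTruth()
    bw = config.bin_width
    tracks: dict[str, CoverageTrack] = {}
    for cond in sorted(config.spacing_conditions):
        median, sd = config.spacing_conditions[cond]
        data = {
            chrom: np.zeros(-(-length // bw)) for chrom, length in genome.items()
        }
        spacings: dict[str, float] = {}
        for rec in tss:
            s = rng.normal(median, sd)
            while s <= config.spacing_min:
                s = rng.normal(median, sd)
            spacings[rec.gene_id] = float(s)
            arr = data[rec.chrom]
            for center in (rec.tss - s / 2.0, rec.tss + s / 2.0):
                c_bin = center / bw
                span = int(np.ceil(5 * config.bump_sd / bw))
                lo = max(0, int(c_bin) - span)
                hi = min(len(arr), int(c_bin) + span + 1)
                pos = (np.arange(lo, hi) + 0.5) * bw
                arr[lo:hi] += config.bump_amplitude * np.exp(
                    -0.5 * ((pos - center) / config.bump_sd) ** 2
                )
        if config.coverage_noise > 0:
            for chrom in data:
                lam = data[chrom] * config.coverage_noise
                data[chrom] = rng.poisson(lam).astype(float) / config.coverage_noise
        tracks[cond] = CoverageTrack(data, bw, label=cond)
        truth.spacing[cond] = spacings
    return tracks, truth


def generate_expression(
    config: SyntheticConfig,
    tss: Sequence[TssRecord],
    truth: GroundTruth,
) -> tuple[ExpressionMatrix, dict[str, list[str]], GroundTruth]:
    """log2 expression matrix (WT vs KO) with planted effects.

    Differential effects of +/- ``de_effect_size`` log2 units go to random
    subsets of the genes that carry a proximal factor peak and whose
    baseline lies above ``de_min_baseline`` (so planted truth is not lost
    to the minimum-signal filter downstream); signature
    blocks are disjoint non-differential gene sets shifted in the KO group
    by ``shift * de_noise_sd`` so the planted shift is expressed in
    per-gene SD units.
    """
    rng = config.rng(3)
    gene_ids = [r.gene_id for r in tss]
    n = config.samples_per_group
    samples = [f"WT_{i + 1}" for i in range(n)] + [f"KO_{i + 1}" for i in range(n)]
    groups = pd.Series(["WT"] * n + ["KO"] * n, index=samples)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, len(gene_ids))
    values = baseline[:, None] + rng.normal(
        0.0, config.de_noise_sd, (len(gene_ids), 2 * n)
    )

    index = {g: i for i, g in enumerate(gene_ids)}
    linked = sorted({g for g in truth.peak_gene.values() if g in index})
    eligible = [g for g in linked if baseline[index[g]] >= config.de_min_baseline]
    perm = rng.permutation(len(eligible))
    n_up = int(round(config.de_up_fraction * len(eligible)))
    n_down = int(round(config.de_down_fraction * len(eligible)))
    up_genes = [eligible[i] for i in perm[:n_up]]
    down_genes = [eligible[i] for i in perm[n_up:n_up + n_down]]
    ko = slice(n, 2 * n)
    for g in up_genes:
        values[index[g], ko] += config.de_effect_size
        truth.de_direction[g] = "up"
    for g in down_genes:
        values[index[g], ko] -= config.de_effect_size
        truth.de_direction[g] = "down"

    taken = set(up_genes) | set(down_genes)
    pool = [g for g in gene_ids if g not in taken]
    pool = [pool[i] for i in rng.permutation(len(pool))]
    signatures: dict[str, list[str]] = {}
    cursor = 0
    for name in sorted(config.signature_shifts):
        shift = config.signature_shifts[name]
        members = pool[cursor:cursor + config.signature_size]
        cursor += config.signature_size
        if not members:
            raise ValueError("not enough genes for the signature blocks")
        for g in members:
            values[index[g], ko] += shift * config.de_noise_sd
        signatures[name] = members
        truth.signature_genes[name] = members
        truth.signature_shift[name] = shift

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples), groups
    )
    return matrix, signatures, truth


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> GroundTruth:
    """Generate everything and write the file formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, tss = generate_genome(config)
    truth = GroundTruth()
    factor, marks, truth = generate_peaks(config, tss, genome, truth)
    tracks, truth = generate_coverage(config, tss, genome, truth)
    matrix, signatures, truth = generate_expression(config, tss, truth)

    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for chrom, length in sorted(genome.items()):
            fh.write(f"{chrom}\t{length}\n")
    with open(outdir / "tss.tsv", "w") as fh:
        for rec in tss:
            fh.write(f"{rec.gene_id}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")
    write_bed(factor, outdir / "factor_peaks.bed")
    for name, coll in marks.items():
        write_bed(coll, outdir / f"{name}.bed")
    for cond, track in tracks.items():
        write_bedgraph(track, outdir / f"{cond}.bedgraph")
    matrix.values.to_csv(outdir / "expression.tsv", sep="\t")
    matrix.groups.rename("group").to_csv(
        outdir / "groups.tsv", sep="\t", index_label="sample"
    )
    with open(outdir / "signatures.tsv", "w") as fh:
        for name, members in sorted(signatures.items()):
            for g in members:
                fh.write(f"{name}\t{g}\n")
    # ground truth sidecars
    with open(outdir / "truth_peaks.tsv", "w") as fh:
        fh.write("peak\tlocality\tcategory\tgene_id\n")
        for name in sorted(truth.peak_category):
            locality, label = truth.peak_category[name]
            fh.write(f"{name}\t{locality}\t{label}\t{truth.peak_gene[name]}\n")
    with open(outdir / "truth_de.tsv", "w") as fh:
        fh.write("gene_id\tdirection\n")
        for g in sorted(truth.de_direction):
            fh.write(f"{g}\t{truth.de_direction[g]}\n")
    with open(outdir / "truth_spacing.tsv", "w") as fh:
        fh.write("condition\tgene_id\tspacing\n")
        for cond in sorted(truth.spacing):
            for g in sorted(truth.spacing[cond]):
                fh.write(f"{cond}\t{g}\t{truth.spacing[cond][g]:.3f}\n")
    return truth
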