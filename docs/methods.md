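# Methods

This note records the models, conventions and design choices behind
`chromstate`, in the spirit of the methods documentation of mature
analysis packages: what is computed, under which assumptions, with
which defaults, and what the synthetic tests do and do not demonstrate.

## Coordinates and interval logic

All internal coordinates are 0-based half-open (BED convention).
GTF-lite input (1-based inclusive) is converted at parse time; for a
minus-strand transcript the TSS is the last base of the feature. A
peak's representative point ("anchor") is its narrowPeak summit when
present, otherwise its midpoint — the summit is the most specific
point available, and the choice is exposed as a parameter. Peak strand
is ignored in all overlap logic (histone marks and factor binding are
unstranded). Overlap queries run on per-chromosome interval trees
(`intervaltree`); a quadratic brute-force scan serves as the
independent oracle in the test suite, never as the implementation.

Nearest-TSS distance is signed on the gene's strand (positive =
downstream of the TSS); ties break by smaller |distance| and then by
lexicographic gene id, making every downstream result deterministic.

## Promoter-proximal definition

A peak is promoter-proximal when |signed distance from anchor to the
nearest TSS| ≤ 1000 bases (inclusive boundary; a peak exactly 1 kb
away is proximal, 1001 bases is distal). An alternative reading —
distance to the nearest gene *body* rather than to the TSS — is a
recognized ambiguity of the "within 1 kb of a gene or TSS" convention;
the TSS reading is implemented and the threshold is configurable.

## Chromatin-state categories

Proximal: **active** = overlaps H3K4me3 and H3K27Ac; **bivalent** =
overlaps H3K4me3 and H3K27me3. The two rules are not mutually
exclusive. A peak satisfying both carries the label `bivalent` but is
tallied under both rules in the composition table (`active-rule` row),
because the active/bivalent percentages of such classifications are
conventionally reported non-additively. Peaks matching neither rule
are `other`.

Distal, as a priority cascade: **bivalent** (K27me3 ∧ K27Ac ∧ K4me1) >
**active** (K27Ac ∧ K4me1) > **repressed** (K27me3) > **latent**
(K4me1 only) > **isolated** (none). Read literally, five such rules
are not a partition: a K27Ac-only peak fits none of them, and
K27me3 ∧ K4me1 fits two. The cascade resolves the double matches
(repressed wins over latent), and K27Ac-only peaks are reported as
`other` so that nothing is silently dropped; a `strict_five` mode
folds them into `latent`, which is the nearest single-mark reading,
so that exactly five distal classes sum to the distal total. Mark
overlap uses a 1-base minimum — the weakest consistent reading of
"overlapping" — and is configurable.

## Cross-tissue matrices

Overlap fraction (i, j) = share of set i's peaks with ≥ 1 base of
overlap against set j; it is asymmetric by definition and undefined
(an error, not 0) for an empty set. The correlation matrix is the
Pearson correlation of binary membership indicators over the union
atlas obtained by merging all sets' peaks; zero-variance membership
vectors (a set covering all or none of the atlas) get correlation 1
against an identical vector and 0 otherwise, by convention. Both
matrices are produced because overlap tables and correlation heat maps
answer subtly different questions and neither determines the other.

## Expression analysis

The expression filter keeps a gene when its mean log2 signal reaches
6.0 (RMA scale) in at least one sample group. The per-gene test is a
Welch two-sample t-test on log2 values — standard for small-n array
groups and free of package-specific variance moderation; with 2×4
samples its null positive rate at P < 0.05 is close to nominal (the
acceptance script measures it). Benjamini–Hochberg q-values are
computed over the tested gene set by the step-up rule
q(i) = min over j ≥ i of m·p(j)/j, capped at 1. A gene is "up" when
log2FC ≥ log2(2) and the significance rule holds; both a raw-p rule
(P < 0.05) and an FDR rule (q < 0.05) are offered because both
conventions are common and they select different gene sets; the
pipeline default is the raw-p rule.

Signature scores: per gene, z-score against the baseline group's mean
and SD (ddof = 1); per sample, the mean z over the signature's genes;
per group, the mean over samples. The baseline group scores 0 by
construction. This is the simplest score that yields
baseline-centered, SD-unit-comparable values; users wanting
rank-based or GSEA-style scoring can substitute at the library level.
Signature gene lists are plain two-column TSVs supplied by the user.

## Peak-to-gene linkage

Proximal peaks link to their nearest-TSS gene (the same assignment
used for the proximal/distal split). Distal peaks link to *every* TSS
within 100 kb of the anchor, boundary inclusive — many-to-many,
because one distal element can serve several genes and gene counts are
reported over the deduplicated union. A nearest-gene-only mode is easy
to emulate by filtering the link table on minimum |distance| per peak.
Links widen monotonically with the window, and peak-level proximal and
distal link sets are disjoint by construction.

## Nucleosome calling and spacing comparison

The caller takes coverage in [TSS − 1000, TSS + 1000) at 10-base bins,
smooths with a centered moving average of 50 bases, and finds local
maxima with prominence ≥ 0.1 × window maximum (`scipy.signal.find_peaks`).
The highest candidate strictly downstream of the TSS on the gene's
strand is +1, strictly upstream is −1; genes lacking a candidate on
either side are no-calls with a reason. Positions are bin centres, so
called distances are quantized to the bin width; recovery tests use a
two-bin tolerance. All knobs (search window, smoothing bandwidth,
prominence, bin width) are exposed; they are declared defaults, not
values inferred from any reference dataset.

Spacing comparison pairs genes called in both conditions (the gene is
the pairing unit), reports medians over that intersection, and applies
the paired Wilcoxon signed-rank test: zero differences dropped
(Pratt's alternative is available), tied |differences| mid-ranked,
W = min(W+, W−). The exact null distribution is computed by
convolution over doubled ranks (equivalent to enumerating the 2^n
sign assignments) for n ≤ 25; above that a normal approximation with
tie correction and 0.5 continuity correction is used. Two-sided
p = 2·min(P(W+ ≤ w), P(W+ ≥ w)), capped at 1. Fewer than 6 paired
genes is an error rather than a weak p-value. When replicate mutant
tracks exist, each is compared against the reference separately, one
test per pair, mirroring how replicate comparisons are normally
reported.

## Synthetic data: what it emulates and what it does not

The generator builds a toy genome whose TSSs are ≥ 5 kb apart, then
plants: (i) factor peaks with a specified category composition
(largest-remainder rounding converts fractions to counts), proximal
peaks on distinct TSSs within ±800 bases, distal peaks in a dedicated
zone ≥ 10 kb past the last TSS with 3-kb slot spacing so marks planted
for one peak can never touch another; (ii) mark peaks by direct
coordinate arithmetic around each factor peak so that each planted
category is the classifier's unique answer — the generator never calls
the overlap engine, keeping the two code paths independent;
(iii) coverage with two Gaussian bumps (SD 75 bases, amplitude 10) at
TSS ± spacing/2, spacing drawn per gene and condition from
Normal(median, SD) truncated above 150 bases, with the default
condition medians 589 (wild-type-like) and 482 (mutant-like) bases and
SD 60, plus Poisson count noise at configurable depth;
(iv) a log2 expression matrix with per-gene baselines Normal(7, 1.2)
(so most genes pass the ≥ 6 filter), residual noise SD 0.3, 4 samples
per group, differential effects of ±1.5 log2 units planted on a
fraction of the genes carrying a proximal factor peak, and signature
blocks of 20 genes shifted in SD units. Differential effects are
planted only on genes whose baseline exceeds 6.5, so the planted truth
is not silently removed by the expression filter — planting
undetectable truth would make exact-recovery checks meaningless.

A single integer seed expands into independent per-stage RNG streams
via `SeedSequence(seed, spawn_key=(stage,))`, so any stage can be
regenerated without consuming another's randomness, and emitted files
are byte-identical across runs for a given config.

Deliberately *not* emulated: read-level sampling and fragment-length
effects, overlapping genes and bidirectional promoters, mark peaks
unrelated to factor peaks, batch effects and probe-level structure in
expression data, and empirical (non-Gaussian) nucleosome spacing
distributions. Passing the synthetic recovery tests therefore
demonstrates the correctness of the pipeline's logic under its own
model assumptions, not the biological accuracy of any particular
threshold on real data.

## Problem sizes and numerical conventions

The test suite and acceptance script run at desk scale by design:
hundreds of genes and peaks per instance, 10–100 seeds per stochastic
claim (500 genes × 100 seeds for the spacing recovery, 20 seeds for
null calibration, 2,000 genes for the power check). These sizes were
chosen so every claim is measured on enough replicates to be stable
while the whole suite stays fast; all generators scale to larger
instances through the same config. Fractions are exact rationals of
counts wherever possible; compositions sum to 1 within 1e-12;
degenerate inputs (empty peak sets, all-zero differences, all-tied
pairs, absent chromosomes) return flagged/sentinel results rather than
silent zeros, as documented per function.

## Known limitations

- The distal category rules are a chosen disambiguation of an
  under-specified convention; other cascades are defensible and would
  shuffle a small number of multi-mark peaks between classes.
- Nearest-TSS assignment ignores gene length and expression; distal
  linkage is distance-only (no chromatin-contact information).
- The nucleosome caller estimates dyad positions from an acetylation
  signal at bin resolution; it is a flanking-maximum heuristic, not an
  occupancy deconvolution.
- The Welch test assumes approximate normality of log2 values within
  groups; with n = 4 per group this is adequate for calibration but
  moderated-variance methods will be more powerful on real arrays.
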