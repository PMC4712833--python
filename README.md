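# chromstate

Integrative annotation of transcription-factor ChIP-seq binding sites by
chromatin state, with expression integration and nucleosome-spacing
analysis. The package was built around the kind of study that profiles a
chromatin remodeler (e.g. Brg1/Smarca4, the SWI/SNF ATPase) together
with four histone marks (H3K4me3, H3K4me1, H3K27Ac, H3K27me3) in a
developing tissue, and asks: where does the factor bind relative to
promoters, in what chromatin context, which genes respond, and does the
remodeler move the +1/−1 nucleosomes?

It is a library plus a `chromstate` command-line tool, aimed at
computational biologists who already have peak calls (BED/narrowPeak),
coverage tracks (bedGraph) and normalized log2 expression matrices, and
want a reproducible, testable version of this analysis chain.

## What it computes

**Chromatin-state classification.** Factor peaks whose anchor (summit,
else midpoint) lies within 1 kb of the nearest annotated TSS are
*promoter-proximal*; the rest are *promoter-distal*. Proximal peaks are
**active** (overlap H3K4me3 ∧ H3K27Ac) or **bivalent** (H3K4me3 ∧
H3K27me3); these two rules can both fire, in which case the peak is
labelled bivalent but counted under both rules, so the two percentages
may sum past 100%. Distal peaks follow a priority cascade:
**bivalent** (K27me3 ∧ K27Ac ∧ K4me1) > **active** (K27Ac ∧ K4me1) >
**repressed** (K27me3) > **latent** (K4me1 only) > **isolated** (none
of the three). The one combination these rules leave out (K27Ac alone)
is reported separately as `other`, or folded into `latent` under
`--strict-five`.

**Cross-tissue comparison.** For peak sets from several tissues,
asymmetric overlap fractions (share of set *i*'s peaks touching set
*j*) and a symmetric Pearson correlation of binary membership over the
merged union atlas of all peaks.

**Expression integration.** Genes are kept when their mean log2 (RMA)
signal reaches 6 in at least one sample group; differential expression
is a per-gene Welch t-test with Benjamini–Hochberg adjustment, calling
a gene changed at fold-change > 2 and *P* < 0.05 (or FDR < 0.05 —
both modes are provided). Proximal peaks link to their nearest-TSS
gene; distal peaks link to every TSS within 100 kb (inclusive,
many-to-many). Intersecting links with differential calls yields the
up/down target-gene lists and counts. Cell-type signature scores are
means of baseline-referenced per-gene z-scores over curated gene sets.

**Nucleosome spacing.** From a coverage track (e.g. H3K27Ac), the
highest smoothed local maximum strictly downstream of each TSS is the
+1 nucleosome and strictly upstream the −1; per-gene +1/−1 distances
in two conditions are compared with a paired Wilcoxon signed-rank test
(exact null by enumeration for n ≤ 25, normal approximation with tie
and continuity corrections above).

**Synthetic ground truth.** `chromstate synth` writes a complete toy
input bundle — genome, TSS table, factor and mark peaks with planted
categories, coverage with planted +1/−1 spacing distributions, and an
expression matrix with planted fold changes and signature blocks — so
every stage of the pipeline can be verified against known truth.

## Worked example

```sh
chromstate synth --seed 5 --out demo
chromstate run --config demo.yaml     # paths for the demo bundle + outdir
```

The pipeline prints a JSON summary (also written to
`demo_out/summary.json`). With the default synthetic configuration
(400 peaks, 200 genes, 2% proximal peaks, the headline distal mix):

```json
"classification": {
  "composition": {
    "distal-active": 52, "distal-bivalent": 4, "distal-isolated": 244,
    "distal-latent": 72, "distal-repressed": 20,
    "proximal-active": 4, "proximal-active-rule": 4, "proximal-bivalent": 4
  },
  "n_distal": 392, "n_peaks": 400, "n_proximal": 8
},
"nucleosome": {
  "mut_vs_wt": {
    "median_mut": 490.0, "median_wt": 580.0,
    "n_pairs": 198, "pvalue": 9.77e-27, "statistic": 950.0
  }
}
```

Reading this: of 400 factor peaks, 8 were promoter-proximal and 392
distal; the distal classes recover the planted 13/1/61/18/5% mix
exactly (52/4/244/72/20 of 400). The +1/−1 spacing medians recover the
two planted regimes (planted medians 589 vs 482 bp; called 580 vs
490 bp at 10-bp bin resolution over 198 genes called in both
conditions), and the paired Wilcoxon rejects equality decisively.
Per-stage outputs (classified peaks BED, composition TSV, DE table,
link tables, gene lists, nucleosome calls) land in the output
directory.

Individual stages are available as subcommands: `chromstate classify`,
`crosstissue`, `de`, `nucspace`, `stats wilcoxon`, `intervals
validate`.

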