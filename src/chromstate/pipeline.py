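"""End-to-end orchestration: classify -> cross-tissue -> DE -> link -> spacing.

One config object (loadable from YAML) drives every stage and a
consolidated JSON summary is written alongside the per-stage TSV
outputs. Any stage failure aborts the run naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import crosstissue as _crosstissue
from . import linkage as _linkage
from .expression import (
    differential_expression,
    filter_expressed,
    read_expression,
    read_signatures,
    signature_score,
)
from .intervals import read_bed, read_tss, write_bed, GenomicInterval, IntervalCollection
from .nucleosome import call_many, compare_spacing, read_bedgraph

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    # inputs
    peaks: str
    tss: str
    k4me3: str | None = None
    k4me1: str | None = None
    k27ac: str | None = None
    k27me3: str | None = None
    expression: str | None = None
    groups: str | None = None
    group1: str = "WT"
    group2: str = "KO"
    signatures: str | None = None
    baseline_group: str | None = None  # defaults to group1
    coverage: dict[str, str] = field(default_factory=dict)  # condition -> bedGraph
    tissue_sets: dict[str, str] = field(default_factory=dict)  # label -> BED
    peak_dialect: str = "bed6"
    mark_dialect: str = "bed6"
    # thresholds
    proximal_bp: int = 1000
    distal_window: int = 100_000
    fc: float = 2.0
    p: float = 0.05
    fdr: float = 0.05
    significance: str = "p"
    min_rma: float = 6.0
    min_overlap: int = 1
    strict_five: bool = False
    wilcoxon_mode: str = "auto"
    search: int = 1000
    smooth: int = 50
    min_prominence: float = 0.1
    bin_width: int = 10
    # output
    outdir: str = "chromstate_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("peaks", "tss", "k4me3", "k4me1", "k27ac", "k27me3",
                     "expression", "groups", "signatures"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value}")
        for label, path in {**self.coverage, **self.tissue_sets}.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: no such file {path}")
        if not 0 < self.p <= 1 or not 0 < self.fdr <= 1:
            raise ValueError("p and fdr thresholds must lie in (0, 1]")
        if self.fc < 1:
            raise ValueError("fold-change threshold must be >= 1")


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the JSON-ready summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "proximal_bp": config.proximal_bp, "distal_window": config.distal_window,
        "fc": config.fc, "p": config.p, "fdr": config.fdr,
        "significance": config.significance, "min_rma": config.min_rma,
        "min_overlap": config.min_overlap, "strict_five": config.strict_five,
    }}

    classified = _stage_classify(config, outdir, summary)
    if config.tissue_sets:
        _stage_crosstissue(config, outdir, summary)
    de = None
    if config.expression:
        de = _stage_expression(config, outdir, summary)
    if de is not None:
        _stage_linkage(config, classified, de, outdir, summary)
    if len(config.coverage) >= 2:
        _stage_nucleosome(config, outdir, summary)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


@_stage("classify")
def _stage_classify(config, outdir, summary):
    peaks = read_bed(config.peaks, dialect=config.peak_dialect, label="factor")
    tss = read_tss(config.tss)
    marks = {}
    for mark in ("k4me3", "k4me1", "k27ac", "k27me3"):
        path = getattr(config, mark)
        if path is None:
            raise ValueError(f"classification requires a {mark} peak file")
        marks[mark] = read_bed(path, dialect=config.mark_dialect, label=mark)
    classified = _classify.classify_peaks(
        peaks, tss, marks["k4me3"], marks["k4me1"], marks["k27ac"],
        marks["k27me3"], proximal_threshold=config.proximal_bp,
        min_overlap=config.min_overlap, strict_five=config.strict_five,
    )
    out = IntervalCollection(
        "classified",
        [
            GenomicInterval(
                p.peak.chrom, p.peak.start, p.peak.end,
                name=f"{p.peak.name or 'peak'}|{p.category}",
                score=p.peak.score, strand=p.peak.strand,
            )
            for p in classified.peaks
        ],
    )
    write_bed(out, outdir / "classified_peaks.bed")
    composition = _classify.class_composition(classified)
    composition.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    summary["classification"] = {
        "n_peaks": len(classified),
        "n_proximal": len(classified.subset("proximal")),
        "n_distal": len(classified.subset("distal")),
        "composition": {
            f"{r.locality}-{r.category}": int(r.count)
            for r in composition.itertuples()
        },
    }
    logger.info("classified %d peaks", len(classified))
    return classified


@_stage("crosstissue")
def _stage_crosstissue(config, outdir, summary):
    sets = [read_bed(config.peaks, dialect=config.peak_dialect, label="factor")]
    for label, path in sorted(config.tissue_sets.items()):
        sets.append(read_bed(path, dialect=config.mark_dialect, label=label))
    matrix = _crosstissue.overlap_matrix(sets, min_overlap=config.min_overlap)
    matrix.fraction_frame().to_csv(outdir / "overlap_fraction.tsv", sep="\t")
    matrix.correlation_frame().to_csv(outdir / "overlap_correlation.tsv", sep="\t")
    summary["crosstissue"] = {"labels": matrix.labels}


@_stage("expression")
def _stage_expression(config, outdir, summary):
    if not config.groups:
        raise ValueError("expression analysis requires a groups file")
    matrix = read_expression(config.expression, config.groups)
    filtered = filter_expressed(matrix, min_mean_signal=config.min_rma)
    de = differential_expression(
        filtered, config.group1, config.group2, fc_threshold=config.fc,
        p_threshold=config.p, fdr_threshold=config.fdr,
        significance=config.significance,
    )
    frame = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in de],
            "log2_fold_change": [r.log2_fold_change for r in de],
            "pvalue": [r.pvalue for r in de],
            "fdr": [r.fdr for r in de],
            "direction": [r.direction for r in de],
        }
    )
    frame.to_csv(outdir / "differential_expression.tsv", sep="\t", index=False)
    summary["expression"] = {
        "n_genes_input": len(matrix.gene_ids),
        "n_genes_filtered": len(filtered.gene_ids),
        "n_up": sum(r.direction == "up" for r in de),
        "n_down": sum(r.direction == "down" for r in de),
    }
    if config.signatures:
        baseline = config.baseline_group or config.group1
        scores = {}
        for name, genes in read_signatures(config.signatures).items():
            score = signature_score(filtered, genes, baseline, name=name)
            scores[name] = {g: round(v, 4) for g, v in score.per_group.items()}
        summary["signature_scores"] = scores
    return de


@_stage("linkage")
def _stage_linkage(config, classified, de, outdir, summary):
    tss = read_tss(config.tss)
    proximal_links = _linkage.link_proximal(classified)
    distal_links = _linkage.link_distal(classified, tss, window=config.distal_window)
    rows = [
        {
            "peak": lk.peak.peak.name or "", "gene_id": lk.gene_id,
            "type": lk.link_type, "distance": lk.distance,
            "category": str(lk.peak.category),
        }
        for lk in proximal_links + distal_links
    ]
    pd.DataFrame(rows).to_csv(outdir / "links.tsv", sep="\t", index=False)
    summary["linkage"] = {}
    for kind, links in (("proximal", proximal_links), ("distal", distal_links)):
        result = _linkage.intersect_links_with_de(links, de)
        with open(outdir / f"{kind}_up_genes.tsv", "w") as fh:
            fh.write("\n".join(result.up_genes) + ("\n" if result.up_genes else ""))
        with open(outdir / f"{kind}_down_genes.tsv", "w") as fh:
            fh.write("\n".join(result.down_genes) + ("\n" if result.down_genes else ""))
        summary["linkage"][kind] = {
            "n_links": len(links),
            "n_up": result.n_up,
            "n_down": result.n_down,
            "conflicting": result.conflicting_genes,
        }


@_stage("nucleosome")
def _stage_nucleosome(config, outdir, summary):
    tss = read_tss(config.tss)
    calls = {}
    for cond, path in sorted(config.coverage.items()):
        track = read_bedgraph(path, bin_width=config.bin_width, label=cond)
        good, bad = call_many(
            track, tss, search=config.search, smooth_bandwidth=config.smooth,
            min_prominence=config.min_prominence,
        )
        calls[cond] = good
        pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in good],
                "minus1": [c.minus1 for c in good],
                "plus1": [c.plus1 for c in good],
                "distance": [c.distance for c in good],
            }
        ).to_csv(outdir / f"nucleosome_calls_{cond}.tsv", sep="\t", index=False)
    conditions = sorted(calls)
    reference = conditions[0]
    summary["nucleosome"] = {}
    for other in conditions[1:]:
        cmp = compare_spacing(calls[reference], calls[other],
                              mode=config.wilcoxon_mode)
        summary["nucleosome"][f"{reference}_vs_{other}"] = {
            "median_" + reference: cmp.median_a,
            "median_" + other: cmp.median_b,
            "n_pairs": cmp.n_pairs,
            "statistic": cmp.statistic,
            "pvalue": cmp.pvalue,
        }
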