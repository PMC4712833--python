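"""Expression-matrix filtering, differential expression and signature scores.

Operates on normalized log2 (RMA-style) matrices, genes x samples. The
expression filter keeps genes whose mean signal reaches a threshold in at
least one sample group; differential expression is a per-gene Welch
two-sample t-test with Benjamini-Hochberg adjustment and a fold-change
gate; signature scoring averages baseline-referenced z-scores over a
curated gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .stats import bh_fdr

__all__ = [
    "ExpressionMatrix",
    "DifferentialResult",
    "SignatureScore",
    "read_expression",
    "read_signatures",
    "filter_expressed",
    "differential_expression",
    "signature_score",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """log2-scale expression values with a sample -> group mapping."""

    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups[s] == group]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return cols


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    log2_fold_change: float  # group2 mean - group1 mean
    pvalue: float
    fdr: float
    direction: str  # up | down | unchanged


@dataclass(frozen=True)
class SignatureScore:
    name: str
    per_sample: pd.Series
    per_group: pd.Series
    baseline_group: str
    n_genes_used: int


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a sample -> group sidecar TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    groups = pd.Series(
        groups_df.iloc[:, 1].to_numpy(), index=groups_df.iloc[:, 0].astype(str)
    )
    return ExpressionMatrix(values, groups)


def read_signatures(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (signature, gene_id) -> name -> gene list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["signature", "gene_id"],
                     comment="#")
    return {
        name: sub["gene_id"].tolist() for name, sub in df.groupby("signature", sort=True)
    }


def filter_expressed(
    matrix: ExpressionMatrix,
    min_mean_signal: float = 6.0,
    groups: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Keep genes whose mean signal in at least one group meets the threshold."""
    group_names = list(groups) if groups is not None else sorted(set(matrix.groups))
    keep = np.zeros(len(matrix.values), dtype=bool)
    for g in group_names:
        cols = matrix.samples_in(g)
        keep |= (matrix.values[cols].mean(axis=1) >= min_mean_signal).to_numpy()
    return ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.groups)


def differential_expression(
    matrix: ExpressionMatrix,
    group1: str,
    group2: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    significance: str = "p",
) -> list[DifferentialResult]:
    """Per-gene Welch t-test of group2 vs group1 on log2 values.

    A gene is called up when log2FC >= log2(fc_threshold) and the chosen
    significance rule holds (``significance='p'`` uses the raw p-value
    threshold, ``'fdr'`` the BH-adjusted one); down is symmetric.
    """
    if significance not in ("p", "fdr"):
        raise ValueError("significance must be 'p' or 'fdr'")
    cols1 = matrix.samples_in(group1)
    cols2 = matrix.samples_in(group2)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    x1 = matrix.values[cols1].to_numpy()
    x2 = matrix.values[cols2].to_numpy()
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    tstat, pvals = ttest_ind(x2, x1, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance identical groups
    qvals = bh_fdr(pvals)
    lfc_cut = np.log2(fc_threshold)
    results = []
    for gene, lfc, p, q in zip(matrix.gene_ids, log2fc, pvals, qvals):
        significant = (p <= p_threshold) if significance == "p" else (q <= fdr_threshold)
        if significant and lfc >= lfc_cut:
            direction = "up"
        elif significant and lfc <= -lfc_cut:
            direction = "down"
        else:
            direction = "unchanged"
        results.append(DifferentialResult(gene, float(lfc), float(p), float(q), direction))
    return results


def signature_score(
    matrix: ExpressionMatrix,
    gene_set: Sequence[str],
    baseline_group: str,
    name: str = "signature",
) -> SignatureScore:
    """Mean baseline-referenced z-score of the set genes, per sample.

    Each gene is z-scored against the baseline group's mean and SD, so
    the baseline group's mean score is 0 by construction; per-group mean
    scores are reported alongside the per-sample scores.
    """
    present = [g for g in gene_set if g in matrix.values.index]
    absent = sorted(set(gene_set) - set(present))
    if absent:
        logger.info("signature %s: %d genes absent from matrix", name, len(absent))
    if not present:
        raise ValueError(f"signature {name!r}: no genes found in the matrix")
    base_cols = matrix.samples_in(baseline_group)
    sub = matrix.values.loc[present]
    mu = sub[base_cols].mean(axis=1)
    sd = sub[base_cols].std(axis=1, ddof=1).replace(0.0, np.nan)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    per_sample = z.mean(axis=0, skipna=True)
    per_group = per_sample.groupby(matrix.groups).mean()
    return SignatureScore(name, per_sample, per_group, baseline_group, len(present))
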