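"""Shared statistical kernels.

Paired Wilcoxon signed-rank (exact null by convolution of the signed
rank-sum distribution for small n, normal approximation with tie and
continuity corrections otherwise), Benjamini-Hochberg step-up FDR, and
the nuclear shape-factor rule (longest/shortest diameter, elongated at
ratio >= 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "shape_factor",
    "EXACT_N_MAX",
]

#: auto mode switches from the exact null to the normal approximation here
EXACT_N_MAX = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    pvalue: float
    n: int  # nonzero differences used
    mode: str  # exact | approx | degenerate


def wilcoxon_signed_rank(
    differences,
    mode: str = "auto",
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (``zero_method='wilcox'``) or kept in the
    ranking with their rank-halves split between W+ and W-
    (``zero_method='pratt'``). Tied absolute differences are mid-ranked.
    ``mode='exact'`` enumerates the null distribution of W+ (uniform over
    the 2^n sign assignments) by convolution; ``'approx'`` uses the normal
    approximation with tie correction and a 0.5 continuity correction;
    ``'auto'`` picks exact for n <= 25.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1-D array")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    if zero_method == "wilcox":
        d = d[d != 0.0]
    if d.size == 0 or np.all(d == 0.0):
        warnings.warn("all differences are zero: degenerate test", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")

    ranks = rankdata(np.abs(d))  # mid-ranks for ties (zeros rank lowest, pratt)
    if zero_method == "pratt":
        nonzero = d != 0.0
        ranks = ranks[nonzero]
        d = d[nonzero]
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if mode == "auto":
        mode = "exact" if n <= EXACT_N_MAX else "approx"

    if mode == "exact":
        p = _exact_two_sided(ranks, w_plus)
    else:
        p = _approx_two_sided(ranks, w)
    return WilcoxonResult(w, min(1.0, p), n, mode)


def _exact_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    # work on doubled ranks so mid-ranks (.5) become integers
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    # counts[k] = number of sign assignments with doubled W+ == k
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return 2.0 * min(p_le, p_ge)


def _approx_two_sided(ranks: np.ndarray, w: float) -> float:
    n = ranks.size
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    # W = min(W+, W-) <= mean, so the continuity correction moves toward it
    z = (w - mean + 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.cdf(z)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def shape_factor(d_max: float, d_min: float, threshold: float = 2.0) -> tuple[float, str]:
    """Nuclear shape factor d_max/d_min; 'elongated' when the nucleus is at
    least ``threshold`` times as long as it is wide, else 'round'."""
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    if d_max < d_min:
        raise ValueError("d_max must be >= d_min")
    factor = d_max / d_min
    return factor, ("elongated" if factor >= threshold else "round")
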