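"""Paired significance testing between segmentation methods.

Two methods are compared per metric with the two-sided Wilcoxon
signed-rank test on per-image values; the resulting p-values across the
metric family are corrected for multiple comparisons with the
Holm-Bonferroni step-down procedure at alpha = 0.05.

The signed-rank test discards zero differences, midranks ties, and uses
the exact permutation null (all 2^n sign assignments of the ranked
absolute differences) up to n = 12; beyond that a normal approximation
with tie and continuity corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 12
ALPHA = 0.05


@dataclass
class PairedComparison:
    metric: str
    n: int
    statistic: float     # W+ = sum of ranks of positive differences
    p_raw: float
    p_adjusted: float
    significant: bool


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided p-value of the Wilcoxon signed-rank test on paired samples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: comparison degenerate")
    if d.size < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {d.size}")
    ranks = rankdata(np.abs(d))          # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_MAX_N:
        return _exact_two_sided_p(ranks, w_plus)
    return _normal_approx_p(ranks, w_plus)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Enumerate all 2^n sign assignments of the rank vector."""
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    tol = 1e-9
    p_le = float(np.mean(sums <= w_plus + tol))
    p_ge = float(np.mean(sums >= w_plus - tol))
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_approx_p(ranks: np.ndarray, w_plus: float) -> float:
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    var -= ((counts ** 3 - counts).sum()) / 48.0
    if var <= 0:
        raise ValueError("zero variance in signed-rank null (all ranks tied)")
    diff = w_plus - mean
    # continuity correction toward the mean
    diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=ALPHA, method="holm")[1]


def compare_methods(values_a, values_b, metrics=None,
                    alpha: float = ALPHA) -> list[PairedComparison]:
    """Wilcoxon + Holm over a family of metrics.

    ``values_a`` / ``values_b`` map metric name -> per-image value array
    (same image order in both). Metrics whose comparison is degenerate
    (all differences zero) are reported with p = 1 and flagged by n = 0.
    """
    metrics = list(metrics or values_a.keys())
    rows = []
    for m in metrics:
        a = np.asarray(values_a[m], dtype=np.float64)
        b = np.asarray(values_b[m], dtype=np.float64)
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        d = a - b
        n_nonzero = int((d != 0).sum())
        try:
            p = wilcoxon_signed_rank(a, b)
        except ValueError:
            p = 1.0
            n_nonzero = 0
        w_plus = float(rankdata(np.abs(d[d != 0]))[d[d != 0] > 0].sum()) if n_nonzero else 0.0
        rows.append((m, n_nonzero, w_plus, p))
    adj = holm_bonferroni([r[3] for r in rows])
    return [PairedComparison(metric=m, n=n, statistic=w, p_raw=p,
                             p_adjusted=float(q), significant=bool(q < alpha))
            for (m, n, w, p), q in zip(rows, adj)]
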