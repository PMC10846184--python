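"""Shared statistical primitives (rank-sum test, FDR adjustment)."""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of the first sample.  The exact null distribution is
    used when both samples have at most 25 observations and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical -> no evidence either way
        return n * (n + m + 1) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < n + m
    method = "exact" if (n <= 25 and m <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + n * (n + 1) / 2.0  # U1 -> rank sum of x
    return w, float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
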