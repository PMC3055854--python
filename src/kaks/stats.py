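"""Shared statistical primitives: the two-sided rank-sum test."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_test"]


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most 20 and
    there are no ties across the pooled data; otherwise the normal
    approximation with tie correction.  Returns (U statistic, p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 20 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))
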