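"""Exact small-sample statistics shared across the pipeline.

The differential-editing caller pools replicate read counts per condition and
tests the resulting 2x2 table (alt/ref x condition) with a two-sided Fisher
exact test. The implementation here enumerates the hypergeometric support in
exact integer arithmetic, so tie comparisons at the observed table's
probability need no floating-point tolerance.
"""
from __future__ import annotations

from bisect import bisect_right
from functools import lru_cache
from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact_two_sided",
    "fisher_exact_many",
    "benjamini_hochberg",
]


@lru_cache(maxsize=100_000)
def _support_tables(n1: int, n2: int, m: int):
    """Sorted hypergeometric weights and prefix sums for margins (n1, n2, m).

    Weights are the unnormalised table probabilities C(n1, k) * C(n2, m - k)
    for k over the support; all arithmetic is exact (Python ints).
    Returns (kmin, weights, sorted_weights, prefix_sums, total).
    """
    kmin = max(0, m - n2)
    kmax = min(m, n1)
    w = comb(n1, kmin) * comb(n2, m - kmin)
    weights = [w]
    for k in range(kmin, kmax):
        # C(n1,k+1)/C(n1,k) = (n1-k)/(k+1); C(n2,m-k-1)/C(n2,m-k) = (m-k)/(n2-m+k+1)
        w = w * (n1 - k) * (m - k) // ((k + 1) * (n2 - m + k + 1))
        weights.append(w)
    sw = sorted(weights)
    prefix = [0]
    for v in sw:
        prefix.append(prefix[-1] + v)
    return kmin, weights, sw, prefix, prefix[-1]


def fisher_exact_two_sided(alt1: int, ref1: int, alt2: int, ref2: int) -> float:
    """Two-sided Fisher exact p-value for the table [[alt1, ref1], [alt2, ref2]].

    The p-value is the total probability, over all tables with the observed
    margins, of outcomes no more probable than the observed one (ties
    included, decided by exact integer comparison).
    """
    for v in (alt1, ref1, alt2, ref2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n1, n2, m = alt1 + ref1, alt2 + ref2, alt1 + alt2
    if n1 == 0 or n2 == 0:
        return 1.0
    kmin, weights, sw, prefix, total = _support_tables(n1, n2, m)
    w_obs = weights[alt1 - kmin]
    num = prefix[bisect_right(sw, w_obs)]
    return min(1.0, num / total)


def fisher_exact_many(alt1, ref1, alt2, ref2) -> np.ndarray:
    """Vectorised :func:`fisher_exact_two_sided` over equal-length arrays."""
    alt1 = np.asarray(alt1, dtype=np.int64)
    ref1 = np.asarray(ref1, dtype=np.int64)
    alt2 = np.asarray(alt2, dtype=np.int64)
    ref2 = np.asarray(ref2, dtype=np.int64)
    out = np.empty(alt1.shape[0], dtype=float)
    for i in range(alt1.shape[0]):
        out[i] = fisher_exact_two_sided(
            int(alt1[i]), int(ref1[i]), int(alt2[i]), int(ref2[i])
        )
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for a collection of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
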