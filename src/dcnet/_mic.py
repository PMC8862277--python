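"""Numba kernels for the simplified maximal-information-coefficient estimator.

The estimator searches r x c grids with r * c bounded by B(n) = n**alpha.
One axis is always split into c equal-frequency bins; the other axis is
optimised by dynamic programming over "clumps" (maximal runs of points that
share a fixed-axis bin when walked in free-axis order), the same restriction
the original ApproxMaxMI search uses.  Both orientations are tried and the
best normalised mutual information wins.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["best_mi_profile", "clump_cumulative"]


@njit(cache=True)
def _partition_scores(cum: np.ndarray, m: int, c: int, n: int, rmax: int) -> np.ndarray:
    """Best additive partition score for t = 1..rmax contiguous bins.

    ``cum`` is the (m+1, c) cumulative count of fixed-axis bin labels over
    the m clumps in free-axis order.  The additive score of a bin spanning
    clumps (i, j] is sum_q cnt_q/n * log(cnt_q/size); total mutual
    information is the partition score plus the fixed-axis entropy.
    """
    # score[i, j] for 0 <= i < j <= m
    score = np.full((m + 1, m + 1), -np.inf)
    for i in range(m):
        for j in range(i + 1, m + 1):
            size = 0.0
            for q in range(c):
                size += cum[j, q] - cum[i, q]
            s = 0.0
            for q in range(c):
                cnt = cum[j, q] - cum[i, q]
                if cnt > 0.0:
                    s += cnt / n * np.log(cnt / size)
            score[i, j] = s

    dp = np.full((m + 1, rmax + 1), -np.inf)
    dp[0, 0] = 0.0
    for t in range(1, rmax + 1):
        for j in range(t, m + 1):
            best = -np.inf
            for i in range(t - 1, j):
                if dp[i, t - 1] > -np.inf:
                    cand = dp[i, t - 1] + score[i, j]
                    if cand > best:
                        best = cand
            dp[j, t] = best

    out = np.full(rmax + 1, -np.inf)
    for t in range(1, min(m, rmax) + 1):
        out[t] = dp[m, t]
    return out


@njit(cache=True)
def clump_cumulative(labels: np.ndarray, c: int, max_clumps: int) -> np.ndarray:
    """Collapse a free-axis-ordered label sequence into clump count cumsums.

    Consecutive points with the same fixed-axis label form one clump; if the
    clump count exceeds ``max_clumps`` the clumps are merged into
    equal-frequency superclumps.  Returns the (m+1, c) cumulative matrix.
    """
    n = labels.shape[0]
    # clump boundaries
    starts = np.empty(n + 1, np.int64)
    m = 0
    starts[0] = 0
    for i in range(1, n):
        if labels[i] != labels[i - 1]:
            m += 1
            starts[m] = i
    m += 1
    starts[m] = n

    if m > max_clumps:
        # merge into max_clumps superclumps of roughly equal point counts
        merged = np.empty(max_clumps + 1, np.int64)
        merged[0] = 0
        j = 0
        for s in range(1, max_clumps):
            target = s * n / max_clumps
            while j < m and starts[j] < target:
                j += 1
            if j >= m:
                j = m - 1
            merged[s] = starts[j]
        merged[max_clumps] = n
        # drop duplicate boundaries
        mm = 0
        starts2 = np.empty(max_clumps + 1, np.int64)
        starts2[0] = 0
        for s in range(1, max_clumps + 1):
            if merged[s] > starts2[mm]:
                mm += 1
                starts2[mm] = merged[s]
        starts = starts2
        m = mm

    cum = np.zeros((m + 1, c), np.float64)
    for b in range(m):
        for q in range(c):
            cum[b + 1, q] = cum[b, q]
        for i in range(starts[b], starts[b + 1]):
            cum[b + 1, labels[i]] += 1.0
    return cum


@njit(cache=True)
def best_mi_profile(cum: np.ndarray, c: int, n: int, rmax: int) -> np.ndarray:
    """Maximum mutual information (nats) using at most t free-axis bins.

    Entry t of the returned array is the best MI achievable with <= t bins
    against the fixed c-bin equipartition encoded in ``cum``.
    """
    m = cum.shape[0] - 1
    part = _partition_scores(cum, m, c, n, rmax)
    h_fixed = 0.0
    for q in range(c):
        p = cum[m, q] / n
        if p > 0.0:
            h_fixed -= p * np.log(p)
    out = np.zeros(rmax + 1)
    best = -np.inf
    for t in range(1, rmax + 1):
        if part[t] > best:
            best = part[t]
        mi = best + h_fixed
        if mi < 0.0:
            mi = 0.0
        out[t] = mi
    return out
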