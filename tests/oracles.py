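"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive each quantity from its definition with naive
loops/enumeration, sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dcor_bruteforce(x, y) -> float:
    """Distance correlation via explicit O(n^2) double loops."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            a[k, l] = abs(x[k] - x[l])
            b[k, l] = abs(y[k] - y[l])

    def center(m):
        out = np.zeros((n, n))
        rbar = [m[k, :].sum() / n for k in range(n)]
        cbar = [m[:, l].sum() / n for l in range(n)]
        gbar = m.sum() / n**2
        for k in range(n):
            for l in range(n):
                out[k, l] = m[k, l] - rbar[k] - cbar[l] + gbar
        return out

    A, B = center(a), center(b)
    vxy = sum(A[k, l] * B[k, l] for k in range(n) for l in range(n)) / n**2
    vxx = sum(A[k, l] ** 2 for k in range(n) for l in range(n)) / n**2
    vyy = sum(B[k, l] ** 2 for k in range(n) for l in range(n)) / n**2
    if vxx * vyy <= 0:
        return 0.0
    return math.sqrt(max(vxy, 0.0) / math.sqrt(vxx * vyy))


def dcov_sq_bruteforce(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.abs(np.subtract.outer(x, x))
    b = np.abs(np.subtract.outer(y, y))
    A = a - a.mean(1)[:, None] - a.mean(0)[None, :] + a.mean()
    B = b - b.mean(1)[:, None] - b.mean(0)[None, :] + b.mean()
    return float(sum(A[k, l] * B[k, l] for k in range(n)
                     for l in range(n)) / n**2)


def mic_exhaustive(x, y, alpha: float = 0.6) -> float:
    """Exhaustive simplified-MIC: every clump-boundary cut combination.

    Mirrors the estimator's definition (fixed-axis equal-frequency bins,
    free-axis cuts restricted to clump boundaries, both orientations) but
    searches all cut subsets instead of dynamic programming.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    bound = max(n ** alpha, 4.0)
    best = 0.0
    for free, fixed in ((x, y), (y, x)):
        order = np.lexsort((fixed, free))
        for c in range(2, int(bound // 2) + 1):
            rmax = int(bound // c)
            if rmax < 2:
                break
            srt = np.argsort(fixed, kind="stable")
            rank = np.empty(n, dtype=int)
            rank[srt] = np.arange(n)
            labels = ((rank * c) // n)[order]
            bounds = [i for i in range(1, n) if labels[i] != labels[i - 1]]
            for r in range(2, rmax + 1):
                for cuts in itertools.combinations(bounds, r - 1):
                    edges = [0, *cuts, n]
                    mi = 0.0
                    for i in range(len(edges) - 1):
                        seg = labels[edges[i]:edges[i + 1]]
                        sz = len(seg)
                        for q in range(c):
                            cnt = int(np.sum(seg == q))
                            mq = int(np.sum(labels == q))
                            if cnt:
                                mi += cnt / n * math.log2(
                                    cnt * n / (sz * mq))
                    best = max(best, mi / math.log2(min(r, c)))
    return best


def tom_bruteforce(adj) -> np.ndarray:
    """Topological overlap by an explicit O(g^3) triple loop."""
    a = np.asarray(adj, dtype=float).copy()
    g = a.shape[0]
    for i in range(g):
        a[i, i] = 0.0
    w = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            if i == j:
                w[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(g))
            ki = sum(a[i, u] for u in range(g))
            kj = sum(a[j, u] for u in range(g))
            w[i, j] = (l + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return w


def lof_bruteforce(points, k: int) -> np.ndarray:
    """Classic local outlier factor with k-distance neighbourhoods."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    kdist = np.empty(n)
    neigh = []
    for i in range(n):
        others = np.delete(d[i], i)
        kdist[i] = np.sort(others)[k - 1]
        neigh.append([j for j in range(n)
                      if j != i and d[i, j] <= kdist[i] + 1e-12])
    lrd = np.empty(n)
    for i in range(n):
        reach = [max(kdist[j], d[i, j]) for j in neigh[i]]
        lrd[i] = 1.0 / (sum(reach) / len(reach))
    lof = np.empty(n)
    for i in range(n):
        lof[i] = sum(lrd[j] for j in neigh[i]) / (len(neigh[i]) * lrd[i])
    return lof


def hypergeom_tail(k: int, n_a: int, n_b: int, n: int) -> float:
    """P(overlap >= k) for two fixed-size subsets of n genes, by
    enumeration of the hypergeometric probability mass."""
    total = 0.0
    for j in range(k, min(n_a, n_b) + 1):
        total += (math.comb(n_a, j) * math.comb(n - n_a, n_b - j)
                  / math.comb(n, n_b))
    return min(total, 1.0)


def scale_free_fit_regression(log_k, log_p) -> float:
    """Two-pass least-squares R^2 with slope sign, computed from sums."""
    lk = np.asarray(log_k, dtype=float)
    lp = np.asarray(log_p, dtype=float)
    mk, mp = lk.mean(), lp.mean()
    sxy = float(((lk - mk) * (lp - mp)).sum())
    sxx = float(((lk - mk) ** 2).sum())
    syy = float(((lp - mp) ** 2).sum())
    slope = sxy / sxx
    r2 = sxy ** 2 / (sxx * syy)
    return -math.copysign(1.0, slope) * r2
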