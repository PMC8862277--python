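"""Dependence metrics for gene co-expression analysis.

Four pairwise metrics share a common interface: Pearson and Spearman
correlation (signed, in [-1, 1]), the empirical distance correlation
(unsigned, in [0, 1]), and a simplified maximal information coefficient
(unsigned, in [0, 1]).  All are accompanied by a seeded permutation test of
independence and a pairwise-matrix driver for whole expression matrices.

The distance correlation R_n is the square root of

    R_n^2 = V_n^2(X, Y) / sqrt(V_n^2(X) V_n^2(Y)),

where V_n^2(X, Y) = (1/n^2) sum_kl A_kl B_kl is the empirical distance
covariance built from doubly centered pairwise-distance matrices
A_kl = a_kl - abar_k. - abar_.l + abar_.. with a_kl = |X_k - X_l|.
R_n is zero only in the degenerate (constant-input) convention; at the
population level distance correlation vanishes iff X and Y are independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._mic import best_mi_profile, clump_cumulative

METRICS = ("pearson", "spearman", "mic", "dcor")

#: metrics whose statistic is signed; permutation tests use |statistic|
SIGNED_METRICS = ("pearson", "spearman")


class DegenerateWarning(UserWarning):
    """Raised (as a warning) when a zero-variance convention is applied."""


def _as_vector(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"expected a 1-D sample vector, got shape {v.shape}")
    if v.size < 2:
        raise ValueError(f"need at least 2 observations, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("sample vector contains non-finite values")
    return v


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv, yv = _as_vector(x), _as_vector(y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    return xv, yv


def _is_constant(v: np.ndarray) -> bool:
    return bool(np.ptp(v) == 0.0)


def validate_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return metric


# ---------------------------------------------------------------------------
# scalar metrics


def pearson(x, y) -> float:
    """Sample product-moment correlation; 0 (with a warning) if either
    vector is constant."""
    xv, yv = _check_pair(x, y)
    if _is_constant(xv) or _is_constant(yv):
        warnings.warn("constant input: pearson set to 0", DegenerateWarning,
                      stacklevel=2)
        return 0.0
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


def spearman(x, y) -> float:
    """Rank correlation: Pearson correlation of average-ranked data."""
    xv, yv = _check_pair(x, y)
    if _is_constant(xv) or _is_constant(yv):
        warnings.warn("constant input: spearman set to 0", DegenerateWarning,
                      stacklevel=2)
        return 0.0
    return pearson(rankdata(xv), rankdata(yv))


def center_distance_matrix(x) -> np.ndarray:
    """Doubly centered pairwise absolute-difference matrix.

    A_kl = a_kl - abar_k. - abar_.l + abar_.. with a_kl = |x_k - x_l|;
    every row and column of the result sums to zero.
    """
    xv = _as_vector(x)
    a = np.abs(xv[:, None] - xv[None, :])
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def distance_covariance_sq(x, y) -> float:
    """Empirical squared distance covariance V_n^2(X, Y) >= 0."""
    xv, yv = _check_pair(x, y)
    a = center_distance_matrix(xv)
    b = center_distance_matrix(yv)
    return max(float((a * b).mean()), 0.0)


def distance_correlation(x, y) -> float:
    """Empirical distance correlation R_n(X, Y) in [0, 1].

    Returns 0 (with a warning) when either marginal distance variance
    vanishes, i.e. when an input is constant.
    """
    xv, yv = _check_pair(x, y)
    a = center_distance_matrix(xv)
    b = center_distance_matrix(yv)
    vxx = float((a * a).mean())
    vyy = float((b * b).mean())
    if vxx * vyy <= 0.0:
        warnings.warn("zero distance variance: dcor set to 0",
                      DegenerateWarning, stacklevel=2)
        return 0.0
    vxy = max(float((a * b).mean()), 0.0)
    r2 = vxy / math.sqrt(vxx * vyy)
    return math.sqrt(min(r2, 1.0))


def _equifreq_labels(v: np.ndarray, c: int) -> np.ndarray:
    """Assign each point to one of c equal-frequency bins (ordinal ranks)."""
    n = v.size
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * c) // n


def mic(x, y, alpha: float = 0.6, max_clumps_factor: float = 15.0) -> float:
    """Simplified maximal information coefficient in [0, 1].

    Searches r x c grids with r*c <= B(n) = n**alpha (floored at 4 so the
    2x2 grid is always admissible).  One axis is an equal-frequency c-bin
    partition; the other is optimised by dynamic programming over clumps,
    capped at ``max_clumps_factor * r`` superclumps.  Both orientations are
    tried.  Values may differ from the reference MINE implementation.
    """
    xv, yv = _check_pair(x, y)
    n = xv.size
    if n < 4:
        raise ValueError(f"mic requires n >= 4, got {n}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if _is_constant(xv) or _is_constant(yv):
        warnings.warn("constant input: mic set to 0", DegenerateWarning,
                      stacklevel=2)
        return 0.0
    b_n = max(float(n) ** alpha, 4.0)
    best = 0.0
    for free, fixed in ((xv, yv), (yv, xv)):
        order = np.lexsort((fixed, free))
        c_top = int(b_n // 2)
        for c in range(2, c_top + 1):
            rmax = int(b_n // c)
            if rmax < 2:
                break
            labels = _equifreq_labels(fixed, c)[order]
            cap = max(int(math.ceil(max_clumps_factor * rmax)), rmax)
            cum = clump_cumulative(labels, c, cap)
            prof = best_mi_profile(cum, c, n, rmax)
            for r in range(2, rmax + 1):
                val = (prof[r] / math.log(2)) / math.log2(min(r, c))
                if val > best:
                    best = val
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# permutation test

_TIE_EPS = 1e-12


def _perm_stats(metric: str, xv: np.ndarray, yv: np.ndarray, n_perm: int,
                rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """Observed statistic (|.| for signed metrics) and permuted statistics.

    Only y is permuted; the x-side precomputations are shared across
    permutations, which makes the dcor and mic tests tractable.
    """
    n = xv.size
    if metric in SIGNED_METRICS:
        if metric == "spearman":
            xs, ys = rankdata(xv), rankdata(yv)
        else:
            xs, ys = xv, yv
        if _is_constant(xs) or _is_constant(ys):
            return 0.0, np.zeros(n_perm)
        xs = (xs - xs.mean()) / xs.std()
        ys = (ys - ys.mean()) / ys.std()
        obs = abs(float(xs @ ys) / n)
        idx = np.empty((n_perm, n), dtype=np.intp)
        for i in range(n_perm):
            idx[i] = rng.permutation(n)
        perm = np.abs(ys[idx] @ xs) / n
        return obs, perm
    if metric == "dcor":
        a = center_distance_matrix(xv)
        b = center_distance_matrix(yv)
        vxx = float((a * a).mean())
        vyy = float((b * b).mean())
        if vxx * vyy <= 0.0:
            return 0.0, np.zeros(n_perm)
        denom = math.sqrt(vxx * vyy)
        obs = math.sqrt(min(max(float((a * b).mean()), 0.0) / denom, 1.0))
        perm = np.empty(n_perm)
        for i in range(n_perm):
            p = rng.permutation(n)
            vxy = max(float((a * b[np.ix_(p, p)]).mean()), 0.0)
            perm[i] = math.sqrt(min(vxy / denom, 1.0))
        return obs, perm
    # mic
    obs = mic(xv, yv)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = mic(xv, yv[rng.permutation(n)])
    return obs, perm


def permutation_pvalue(metric: str, x, y, n_perm: int = 199,
                       seed: int | np.random.Generator = 0) -> float:
    """Permutation p-value for the independence test H0: X indep Y.

    Uses the add-one estimator p = (1 + #{permuted >= observed}) /
    (1 + n_perm), so p is never 0; signed metrics are compared through
    their absolute value.  Deterministic given the seed.
    """
    validate_metric(metric)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xv, yv = _check_pair(x, y)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    obs, perm = _perm_stats(metric, xv, yv, n_perm, rng)
    hits = int(np.sum(perm >= obs - _TIE_EPS))
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# pairwise matrices


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene dependence matrix tagged with its metric."""

    metric: str
    genes: list
    values: np.ndarray
    constant_genes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        g = len(self.genes)
        if self.values.shape != (g, g):
            raise ValueError("values shape does not match gene list")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


def _expr_to_array(expr) -> tuple[np.ndarray, list]:
    if hasattr(expr, "gene_ids") and hasattr(expr, "values"):
        return np.asarray(expr.values, dtype=float), list(expr.gene_ids)
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), list(expr.index)
    arr = np.asarray(expr, dtype=float)
    return arr, list(range(arr.shape[0]))


def _pearson_rows(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g, n = vals.shape
    sd = vals.std(axis=1)
    const = sd == 0.0
    xs = vals - vals.mean(axis=1, keepdims=True)
    safe = np.where(const, 1.0, sd)
    xs /= safe[:, None]
    corr = xs @ xs.T / n
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    return corr, const


# keep the stacked centered-distance fast path under ~1.6 GB
_DCOR_FAST_BUDGET = 200_000_000


def _dcor_matrix(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g, n = vals.shape
    centered = [center_distance_matrix(vals[i]) for i in range(g)]
    dvar = np.array([float((a * a).mean()) for a in centered])
    const = dvar <= 0.0
    if g * n * n <= _DCOR_FAST_BUDGET:
        flat = np.stack([a.ravel() for a in centered])
        v = flat @ flat.T / (n * n)
    else:
        v = np.empty((g, g))
        for i in range(g):
            ai = centered[i]
            for j in range(i, g):
                v[i, j] = v[j, i] = float((ai * centered[j]).mean())
    np.clip(v, 0.0, None, out=v)
    denom = np.sqrt(np.outer(dvar, dvar))
    denom[denom == 0.0] = 1.0
    r = np.sqrt(np.clip(v / denom, 0.0, 1.0))
    np.fill_diagonal(r, 1.0)
    r[const, :] = 0.0
    r[:, const] = 0.0
    return r, const


def pairwise_matrix(expr, metric: str, progress: bool = False,
                    **metric_kwargs) -> CorrelationMatrix:
    """Compute the gene x gene dependence matrix for one metric.

    Only the upper triangle is computed where no vectorised path exists;
    results are mirrored, so the output is symmetric by construction.
    Constant genes are flagged and their entries set to 0 by the degenerate
    convention.
    """
    validate_metric(metric)
    vals, genes = _expr_to_array(expr)
    if vals.ndim != 2 or vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if not np.all(np.isfinite(vals)):
        raise ValueError("expression matrix contains non-finite values")
    g = vals.shape[0]

    if metric == "pearson":
        corr, const = _pearson_rows(vals)
    elif metric == "spearman":
        ranked = np.apply_along_axis(rankdata, 1, vals)
        corr, const = _pearson_rows(ranked)
    elif metric == "dcor":
        corr, const = _dcor_matrix(vals)
    else:  # mic
        const = np.ptp(vals, axis=1) == 0.0
        corr = np.zeros((g, g))
        iterator = range(g)
        if progress:  # pragma: no cover - cosmetic
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="mic rows")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateWarning)
            for i in iterator:
                for j in range(i + 1, g):
                    corr[i, j] = corr[j, i] = mic(vals[i], vals[j],
                                                  **metric_kwargs)
        np.fill_diagonal(corr, 1.0)
        corr[const, :] = 0.0
        corr[:, const] = 0.0

    const_genes = [genes[i] for i in np.flatnonzero(const)]
    if const_genes:
        warnings.warn(f"{len(const_genes)} constant gene(s) set to 0",
                      DegenerateWarning, stacklevel=2)
    return CorrelationMatrix(metric, genes, corr, const_genes)
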