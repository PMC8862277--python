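"""Weighted network construction: similarity, soft-threshold adjacency,
connectivity, topological overlap, and scale-free-topology fit.

The unsigned similarity s_ij = |cor(i, j)| is raised elementwise to a
soft-thresholding power beta, giving a weighted adjacency a_ij = s_ij**beta.
Connectivity is k_i = sum_{j != i} a_ij.  The network approximates
scale-free topology when the binned degree distribution p(k) follows
p(k) ~ k**-gamma; the fit index is the signed R^2 of the log10 p(k) on
log10 k regression (negative when the distribution rises with k).  beta is
chosen as the smallest candidate whose fit index reaches a target
(conventionally 0.9).

The topological overlap of genes i and j combines their direct adjacency
with their shared neighbourhood:

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij     = sum_u a_iu a_uj,

with omega_ii = 1; the clustering dissimilarity is 1 - omega.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .metrics import CorrelationMatrix, pairwise_matrix

log = logging.getLogger(__name__)


@dataclass
class AdjacencyMatrix:
    """Symmetric weighted adjacency in [0, 1] with its soft power."""

    values: np.ndarray
    beta: int
    genes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SftReport:
    """Scale-free-fit diagnostics per candidate soft-thresholding power."""

    powers: list
    fit_index: list
    mean_connectivity: list
    recommended_power: int | None
    target: float = 0.9

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "power": self.powers,
            "fit_index": self.fit_index,
            "mean_connectivity": self.mean_connectivity,
        })


def similarity(corr: CorrelationMatrix) -> CorrelationMatrix:
    """Unsigned similarity: elementwise absolute value of the correlation.

    Already-unsigned metrics (dcor, mic) pass through unchanged.
    """
    return CorrelationMatrix(corr.metric, corr.genes, np.abs(corr.values),
                             list(corr.constant_genes))


def adjacency(sim, beta: int) -> AdjacencyMatrix:
    """Soft-threshold the similarity: a_ij = s_ij ** beta."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    if isinstance(sim, CorrelationMatrix):
        vals, genes = sim.values, sim.genes
    else:
        vals, genes = np.asarray(sim, dtype=float), []
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("similarity entries must lie in [0, 1]")
    return AdjacencyMatrix(vals ** beta, int(beta), list(genes))


def connectivity(adj) -> np.ndarray:
    """Per-gene connectivity k_i = sum_{j != i} a_ij (diagonal excluded)."""
    vals = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj)
    return vals.sum(axis=1) - np.diag(vals)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Bins k into ``n_bins`` equal-width bins, drops empty ones, and
    regresses log10 of the bin frequency on log10 of the bin mean
    connectivity.  The sign is -sign(slope), so a decreasing (power-law
    like) distribution scores positively.
    """
    kv = np.asarray(k, dtype=float)
    if kv.size < 2 or np.ptp(kv) == 0.0:
        raise ValueError("connectivity is degenerate: fewer than 2 usable bins")
    edges = np.linspace(kv.min(), kv.max(), n_bins + 1)
    which = np.clip(np.digitize(kv, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    sums = np.bincount(which, weights=kv, minlength=n_bins)
    ok = counts > 0
    means = sums[ok] / counts[ok]
    freqs = counts[ok] / kv.size
    usable = means > 0
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable bins for the log-log fit")
    res = linregress(np.log10(means[usable]), np.log10(freqs[usable]))
    return float(-np.sign(res.slope) * res.rvalue ** 2)


def tom(adj) -> np.ndarray:
    """Topological overlap matrix of an unsigned weighted adjacency."""
    a = (adj.values if isinstance(adj, AdjacencyMatrix)
         else np.asarray(adj, dtype=float)).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    den = np.maximum(den, 1e-12)
    w = num / den
    np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


def tom_dissimilarity(tom_matrix: np.ndarray) -> np.ndarray:
    """Clustering dissimilarity 1 - omega with a zero diagonal."""
    d = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def sft_report_from_similarity(sim, powers=range(1, 21),
                               target: float = 0.9,
                               n_bins: int = 10) -> SftReport:
    """Scan candidate powers on a precomputed unsigned similarity."""
    powers = list(powers)
    if not powers or any(powers[i] >= powers[i + 1]
                         for i in range(len(powers) - 1)):
        raise ValueError("powers must be a non-empty ascending sequence")
    fits, mean_k = [], []
    for beta in powers:
        k = connectivity(adjacency(sim, beta))
        mean_k.append(float(k.mean()))
        try:
            fits.append(scale_free_fit(k, n_bins))
        except ValueError:
            fits.append(float("nan"))
    recommended = None
    for beta, fit in zip(powers, fits):
        if np.isfinite(fit) and fit >= target:
            recommended = beta
            break
    if recommended is None:
        warnings.warn(f"no candidate power reached fit target {target}",
                      UserWarning, stacklevel=2)
    return SftReport(powers, fits, mean_k, recommended, target)


def pick_soft_threshold(expr, metric: str = "dcor",
                        powers=range(1, 21), target: float = 0.9,
                        n_bins: int = 10) -> SftReport:
    """Compute the metric's similarity and scan soft-thresholding powers.

    recommended_power is the smallest candidate whose scale-free fit index
    reaches ``target`` (None, with a warning, if none does).
    """
    sim = similarity(pairwise_matrix(expr, metric))
    report = sft_report_from_similarity(sim, powers, target, n_bins)
    log.info("soft-threshold scan (%s): recommended power = %s",
             metric, report.recommended_power)
    return report
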