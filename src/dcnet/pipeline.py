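"""End-to-end network pipeline: similarity -> soft threshold -> TOM ->
average-linkage dendrogram -> tree cut -> coloured module partition."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import DegenerateWarning, pairwise_matrix
from .modules_detect import (Dendrogram, ModulePartition, assign_colors,
                             cut_tree_dynamic, hclust_average)
from .network import (SftReport, adjacency, similarity,
                      sft_report_from_similarity, tom, tom_dissimilarity)

log = logging.getLogger(__name__)


@dataclass
class NetworkResult:
    metric: str
    beta: int
    sft: SftReport
    dendrogram: Dendrogram
    partition: ModulePartition


def run_network_pipeline(expr, metric: str = "dcor", powers=range(1, 21),
                         sft_target: float = 0.9, beta: int | None = None,
                         min_cluster_size: int = 30,
                         cut_height_fraction: float = 0.99) -> NetworkResult:
    """Build the co-expression network and detect modules.

    ``beta`` overrides the soft-threshold scan; otherwise the smallest
    power reaching ``sft_target`` is used, falling back to the best-fitting
    candidate (with a warning) when none reaches the target.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateWarning)
        sim = similarity(pairwise_matrix(expr, metric))
    with warnings.catch_warnings(record=True):
        warnings.simplefilter("always")
        sft = sft_report_from_similarity(sim, powers, sft_target)
    if beta is None:
        # a fit index computed on an almost-empty network is meaningless, so
        # only powers keeping mean connectivity >= 1 are eligible: the first
        # eligible power reaching the target, else the best-fitting eligible
        # power (not every network is scale-free; planted equal blocks are
        # not, and their fit can cross the target spuriously once the
        # adjacency has been soft-thresholded into near-emptiness)
        fits = np.asarray(sft.fit_index, dtype=float)
        if not np.any(np.isfinite(fits)):
            raise ValueError("scale-free fit undefined for all powers")
        mean_k = np.asarray(sft.mean_connectivity, dtype=float)
        ok = np.isfinite(fits) & (mean_k >= 1.0)
        if not ok.any():
            ok = np.isfinite(fits)
        reached = ok & (fits >= sft_target)
        if reached.any():
            beta = sft.powers[int(np.argmax(reached))]
        else:
            beta = sft.powers[int(np.argmax(np.where(ok, fits, -np.inf)))]
            log.warning("no usable power reached fit %.2f; using best-fit "
                        "power %d", sft_target, beta)
    adj = adjacency(sim, beta)
    diss = tom_dissimilarity(tom(adj))
    dendro = hclust_average(diss, expr.gene_ids)
    partition = assign_colors(cut_tree_dynamic(dendro, min_cluster_size,
                                               cut_height_fraction))
    sizes = partition.module_sizes()
    log.info("pipeline(%s): beta=%d, %d modules, sizes=%s", metric, beta,
             partition.n_modules, sizes)
    return NetworkResult(metric, int(beta), sft, dendro, partition)
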