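"""Module detection: average-linkage clustering of the TOM dissimilarity
and static-height tree cutting with a minimum module size.

Branches of the dendrogram below the cut height that contain at least
``min_cluster_size`` leaves become modules, numbered by decreasing size;
everything else is left unassigned (label 0, colour "grey").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

# WGCNA's standard module colour order, for familiarity
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

UNASSIGNED_COLOR = "grey"


@dataclass
class Dendrogram:
    """Average-linkage merge tree over g gene leaves (scipy linkage form)."""

    linkage_matrix: np.ndarray
    gene_ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.gene_ids)

    @property
    def max_height(self) -> float:
        return float(self.linkage_matrix[:, 2].max())


@dataclass
class ModulePartition:
    """Per-gene module labels; 0 means unassigned ("grey")."""

    gene_ids: list
    labels: np.ndarray
    colors: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.gene_ids),):
            raise ValueError("labels length does not match gene_ids")

    @property
    def n_modules(self) -> int:
        return int(len(set(self.labels) - {0}))

    def module_sizes(self) -> dict:
        uniq, cnt = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, cnt)}

    def genes_in(self, label: int) -> list:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def to_dataframe(self) -> pd.DataFrame:
        colors = self.colors if self.colors else [""] * len(self.gene_ids)
        return pd.DataFrame({"gene_id": self.gene_ids,
                             "module": self.labels,
                             "color": colors})


def hclust_average(diss, gene_ids=None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a symmetric dissimilarity."""
    d = np.asarray(diss, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    if gene_ids is None:
        gene_ids = list(range(d.shape[0]))
    return Dendrogram(z, list(gene_ids))


def cut_tree_dynamic(dendro: Dendrogram, min_cluster_size: int = 30,
                     cut_height_fraction: float = 0.99) -> ModulePartition:
    """Static-height branch decomposition with a minimum module size.

    The tree is cut at ``cut_height_fraction`` times the maximum merge
    height; sub-branches with at least ``min_cluster_size`` leaves become
    modules ordered by decreasing size (ties broken by the smallest
    contained gene index), smaller branches are left grey.
    """
    g = dendro.n_leaves
    if not 0.0 < cut_height_fraction <= 1.0:
        raise ValueError("cut_height_fraction must be in (0, 1]")
    if min_cluster_size > g:
        raise ValueError("min_cluster_size exceeds the number of genes")
    h = cut_height_fraction * dendro.max_height
    raw = fcluster(dendro.linkage_matrix, t=h, criterion="distance")
    labels = np.zeros(g, dtype=int)
    branches = []
    for b in np.unique(raw):
        members = np.flatnonzero(raw == b)
        if members.size >= min_cluster_size:
            branches.append((members.size, members[0], members))
    branches.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, members) in enumerate(branches, start=1):
        labels[members] = rank
    return ModulePartition(list(dendro.gene_ids), labels)


def assign_colors(partition: ModulePartition) -> ModulePartition:
    """Attach the conventional colour names to module ids (0 -> grey)."""
    colors = []
    for l in partition.labels:
        if l == 0:
            colors.append(UNASSIGNED_COLOR)
        elif l <= len(COLOR_SEQUENCE):
            colors.append(COLOR_SEQUENCE[l - 1])
        else:
            colors.append(f"module{l}")
    return ModulePartition(list(partition.gene_ids), partition.labels.copy(),
                           colors)


def write_partition_tsv(partition: ModulePartition, path) -> None:
    part = partition if partition.colors else assign_colors(partition)
    part.to_dataframe().to_csv(path, sep="\t", index=False)


def write_partition_gmt(partition: ModulePartition, path,
                        description: str = "co-expression module") -> None:
    """GMT-style per-module gene lists for external enrichment tools."""
    part = partition if partition.colors else assign_colors(partition)
    by_label: dict[int, list] = {}
    for gene, label in zip(part.gene_ids, part.labels):
        if label != 0:
            by_label.setdefault(int(label), []).append(gene)
    color_of = {int(l): c for l, c in zip(part.labels, part.colors)}
    with open(path, "w") as fh:
        for label in sorted(by_label):
            genes = "\t".join(str(g) for g in by_label[label])
            fh.write(f"{color_of[label]}\t{description}\t{genes}\n")
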