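"""Evaluation harness: permutation-test power curves and their AUC,
split-half stability of highly correlated gene pairs, module-preservation
overlap statistics, complex-pair fractions, and enrichment-score
aggregation.

The "power curve" (ROC curve in the loose sense used for dependence-metric
benchmarking) plots, over repeated simulated samples, the proportion of
rejected independence nulls against the significance level; its trapezoidal
area summarises test power (0.5 = no better than random rejection).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .metrics import (CorrelationMatrix, pairwise_matrix, permutation_pvalue,
                      validate_metric, DegenerateWarning)
from .synthdata import RelationshipSpec, gen_relationship

log = logging.getLogger(__name__)

#: significance-level grid for power curves: 0, 0.01, ..., 1.00
SIG_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


@dataclass
class PowerCurve:
    """Rejection proportion per significance level for one metric."""

    metric: str
    sig_levels: np.ndarray
    rejection_rate: np.ndarray
    n_reps: int
    sample_size: int

    def __post_init__(self):
        self.sig_levels = np.asarray(self.sig_levels, dtype=float)
        self.rejection_rate = np.asarray(self.rejection_rate, dtype=float)
        if self.sig_levels.shape != self.rejection_rate.shape:
            raise ValueError("grid and rates must have equal length")


@dataclass
class StabilityResult:
    """Mean absolute between-half difference for top-n ranked gene pairs."""

    metric: str
    top_ns: list
    mean_abs_diff: list
    n_pairs_total: int = 0


@dataclass
class OverlapResult:
    """Cross-tabulation of two partitions with per-cell Fisher statistics."""

    row_labels: list
    col_labels: list
    counts: np.ndarray
    fisher_p: np.ndarray
    neg_log_p: np.ndarray

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)

    def neg_log_p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.neg_log_p, index=self.row_labels,
                            columns=self.col_labels)


def power_pvalues(spec: RelationshipSpec, metric: str, n: int | None = None,
                  n_reps: int = 1000, n_perm: int = 199,
                  seed: int = 0, generator=None) -> np.ndarray:
    """Permutation p-values over repeated draws from a relationship family.

    ``generator`` may override the family: any callable rng -> (x, y).
    Each repetition gets an independent child stream of ``seed``, so the
    whole simulation is reproducible and rep-order independent.
    """
    validate_metric(metric)
    if n is not None:
        spec = RelationshipSpec(spec.kind, n, spec.noise_sd, spec.seed)
    draw = generator if generator is not None \
        else (lambda rng: gen_relationship(spec, rng))
    pvals = np.empty(n_reps)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateWarning)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            x, y = draw(rng)
            pvals[i] = permutation_pvalue(metric, x, y, n_perm, rng)
    return pvals


def curve_from_pvalues(pvals: np.ndarray, metric: str,
                       sample_size: int) -> PowerCurve:
    rates = np.array([(pvals <= a + 1e-12).mean() for a in SIG_GRID])
    return PowerCurve(metric, SIG_GRID.copy(), rates, len(pvals), sample_size)


def power_curve(spec: RelationshipSpec, metric: str, n: int | None = None,
                n_reps: int = 1000, n_perm: int = 199, seed: int = 0,
                generator=None) -> PowerCurve:
    """Simulate the rejection-proportion curve for one metric and family."""
    pvals = power_pvalues(spec, metric, n, n_reps, n_perm, seed, generator)
    return curve_from_pvalues(pvals, metric, n if n is not None else spec.n)


def auc(curve) -> float:
    """Trapezoidal area under a power curve (or (levels, rates) pair)."""
    if isinstance(curve, PowerCurve):
        levels, rates = curve.sig_levels, curve.rejection_rate
    else:
        levels, rates = (np.asarray(v, dtype=float) for v in curve)
    if levels.size < 2:
        raise ValueError("need at least 2 grid points")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("significance grid must be strictly increasing")
    return float(np.trapezoid(rates, levels))


def power_auc_table(kinds, metrics, ns, n_reps: int = 1000,
                    n_perm: int = 199, seed: int = 0,
                    noise_sd: float | None = None) -> pd.DataFrame:
    """AUC per (relationship, sample size, metric) — a benchmark table."""
    rows = []
    root = np.random.SeedSequence(seed)
    for kind in kinds:
        for n in ns:
            for metric in metrics:
                child = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
                spec = RelationshipSpec(kind, n, noise_sd)
                a = auc(power_curve(spec, metric, n, n_reps, n_perm, child))
                rows.append({"relationship": kind, "n": n,
                             "metric": metric, "auc": a})
                log.info("power: %s n=%d %s auc=%.4f", kind, n, metric, a)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stability


def split_half_stability(expr, metric: str, top_ns=(100, 250, 500),
                         seed: int = 0, split=None) -> StabilityResult:
    """Between-half agreement of the most correlated gene pairs.

    Samples are split randomly into two equal halves (one leftover sample
    is dropped and logged).  Pairs are ranked by |corr| in half 1; for each
    ``top_n`` the mean absolute difference between the two halves'
    coefficients over those pairs is reported (smaller = more stable).
    An explicit ``split`` (two index sequences) overrides the random one.
    """
    validate_metric(metric)
    n = expr.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if split is None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        if n % 2:
            log.info("odd sample count: dropping sample %s",
                     expr.sample_ids[perm[-1]])
            perm = perm[:-1]
        half = len(perm) // 2
        split = (np.sort(perm[:half]), np.sort(perm[half:]))
    idx1, idx2 = (np.asarray(s) for s in split)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateWarning)
        c1 = pairwise_matrix(expr.select_samples(idx1), metric)
        c2 = pairwise_matrix(expr.select_samples(idx2), metric)
    iu = np.triu_indices(c1.n_genes, k=1)
    v1, v2 = c1.values[iu], c2.values[iu]
    n_pairs = v1.size
    order = np.argsort(-np.abs(v1), kind="stable")
    diffs, used = [], []
    for top in top_ns:
        if top > n_pairs:
            raise ValueError(f"top_n={top} exceeds {n_pairs} gene pairs")
        sel = order[:top]
        diffs.append(float(np.abs(v1[sel] - v2[sel]).mean()))
        used.append(int(top))
    return StabilityResult(metric, used, diffs, n_pairs)


def module_overlap(part_a, part_b) -> OverlapResult:
    """Fisher's exact overlap statistics between two module partitions.

    For every (module in A, module in B) cell the 2x2 collapse
    (in/out of the A module x in/out of the B module) is tested one-sided
    for over-enrichment; neg_log_p is the natural -log(p), so values above
    ~50 indicate very strongly preserved modules.
    """
    if list(part_a.gene_ids) != list(part_b.gene_ids):
        if set(part_a.gene_ids) != set(part_b.gene_ids):
            raise ValueError("partitions cover different gene sets")
        pos = {g: i for i, g in enumerate(part_b.gene_ids)}
        order = [pos[g] for g in part_a.gene_ids]
        b_labels = part_b.labels[order]
    else:
        b_labels = part_b.labels
    a_labels = part_a.labels
    n = a_labels.size
    rows = sorted(set(a_labels.tolist()))
    cols = sorted(set(b_labels.tolist()))
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for i, ra in enumerate(rows):
        for j, cb in enumerate(cols):
            counts[i, j] = int(np.sum((a_labels == ra) & (b_labels == cb)))
    fisher_p = np.ones_like(counts, dtype=float)
    for i, ra in enumerate(rows):
        na = int(np.sum(a_labels == ra))
        for j, cb in enumerate(cols):
            nb = int(np.sum(b_labels == cb))
            k = counts[i, j]
            table = [[k, na - k], [nb - k, n - na - nb + k]]
            fisher_p[i, j] = fisher_exact(table, alternative="greater")[1]
    neg_log_p = -np.log(fisher_p)
    return OverlapResult(rows, cols, counts, fisher_p, neg_log_p)


def complex_pair_fraction(corr_pearson: CorrelationMatrix,
                          corr_dcor: CorrelationMatrix,
                          dcor_cut: float = 0.5,
                          pearson_cut: float = 0.5) -> float:
    """Fraction of strong-dcor gene pairs that Pearson would miss.

    Among upper-triangle pairs with dcor > ``dcor_cut``, the fraction with
    |Pearson| < ``pearson_cut``; 0 (with a warning) when no pair qualifies.
    """
    if list(corr_pearson.genes) != list(corr_dcor.genes):
        raise ValueError("correlation matrices cover different genes")
    iu = np.triu_indices(corr_dcor.n_genes, k=1)
    strong = corr_dcor.values[iu] > dcor_cut
    if not strong.any():
        warnings.warn("no gene pair passes the dcor cut; fraction set to 0",
                      UserWarning, stacklevel=2)
        return 0.0
    return float((np.abs(corr_pearson.values[iu][strong])
                  < pearson_cut).mean())


def enrichment_score(member_pvalues) -> float:
    """Annotation-cluster enrichment score.

    -log10 of the geometric mean of the member p-values, i.e. the
    arithmetic mean of -log10(p); higher means more enriched.
    """
    p = np.asarray(member_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.mean(-np.log10(p)))
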