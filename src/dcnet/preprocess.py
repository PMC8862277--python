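"""Expression-matrix I/O, filtering, transformation and screening.

The container is a thin genes x samples matrix with identifier bookkeeping.
Filtering follows the usual co-expression preamble: drop low-intensity genes
(per-gene mean at or below the grand mean of per-gene means) and
low-variability genes (coefficient of variation sd/mean at or below a
threshold), since flat genes are uninformative for network analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import shapiro
from sklearn.neighbors import LocalOutlierFactor

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix (typically log-scale intensity)."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        g, n = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (g, n):
            raise ValueError(
                f"values shape {self.values.shape} != ({g} genes, {n} samples)")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} identifier: {i!r}")
                seen.add(i)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def select_genes(self, mask_or_ids) -> "ExpressionMatrix":
        mask = np.asarray(mask_or_ids)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in mask_or_ids])
        return ExpressionMatrix([self.gene_ids[i] for i in idx],
                                self.sample_ids, self.values[idx])

    def select_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(self.gene_ids,
                                [self.sample_ids[i] for i in idx],
                                self.values[:, idx])


@dataclass
class FilterReport:
    n_input_genes: int
    n_kept_genes: int
    mean_threshold: float
    cv_threshold: float
    n_zero_mean: int = 0

    def __post_init__(self):
        if self.n_kept_genes > self.n_input_genes:
            raise ValueError("kept more genes than supplied")


def read_expression(path, delimiter: str = "\t",
                    transpose: bool = False) -> ExpressionMatrix:
    """Read a delimited expression table (header row + row labels).

    Genes end up on rows regardless of file orientation: pass
    ``transpose=True`` for samples-on-rows files.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate row identifier: {dup[0]!r}")
    dupc = df.columns[df.columns.duplicated()]
    if len(dupc):
        raise ValueError(f"duplicate column identifier: {dupc[0]!r}")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if transpose:
        df = df.T
    expr = ExpressionMatrix.from_dataframe(df)
    log.info("read %d genes x %d samples from %s",
             expr.n_genes, expr.n_samples, path)
    return expr


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t",
                     float_format: str = "%.12g") -> None:
    expr.to_dataframe().to_csv(path, sep=delimiter, float_format=float_format)


def log2_plus1(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); input values must be non-negative counts."""
    if np.any(expr.values < 0):
        raise ValueError("log2_plus1 requires non-negative values")
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids,
                            np.log2(expr.values + 1.0))


def filter_genes(expr: ExpressionMatrix, cv_threshold: float = 0.05,
                 mean_threshold: float | None = None,
                 ) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes above average intensity with CV above ``cv_threshold``.

    A gene is kept when its mean expression strictly exceeds
    ``mean_threshold`` (default: the grand mean of per-gene means of the
    input) and its coefficient of variation sd/mean strictly exceeds
    ``cv_threshold``.  Zero-mean genes (undefined CV) are excluded and
    counted.  Pass the report's ``mean_threshold`` back in to re-filter
    reproducibly.
    """
    if expr.n_genes < 1:
        raise ValueError("empty expression matrix")
    means = expr.values.mean(axis=1)
    sds = expr.values.std(axis=1, ddof=1) if expr.n_samples > 1 \
        else np.zeros(expr.n_genes)
    if mean_threshold is None:
        mean_threshold = float(means.mean())
    zero = means == 0.0
    if zero.any():
        log.warning("excluding %d zero-mean gene(s) (CV undefined)",
                    int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(zero, 0.0, sds / np.where(zero, 1.0, means))
    keep = (~zero) & (means > mean_threshold) & (cv > cv_threshold)
    report = FilterReport(expr.n_genes, int(keep.sum()),
                          float(mean_threshold), float(cv_threshold),
                          int(zero.sum()))
    log.info("filter: kept %d / %d genes (mean > %.4g, CV > %.2g)",
             report.n_kept_genes, report.n_input_genes,
             mean_threshold, cv_threshold)
    return expr.select_genes(keep), report


def normality_fraction(expr: ExpressionMatrix, alpha: float = 0.01) -> float:
    """Fraction of genes that pass a Shapiro-Wilk normality screen.

    A gene counts as (plausibly) normal when its Shapiro-Wilk p-value
    exceeds ``alpha``.  Valid for 3 <= n_samples <= 5000.
    """
    n = expr.n_samples
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {n}")
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in expr.values:
            if np.ptp(row) == 0.0:
                continue  # constant profile: certainly not normal
            if shapiro(row).pvalue > alpha:
                hits += 1
    return hits / expr.n_genes


def lof_outliers(x, y, k: int = 5, threshold: float = 1.5,
                 return_scores: bool = False):
    """Flag 2-D outliers by local outlier factor (LOF > ``threshold``).

    ``k`` is the neighbourhood size; requires n > k >= 1.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = xv.size
    if not 1 <= k < n:
        raise ValueError(f"need n > k >= 1 (n={n}, k={k})")
    pts = np.column_stack([xv, yv])
    lof = LocalOutlierFactor(n_neighbors=k)
    lof.fit(pts)
    scores = -lof.negative_outlier_factor_
    flags = scores > threshold
    if return_scores:
        return flags, scores
    return flags
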