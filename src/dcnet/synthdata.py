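"""Seeded generators for synthetic gene-pair and expression-matrix data.

Six bivariate relationship families mirror the shapes commonly observed
between gene expression profiles: independent, linear, power-function
(non-linear monotone), threshold, quadripartite (four clumps whose layout is
dependent but linearly uncorrelated) and parabolic (non-linear,
non-monotone).  Outlier injection displaces points along or normal to the
least-squares regression line of the base cloud.  Module planting embeds
latent-factor gene blocks in an otherwise independent expression matrix.

Every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import ExpressionMatrix

RELATIONSHIP_KINDS = ("independent", "linear", "power", "threshold",
                      "quadripartite", "parabolic")

#: per-family default noise levels, chosen so that at n = 30 the most
#: powerful metric's rejection rate lands in a mid range where metric
#: orderings are informative rather than saturated
DEFAULT_NOISE = {
    "independent": 1.0,
    "linear": 1.4,
    "power": 2.5,
    "threshold": 0.8,
    "quadripartite": 0.4,
    "parabolic": 0.2,
}


@dataclass(frozen=True)
class RelationshipSpec:
    """A bivariate relationship family with sample size, noise and seed."""

    kind: str
    n: int = 30
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in RELATIONSHIP_KINDS:
            raise ValueError(f"unknown relationship kind {self.kind!r}; "
                             f"choose from {RELATIONSHIP_KINDS}")
        if self.n < 4:
            raise ValueError("need n >= 4")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def effective_noise(self) -> float:
        return DEFAULT_NOISE[self.kind] if self.noise_sd is None \
            else self.noise_sd


@dataclass(frozen=True)
class OutlierSpec:
    """How many planted outliers, displaced where, and how far."""

    n_outliers: int
    direction: str = "normal_to_regression"
    magnitude: float = 5.0

    def __post_init__(self):
        if self.direction not in ("along_regression", "normal_to_regression"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")


@dataclass(frozen=True)
class ModulePlant:
    """Planted-module expression design: block sizes, background, target
    within-module correlation."""

    module_sizes: tuple = (50, 45, 35, 30)
    n_background: int = 40
    n_samples: int = 100
    within_corr: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if not 0.0 < self.within_corr < 1.0:
            raise ValueError("within_corr must be in (0, 1)")

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def gen_relationship(spec: RelationshipSpec,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (x, y) sample of size spec.n from the requested family."""
    rng = _rng(spec.seed) if rng is None else rng
    n, sd = spec.n, spec.effective_noise
    kind = spec.kind
    if kind == "independent":
        return rng.standard_normal(n), rng.standard_normal(n)
    if kind == "linear":
        x = rng.standard_normal(n)
        return x, x + sd * rng.standard_normal(n)
    if kind == "power":
        x = rng.standard_normal(n)
        return x, np.sign(x) * np.abs(x) ** 3 + sd * rng.standard_normal(n)
    if kind == "threshold":
        x = rng.standard_normal(n)
        return x, (x > 0).astype(float) + sd * rng.standard_normal(n)
    if kind == "quadripartite":
        # two-level x crossed with a two-level y mixture whose separation
        # depends on the x level: four clumps, zero linear correlation
        s = rng.choice([-1.0, 1.0], size=n)
        t = rng.choice([-1.0, 1.0], size=n)
        sep = np.where(s < 0, 0.5, 1.5)
        x = s + sd * rng.standard_normal(n)
        y = t * sep + sd * rng.standard_normal(n)
        return x, y
    # parabolic
    x = rng.uniform(-1.0, 1.0, size=n)
    return x, x ** 2 + sd * rng.standard_normal(n)


def inject_outliers(x, y, spec: OutlierSpec,
                    seed: int | np.random.Generator = 0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Append planted outliers relative to the base cloud's regression line.

    A least-squares line is fitted to (x, y); outliers are placed either
    out along the line direction beyond the data span (which inflates
    linear correlation) or displaced perpendicular to it (which deflates
    it), at +/- ``magnitude`` in data units with random signs.
    """
    xv = np.asarray(x, dtype=float).copy()
    yv = np.asarray(y, dtype=float).copy()
    if spec.n_outliers == 0:
        return xv, yv
    if spec.n_outliers >= xv.size:
        raise ValueError("n_outliers must be smaller than the base sample")
    if np.ptp(xv) == 0.0:
        raise ValueError("degenerate (vertical) regression fit")
    rng = _rng(seed)
    slope, intercept = np.polyfit(xv, yv, 1)
    norm = np.hypot(1.0, slope)
    u = np.array([1.0, slope]) / norm       # along the line
    v = np.array([-slope, 1.0]) / norm      # normal to the line
    cx = xv.mean()
    center = np.array([cx, intercept + slope * cx])
    signs = rng.choice([-1.0, 1.0], size=spec.n_outliers)
    if spec.direction == "along_regression":
        offs = signs * (spec.magnitude + 0.1 * spec.magnitude
                        * rng.random(spec.n_outliers))
        pts = center + offs[:, None] * u
    else:
        span = np.ptp(xv * u[0] + yv * u[1])
        along = rng.uniform(-span / 2, span / 2, size=spec.n_outliers)
        pts = center + along[:, None] * u \
            + (signs * spec.magnitude)[:, None] * v
    return np.concatenate([xv, pts[:, 0]]), np.concatenate([yv, pts[:, 1]])


def gen_contaminated_relationship(spec: RelationshipSpec,
                                  outlier_rate: float = 0.05,
                                  magnitude: float = 8.0,
                                  direction: str = "normal_to_regression",
                                  rng: np.random.Generator | None = None,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a relationship sample with Bernoulli outlier contamination.

    Each of the n points is independently an outlier with probability
    ``outlier_rate``; the non-outliers are drawn from the base family and
    the outliers injected relative to their regression line.  Total sample
    size stays spec.n, so larger samples carry more outliers on average —
    the mechanism by which added data can *hurt* outlier-sensitive metrics.
    """
    rng = _rng(spec.seed) if rng is None else rng
    n_out = int(rng.binomial(spec.n, outlier_rate))
    n_out = min(n_out, spec.n - 4)  # keep a usable base cloud
    base = replace(spec, n=spec.n - n_out)
    x, y = gen_relationship(base, rng)
    if n_out == 0:
        return x, y
    return inject_outliers(x, y, OutlierSpec(n_out, direction, magnitude),
                           rng)


def gen_module_expression(plant: ModulePlant,
                          ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Expression matrix with planted correlated gene modules.

    Each module's genes load on a shared latent factor with weight
    sqrt(within_corr), so any two genes of a module have expected Pearson
    correlation ``within_corr``; background genes are independent noise.
    Gene order is shuffled.  Returns the matrix and the true per-gene
    module labels (0 = background).
    """
    rng = _rng(plant.seed)
    g, n = plant.n_genes, plant.n_samples
    a = np.sqrt(plant.within_corr)
    b = np.sqrt(1.0 - plant.within_corr)
    rows, labels = [], []
    for m, size in enumerate(plant.module_sizes, start=1):
        factor = rng.standard_normal(n)
        rows.append(a * factor + b * rng.standard_normal((size, n)))
        labels.extend([m] * size)
    if plant.n_background:
        rows.append(rng.standard_normal((plant.n_background, n)))
        labels.extend([0] * plant.n_background)
    values = np.vstack(rows)
    labels = np.array(labels)
    perm = rng.permutation(g)
    values, labels = values[perm], labels[perm]
    width = len(str(g))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(g)]
    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    return ExpressionMatrix(gene_ids, sample_ids, values), labels


def gen_powerlaw_degrees(gamma: float, k_max: int, n_nodes: int,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample node degrees with P(k) proportional to k**-gamma on 1..k_max."""
    if gamma <= 1.0:
        raise ValueError("gamma must be > 1")
    if k_max < 1 or n_nodes < 1:
        raise ValueError("k_max and n_nodes must be >= 1")
    rng = _rng(seed)
    ks = np.arange(1, k_max + 1, dtype=float)
    p = ks ** -gamma
    p /= p.sum()
    return rng.choice(ks, size=n_nodes, p=p)
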