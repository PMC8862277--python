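# Methods

## Dependence metrics

`dcnet` treats a gene's expression profile as a real sample vector (log-scale
intensity or log2(count+1), unitless) and measures pairwise dependence four
ways.

**Pearson / Spearman** are the textbook product-moment and rank correlations
(average ranks for ties). Both are signed in [−1, 1]; the unsigned network
uses their absolute value.

**Distance correlation** is the empirical energy-statistics estimator built
from doubly centered pairwise-distance matrices. Distances are absolute
differences (the exponent-1 choice standard for univariate profiles). The
estimator is O(n²) in time and memory per pair; for whole-matrix computation
the centered matrices are flattened and the g×g distance-covariance matrix
obtained as one BLAS product, which keeps a 200-gene × 100-sample problem
under a second. No fast O(n log n) variant is implemented. Note the
empirical R_n is biased upward under independence at small n (≈0.2 for two
independent normals at n = 100); soft-thresholding suppresses this floor in
network construction.

**MIC** here is a deliberately simplified estimator, not the reference MINE
implementation, and values can differ from it. The search space is r×c grids
with r·c ≤ B(n) = n^0.6, with B floored at 4 so the 2×2 grid is always
admissible (otherwise the estimator would be undefined below n = 11). One
axis is partitioned into c equal-frequency bins; the other axis is optimised
by dynamic programming whose atoms are clumps (maximal runs of points
sharing a fixed-axis bin in free-axis order), capped at 15·r superclumps by
equal-frequency merging — the same restriction the original ApproxMaxMI
search uses. Both orientations are searched and the best normalised mutual
information MI/log2(min(r, c)) is returned. The DP is JIT-compiled with
numba; the test suite checks it against exhaustive enumeration of all
clump-boundary cut combinations at n ≤ 20.

**Degenerate inputs.** Constant vectors make every metric's denominator
vanish; all four return 0 and emit a `DegenerateWarning` rather than NaN so
downstream matrices stay finite. Vectors containing non-finite values are
rejected outright.

## Permutation testing and power curves

Independence is tested by permuting y only (x-side precomputation — the
centered distance matrix, ranks, standardisation — is shared across
permutations, which is what makes 1000 × 199 simulations tractable). The
add-one estimator p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm) never
returns 0; default n_perm = 199. Permuted statistics are compared with a
1e−12 slack so exact ties count conservatively. With 199 permutations p is
uniform on {1/200, …, 1}, so the type-I error at α = 0.05 is exactly 0.05 in
expectation — the calibration test exploits this.

A power curve is the proportion of rejected nulls versus significance level
on the grid 0, 0.01, …, 1.00, over repeated draws from a relationship
generator; its trapezoidal AUC summarises power (0.5 = none). Each
repetition consumes an independent `SeedSequence` child stream, so results
are reproducible and independent of repetition order.

## Network construction

Unsigned similarity |cor| is raised elementwise to the soft power β.
Connectivity excludes the diagonal. The scale-free fit index bins k into 10
equal-width bins (empty bins dropped), regresses log10 frequency on log10
bin-mean connectivity, and signs the R² by −sign(slope) so rising degree
distributions are penalised; fewer than two usable bins is an error. The
plain log–log R² is used, not the truncated-exponential variant.

β is chosen as the smallest candidate (default 1..20) whose fit index
reaches 0.9. When no candidate reaches the target — planted-block networks
are not scale-free, and real data can fail too — the pipeline restricts the
candidates to those keeping mean connectivity ≥ 1 and takes the best-fitting
one. The floor matters: after heavy soft-thresholding an almost-empty
network can cross the 0.9 target spuriously while carrying no usable
topology. The `SftReport` itself always records the unrestricted first-reach
recommendation.

TOM uses the standard unsigned formula ω_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) +
1 − a_ij), diagonal fixed at 1, denominator floored at 1e−12; dissimilarity
is 1 − ω with a zero diagonal.

## Module detection

Average-linkage (UPGMA) clustering of the TOM dissimilarity via
`scipy.cluster.hierarchy.linkage`. Tree cutting is the static-height
variant: cut at `cut_height_fraction` (default 0.99) of the maximum merge
height; branches with ≥ `min_cluster_size` (default 30) leaves become
modules, ordered by decreasing size with ties broken by the smallest
contained gene index; the rest is grey (label 0). This is simpler than the
hybrid dynamic tree cut used by the WGCNA package — module boundaries can
differ from it, and the package's own recovery guarantee is therefore stated
against planted ground truth (adjusted Rand index), not label-for-label
equality with another implementation. Colours follow the conventional
module-colour order (turquoise, blue, brown, …) by decreasing size.

## Preprocessing

Gene filtering keeps genes whose mean expression strictly exceeds a mean
threshold — by default the grand mean of per-gene means of the matrix being
filtered ("above average intensity") — and whose coefficient of variation
sd/mean (sample sd, ddof 1) strictly exceeds `cv_threshold` (default 0.05,
i.e. 5%). Mean and CV are computed on the matrix as given (log scale if the
input is log scale); no back-transformation is attempted. Because the grand
mean rises after filtering, re-filtering is only a no-op when the recorded
`mean_threshold` from the report is passed back in; that is the supported
idempotence contract. Zero-mean genes have undefined CV and are excluded.

The normality screen counts genes with Shapiro–Wilk p > α (default 0.01),
valid for 3–5000 samples; constant genes count as non-normal. 2-D outlier
flagging uses the local outlier factor (k = 5 neighbours, flag at LOF > 1.5;
both configurable — the threshold is a package choice, as LOF defines no
canonical cutoff) via scikit-learn, cross-checked in the tests against a
from-scratch LOF implementation.

## Synthetic data: what it does and does not emulate

Relationship families (x standard normal unless noted; ε ~ N(0, noise²)):

| kind          | construction                          | default noise | rationale |
|---------------|---------------------------------------|---------------|-----------|
| independent   | y fresh normal                        | 1.0 (unused)  | null model |
| linear        | y = x + ε                             | 1.4           | signal corr ≈ 0.58 |
| power         | y = sign(x)·|x|³ + ε                  | 2.5           | non-linear monotone |
| threshold     | y = 1[x > 0] + ε                      | 0.8           | step response |
| quadripartite | two-level x; two-level y mixture with x-dependent separation (±0.5 vs ±1.5), jitter ε | 0.4 | four clumps, zero linear correlation, strong dependence |
| parabolic     | x ~ U(−1,1); y = x² + ε               | 0.2           | non-monotone |

Default noise levels were fixed once so that the most powerful metric's
rejection rate at n = 30, α = 0.05 lands mid-range (roughly 0.7–0.95) —
saturated generators make every metric look identical and mask the
orderings of interest. A note on the quadripartite family: a two-level ×
two-level product grid is mathematically independent whenever it is
uncorrelated (binary margins), so the four clumps are instead produced by
letting the y-mixture separation depend on the x level; this preserves the
four-clump shape while keeping linear correlation exactly zero.

Outlier injection fits a least-squares line to the base cloud and plants
points either out along the line beyond the data span (inflates |r|) or
displaced ±magnitude perpendicular to it at random positions along the line
(deflates |r|), magnitudes in data units. The contaminated generator used in
the robustness study draws the outlier count per sample as Binomial(n,
rate = 0.05) with magnitude 8: a fixed count cannot reproduce the
sample-size reversal (Pearson's power *falling* as n grows) because that
effect is driven by small samples often containing no outlier at all.

Module planting gives each module's genes a loading of sqrt(within_corr) on
a shared standard-normal latent factor plus independent noise, so any two
same-module genes have expected Pearson correlation `within_corr`;
background genes are pure noise; gene order is shuffled. Defaults: sizes
(50, 45, 35, 30) + 40 background = 200 genes × 100 samples, within_corr 0.7.

None of the generators emulate microarray/RNA-seq count distributions, mean–
variance coupling, batch effects or library-size artefacts. Passing tests
therefore demonstrate correctness of the algorithms and the claimed
qualitative metric orderings under clean Gaussian-ish conditions — not
performance guarantees on real expression data.

## Problem sizes and numerical choices

Simulation sizes used by the test and acceptance suites are a package
choice balancing Monte-Carlo error against desk-scale runtimes: 1000
repetitions for calibration (3-SE band ±0.021 around α = 0.05), 300 for the
ordering and contamination studies (AUC standard error ≈ 0.01, small against
the observed gaps of 0.05–0.4), 5 seeds for planted-module recovery.
Recovery ARI is computed over genes assigned to a module in both the truth
and the detected partition (grey excluded on both sides), with the separate
requirement that ≥ 90% of truly modular genes be assigned at all. Oracle
comparisons (distance correlation double loop, TOM triple loop, exhaustive
MIC, hypergeometric enumeration) use tolerance 1e−10.

## Known limitations

- O(n²) distance correlation: ~3000 genes × 300 samples is hours of CPU,
  consistent with the method's published complexity; no fast algorithm or
  block-wise computation for >20k genes is provided.
- The MIC estimator is intentionally simplified (see above).
- Signed and signed-hybrid networks, module eigengenes, eigengene-based
  module merging and module–trait analysis are out of scope.
- Multivariate (vector-valued) distance correlation is not implemented.
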