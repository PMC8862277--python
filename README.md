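# dcnet

Distance-correlation based weighted gene co-expression network analysis.

Gene co-expression networks are usually built on Pearson correlation, which
only sees linear association: a gene pair with a parabolic, threshold-like or
clumped relationship scores near zero and is silently dropped from the
network. `dcnet` builds the standard weighted-network pipeline (unsigned
similarity → soft-threshold adjacency → topological overlap → hierarchical
clustering → tree cut) on top of the empirical **distance correlation**, a
dependence measure that is zero (in population) only under independence, and
ships Pearson, Spearman and a simplified maximal information coefficient
(MIC) as comparators. It is aimed at computational biologists who want to ask
"what does my module structure look like under a dependence measure that can
see non-linear relationships?" and at methods people who want a reproducible,
fully synthetic benchmark harness for dependence metrics.

## The statistics

For sample vectors `x, y` of length `n`, form the pairwise distance matrices
`a_kl = |x_k − x_l|`, `b_kl = |y_k − y_l|` and double-center them,

    A_kl = a_kl − ā_k· − ā_·l + ā_··   (likewise B_kl),

so every row and column sums to zero. The empirical distance covariance and
correlation are

    V²_n(x, y) = (1/n²) Σ_kl A_kl B_kl ≥ 0,
    R_n(x, y)  = sqrt( V²_n(x, y) / sqrt(V²_n(x) V²_n(y)) ) ∈ [0, 1].

Dependence is tested by permutation: `p = (1 + #{R_perm ≥ R_obs}) / (1 +
n_perm)`, permuting `y` only (signed metrics are compared through their
absolute value). Network construction follows the usual weighted-network
conventions: adjacency `a_ij = |cor(i,j)|^β`, connectivity `k_i = Σ_{j≠i}
a_ij`, scale-free-topology fit index = signed R² of the log–log regression of
the binned degree distribution (β is the smallest power reaching 0.9), and
topological overlap

    ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),  ℓ_ij = Σ_u a_iu a_uj,

with `1 − ω` as the clustering dissimilarity. Modules are branches of the
average-linkage dendrogram below a height cut with at least
`min_cluster_size` leaves; unassigned genes form the grey module.

## Worked example

Generate a synthetic expression matrix with four planted modules (sizes
50/45/35/30, 40 background genes, 100 samples, within-module correlation
0.7), then build the distance-correlation network:

```bash
dcnet synth -o demo --seed 1
# synthetic expression (200 genes x 100 samples) -> demo

dcnet net demo/expression.tsv -o demo_net --metric dcor --no-filter
# beta=5 modules=4 -> demo_net
```

`demo_net/sft.tsv` holds the soft-threshold scan (fit index and mean
connectivity per power) and `demo_net/modules.tsv` the per-gene assignments.
For this run the pipeline picks β = 5 and recovers exactly the planted
structure — modules turquoise/blue/brown/yellow of sizes 50/45/35/30, the 40
background genes grey, adjusted Rand index 1.0 against `demo/truth.tsv`.

The same machinery benchmarks the metrics themselves. On a parabolic
gene-pair relationship Pearson is nearly blind while distance correlation
retains almost full power; on independent pairs both sit at the no-power
baseline of 0.5:

```bash
dcnet power -o demo_power --kinds parabolic,independent \
    --metrics pearson,dcor --ns 30 --reps 200 --seed 5
# relationship  n  metric     auc
#    parabolic 30 pearson 0.55165
#    parabolic 30    dcor 0.97315
#  independent 30 pearson 0.52435
#  independent 30    dcor 0.51485
```

The `auc` column is the area under the curve of rejection proportion versus
significance level over repeated simulated samples (permutation test, 199
permutations): 1.0 means the dependence is always detected at any reasonable
level, 0.5 means the test does no better than chance.

Library use mirrors the CLI:

```python
from dcnet import distance_correlation, run_network_pipeline
from dcnet.synthdata import ModulePlant, gen_module_expression

expr, truth = gen_module_expression(ModulePlant(seed=1))
result = run_network_pipeline(expr, metric="dcor")
result.partition.module_sizes()   # {0: 40, 1: 50, 2: 45, 3: 35, 4: 30}
```

`dcnet filter` applies the standard expression pre-filter (mean intensity
above the grand mean of per-gene means, coefficient of variation above a
threshold), and `dcnet stability` runs the split-half pair-stability and
module-preservation analyses (Fisher's exact overlap between halves).

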