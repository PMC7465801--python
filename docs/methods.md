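# Methods

## The execution model

A `PipelineDefinition` is a strictly linear sequence of steps; each step
owns an ordered, disjoint set of parameter names and exposes an
`operation(state, **params)` contract, an optional `evaluator(state)` and
an optional per-step `aggregator`. Given per-parameter alternative lists,
the combination plan is the Cartesian product (optionally subset by a
predicate or per-parameter allow-lists), enumerated lexicographically by
step order, then parameter order within a step, then alternative
declaration order. This ordering is part of the contract: combination
indices are stable across runs and machines.

Execution walks the *prefix tree* of the plan: one node per distinct
assignment of all parameters of steps `≤ j`. Each node's operation runs
exactly once per dataset, so step `j` of a full grid runs
`∏_{i≤j} |A_i|` times rather than `∏_i |A_i|`. Traversal is depth-first
with children in declaration order, which bounds the number of live
intermediate states by the pipeline depth; intermediates are never
persisted. Evaluator payloads, wall-clock times and statuses are recorded
per node and broadcast to the leaf combinations under the node when the
tidy per-step tables are built, so every step table has one row per
(dataset, full combination) and is joinable across steps.

Failure semantics: an operation exception marks its node `error` and all
descendant nodes `skipped`; sibling subtrees are unaffected. An evaluator
exception is recorded in the node's message but does not fail the node —
losing a metric should not lose the downstream computation. A dataset
whose initiator fails has all its nodes marked without aborting other
datasets.

Seeding: stochastic operations declare a `seed` keyword; the engine
injects `crc32(global_seed | dataset_id | node_key) & 0x7fffffff`, giving
reproducibility, independence between sibling nodes, and invariance to
traversal order. Parallelism is over datasets only (records are keyed, so
merge order is deterministic); within a dataset the prefix tree is walked
serially to preserve sharing.

Resumability: with a log path set, every completed node is appended as
one JSON line keyed by (dataset, node-key). On restart, recorded nodes
are not re-evaluated and fully recorded subtrees are skipped outright;
partially recorded subtrees re-execute operations (cheaply reproducible
under the seeding scheme) only to regenerate the state needed by missing
descendants. A crash therefore costs only the unrecorded tail of the run.

## Synthetic data

The generator produces the minimal structure every downstream module
needs to be scored exactly, with all truth recorded:

- Singlet counts are NB with mean `libfactor × mu[gene, subpop]` and a
  shared dispersion (`size = 1/dispersion`, default dispersion 0.4, a
  typical droplet-data value). Gene baselines have log-means uniform on
  (−1, 2) (natural log); each subpopulation perturbs a random 10% of
  genes by log-fold changes uniform on (1, 2) with random sign. Library
  factors are lognormal with sd 0.35.
- Doublets (default rate 0) are entrywise sums of two freshly drawn
  singlets from *different* subpopulations; their truth label joins both
  parents. Homotypic doublets exist only behind an explicit flag, for
  studying their (near-)invisibility to count-based callers.
- Low-quality cells have non-mitochondrial counts binomially thinned
  with keep probability `1/lowq_mito_inflation` (default 1/4), which
  simultaneously shrinks the library and inflates the mitochondrial
  fraction — the degradation signature.
- An optional hierarchical mode grows subpopulation means along a random
  bifurcating structure, producing close pairs of subpopulations.

What it does *not* emulate: UMI-vs-read error, ambient RNA, empty
droplets, batch effects, gene-specific dispersions, or realistic
gene-gene correlation beyond the subpopulation structure. Tests passing
on this generator show the algorithms implement their definitions and
respond to planted signal; they do not certify performance on real
tissue.

## QC metrics and filters

Five covariates per cell: `log10_total_counts`, `log10_total_features`
(count > 0 defines "detected"), `pct_counts_in_top_20_features` (and the
top-50 variant used by the multivariate filter), `featcount_dist` — the
residual of an OLS fit of log10 features on log10 counts across all
cells (a robust Theil–Sen fit is an option) — and `pct_counts_Mt`.
Fractions are stored in [0, 1]; the absolute mitochondrial threshold
0.08 means 8%. Zero-count cells get −inf log metrics and are always
removable.

Outlier calls are MAD-based (constant 1.4826, configurable); a zero MAD
disables the call except for values beyond a small epsilon of the
median, so constant vectors are outlier-free but a lone extreme among
ties is still caught. The filter sets:

- `default`: excluded when ≥ 2 of — log10 counts (upper 2.5 / lower 5
  MADs), log10 features (2.5/5), top-20 fraction (5/5), featcount_dist
  (5/5), mito (> 2.5 MADs **and** > 0.08).
- `stringent`: same calls, any one suffices (so its exclusions are a
  superset of `default`'s by construction).
- `lenient`: ≥ 2 calls at 5 MADs; mito > 3 MADs and > 0.08.
- `veryStringent`: any single two-sided 2-MAD call on counts, features,
  mito or top-20 fraction; no absolute mito floor here, as none is part
  of this set's definition.

Datasets without mitochondrial annotation skip the Mt criterion with a
warning. Cluster-wise filtering pre-clusters (log-normalize → top-1000
variable genes → 10-PC PCA → SNN graph → modularity clustering) and
applies a set within each cluster of ≥ 3 cells, excluding the union —
this spares genuine subpopulations whose QC profile is merely shifted.
The multivariate filter standardizes covariates robustly, fits a
minimum-covariance-determinant estimate and excludes cells beyond the
χ² 0.999 quantile of robust Mahalanobis distance, falling back to
per-axis 3.5-MAD calls if the covariance is (near-)singular.

## Doublet detection

Artificial doublets are raw-count sums of two cells from different
pre-clusters (uniform over cluster pairs; unscaled, since real doublets
are sums of transcript pools), 1:1 with real cells by default; the
meta-cell option adds 25% composites of a cluster-mean profile plus a
cell from another cluster, emulating triplets. Real and artificial cells
are embedded jointly (log-normalize, top-1000 variable genes, 10 PCs);
a cell's raw score is the artificial fraction `p` among its k = 20
nearest neighbors, normalized by the realized artificial fraction `r` as
`(p/r) / (p/r + (1−p)/(1−r))`, so 0.5 means "neighborhood matches the
global composition". Calling: admissible call counts span
`(expected_rate ± rate_uncertainty) · n`; within that band the threshold
sits at the largest drop between consecutive sorted scores. Zero
uncertainty reduces to the exact expected-count quantile; constant
scores degrade to the expected count in index order. Homotypic doublets
are largely invisible to any count-based scorer; the suite asserts this
directionally rather than hiding it.

## Feature ranking and PCA

`standardized_variance` fits a kernel-weighted local-linear trend of log
variance on log mean, standardizes each gene by the fitted sd (clipped
at √n) and ranks by the variance of the standardized values, so ranking
is not driven by expression level. `deviance` is the per-gene binomial
deviance under a constant-share null computed on raw counts,
`D_g = 2 Σ_i [y ln(y/(n_i π̂_g)) + (n_i−y) ln((n_i−y)/(n_i(1−π̂_g)))]`
with `π̂_g = Σ y / Σ n` and `0·ln 0 ≡ 0` — the binomial approximation to
the multinomial null. PCA is a truncated SVD of the gene-centered scaled
matrix; the weighted embedding (default) scales scores by singular
values, the unweighted one returns unit-variance scores; signs are fixed
by making the largest-magnitude loading positive.

Neighbor graphs are built on the kNN edge set (exact k-d tree by
default; approximate search via pynndescent behind the `exact=False`
flag): `knn` uses 1/(1+distance) weights, `snn_jaccard` the Jaccard
overlap of endpoint neighborhoods (each including its point), and
`snn_rank` the weight `k − r/2` with `r` the smallest rank-sum over
shared neighbors — computed on kNN pairs only, the convention of the
field's graph builders. Community detection is a pluggable contract;
shipped methods are resolution-parameterized modularity (Leiden),
random-walk (walktrap) and greedy modularity, all seeded.

## Truth-based metrics

Variance explained is the one-way ANOVA `R² = SS_between / SS_total` per
gene or component; zero-variance rows give 0. Deviance explained fits,
per gene, NB GLMs with log link — reduced: intercept + log-library
offset; full: + subpopulation factor — with the dispersion estimated
once by 1-d maximum likelihood on the reduced model's Poisson means and
held fixed for both fits, guaranteeing nestedness;
`(dev_r − dev_f)/dev_r` is clipped at 0. Treating library size as a free
coefficient instead of an offset is an option; the offset is the default
reading of "adjusting for library size". Non-convergent genes fall back
to Poisson with a log message. Covariate association of a component is
the Pearson correlation between the residuals of component ∼
subpopulation and the covariate (squared when reported as variance
explained). `ari_at_true_k` takes the *maximum* ARI among sweep members
hitting the true cluster count — the "can this configuration be coerced
into the right granularity" reading — and is missing (NaN, gray in
heatmaps) when none does.

## Dimensionality estimators

The elbow rule takes the point of the scree curve (first min(50, rank)
components) farthest from the chord between its first and last points;
ties resolve to the smallest index with a tolerance scaled to the chord
so the rule is invariant to jointly rescaling both axes. The same rule
applied to log10 permutation p-values gives the jackstraw estimate: per
permutation (default 100, fraction 0.01 of genes shuffled across cells)
the shuffled genes' absolute loadings form each component's null, and
the component p-value is a one-sided Mann–Whitney test of observed
against null loadings — a drop in significance, not a p threshold,
selects the dimensionality.

Molecular cross-validation splits every count binomially
(A ~ Bin(y, ½), B = y − A; non-integer inputs are rounded up first),
log-normalizes both halves identically, fits the PCA basis *and scores*
on half A (genes centered on A's means) and reports the mean squared
error of half B against A's rank-k reconstruction; the arg-min k is the
estimate, optionally averaged over multiple splits. Two caveats are
inherent and documented rather than patched: the halved depth biases the
estimate down, and the gamma (overdispersion) component of NB noise is
shared between halves by construction, so strongly overdispersed data
push the arg-min up — the planted-rank validation therefore uses
low-dispersion counts, where the split halves are near-independent.

## Reporting

For a variants × datasets metric matrix, entries are centered on their
column (dataset) median; the pooled MAD of all centered deviations (one
scale for the whole matrix) gives the transform
`sign(d)·sqrt(|d|/MAD)`, so a color difference means the same number of
matrix-wise MADs in every dataset. Missing entries (true k unreachable)
stay missing. Silhouettes use a sign-preserving square root. Raw values
are always written alongside the transformed ones.

## Problem sizes and numerical choices

The shipped default grid mirrors common practice: 2000 selected
features, dimensions {5, 10, 15, 20, 30, 50}, sixteen resolutions from
0.005 to 4. The validation suite runs on 600–800 genes × 1000–2000
cells with 2–5 subpopulations — sizes where every planted effect is
comfortably detectable yet the whole suite completes in well under a
minute per scenario on one core. Tolerances: MCV and truth-based
dimensionality are asserted within ±1 of the planted rank; doublet
AUROC at ≥ 0.9; table-equality checks compare everything except wall
times. Degenerate inputs are handled explicitly throughout (zero-count
cells, zero-MAD metrics, singular covariances, constant doublet scores,
single-cluster doublet generation, two-point scree curves) with the
behavior stated in each docstring.

## Known limitations

Strictly linear pipelines only (no DAGs); no cross-invocation caching
beyond the resumability log; the doublet scorer follows the described
principles (counts, pre-clustering, meta-cells, rate uncertainty) as a
documented design, not a bit-exact port of any released caller; the
deviance-explained GLM uses one documented dispersion convention rather
than a specific external package's internals; synthetic data omits the
real-data artifacts listed above, so absolute metric values on real
datasets will differ even where rankings agree.
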