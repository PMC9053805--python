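# Methods

This note documents the models, parameter choices and numerical conventions
behind `polypnet`, and what the synthetic benchmarks do and do not show.

## Cohort model and the synthetic generator

The pipeline consumes probe-level log2 intensity matrices with per-sample
phenotype (normal / polyp) and batch (source dataset) labels. The generator
(`polypnet.simulate`) emulates exactly the structure the downstream stages
assume, with one latent factor per planted module:

    x_gs = baseline_g + loading_g · f_ms + Δ_g · y_s + γ_bg + δ_bg · ε_gs

* `baseline_g ~ U(6, 12)` log2 units — the marginal scale of RMA-style
  microarray intensities.
* `f_ms = d · e · z_s + sqrt(1 − e²) · η_s` — the module factor for sample
  s, where `z` is the standardized phenotype code, `e = eigen_effect` is the
  target |correlation| between factor and phenotype, and `d = ±1` sets the
  direction (default −1: module genes higher in normal, lower in polyp,
  matching the expression pattern the pipeline is designed to find).
  `loading_g ~ U(0.7, 1.0)`. A latent-factor model was preferred over
  drawing from a fixed correlation matrix because it scales to thousands of
  genes and gives direct control of the module–trait correlation.
* `Δ_g` — planted differential-expression shift for a subset of module
  genes (`de_genes`), applied to polyp samples. With balanced phenotypes
  the module factor itself contributes `loading · d · e / sqrt(p(1−p))·p(1−p)`
  ≈ `2 · loading · d · e` log2FC, so the expected fold change of a DE gene
  is the sum of both terms; the recorded truth (`true_log2fc`) is exactly
  this expectation and defines the gene's true direction. In the reference
  configuration most DE genes are planted down (−1.5) and one gene per
  module is planted up with shift +2.5, compensating the factor's ≈ −1.1
  pull so its net fold change clears the +1 filter — mirroring the lone
  up-regulated gene among down-regulated chemokines that motivates
  direction bookkeeping.
* `γ_bg ~ N(0, batch_shift_sd²)` and `δ_bg = exp(N(0, batch_scale_sd²))` —
  additive and multiplicative batch effects per (batch, gene), i.e. exactly
  the ComBat location/scale model, so the correction stage is exercised on
  data generated under its own assumptions. Defaults 0.8 / 0.2 produce
  batch effects that visibly dominate the biology before correction.
* `ε_gs ~ N(0, noise_sd²)`, default 0.5 log2 units.

Each gene gets 1–3 probes (weights 0.5/0.3/0.2) with independent probe
noise (SD 0.1); 5% additional probes are emitted without gene annotation to
exercise the NA-drop rule. The reference conditions (`reference_config`):
2000 genes, two 50-gene modules with `eigen_effect 0.6`, 15 DE genes per
module, three batches of 40 samples, balanced phenotype, seed 7 — a
150-sample-scale multi-batch cohort scaled to 120 samples.

The weighted functional network is a planted partition: module genes form
the first communities, background genes are chunked into 50-gene
communities; within-community edges appear with p=0.3 and weights
U(0.5, 1.0), between-community edges with p=0.02 and weights U(0.05, 0.5)
(so part of the between-community noise falls under the 0.1 weight filter).
The ontology is a layered DAG per namespace (BP, MF): one branch term per
community under the root, three leaves per branch, relations 80% `is_a` /
20% `part_of` (the approximate prevalence in GO); genes annotate to a leaf
plus its branch term, staying inside their own community's branch with
probability 0.85, and 90% of genes are annotated at all. Annotating the
branch term as well as a leaf gives genes of one community a shared
functional class, which is what makes the homogeneity index informative.

What the generator does **not** emulate: probe saturation and mismatch
behavior, RMA itself, platform differences between cohorts, correlated
noise between modules, scale-free global network topology, and the
shallow/deep imbalance of real GO. Passing the recovery benchmarks
therefore demonstrates the pipeline's correctness under its own model
assumptions, not performance on real microarray data.

Seeding: one integer seed with fixed offsets per artifact (cohort +0,
network +1, ontology +2, tissue list +3, compounds +4; validation cohort
+1000), so artifacts are independently reproducible and identical
configurations produce byte-identical files.

## Preprocessing

Probes without a gene annotation are removed; each gene's expression is the
per-sample **median** of its probes; cohorts merge on the **intersection**
of gene ids (no imputation; matches a single-platform design). Batch
correction is the parametric empirical-Bayes location/scale adjustment:
method-of-moments hyperpriors, iterated gamma*/delta* updates until the
relative change falls below 1e-4 (max 100 iterations). The implementation
reproduces R's `sva::ComBat` to ~1e-14 on shared fixtures (a cross-check in
the test suite runs the R oracle directly). Phenotype is deliberately *not*
a covariate of the adjustment — with phenotype balanced across batches the
planted effect survives within a few percent; with unbalanced designs some
signal is absorbed, which is the main caveat of this configuration. A
`shrink=False` mode applies the per-batch estimates without prior
shrinkage; in that mode a pure location offset between equal-size batches
is removed exactly (the closed-form oracle used in tests). Validation
cohorts are never merged and never batch-corrected; the pipeline enforces
this by analyzing each independently.

## Co-expression stage

Unsigned network (`|cor|^β`), Pearson correlation, pairwise-complete data
required (constant genes are an error). The scale-free criterion bins
log10 connectivity into 10 bins and regresses log10 p(k) on log10 k; the
fit index is R² signed by requiring a negative slope, and the chosen β is
the smallest candidate with fit ≥ 0.8 (else the best fit, with a warning).

Module detection is average-linkage clustering of 1−TOM with a **static**
height cut (default 0.95) plus a minimum module size (default 30) — a
documented simplification of adaptive dendrogram cutting, whose
over-splitting is absorbed by the eigengene merge step. The 0.95 default
was fixed during design calibration on the reference generator: planted
branches join well below it while the diffuse background joins above ~0.97,
so the background either stays unassigned or forms one loose pseudo-module
that the module–trait filter (|r| > 0.3) then discards. Eigengenes are the
first right singular vector of the gene-standardized module submatrix,
sign-oriented to correlate positively with members; merging clusters
eigengene dissimilarity (1 − cor) at height 0.25 — i.e. correlation 0.75 —
and iterates until stable. Module–trait correlation codes normal=0,
polyp=1; a selected module with r < 0 is "up in normal / down in polyp".

## Tissue network and clustering

Edge filter keeps weight **strictly greater than 0.1** (the 0–0.1 band
read with a decimal comma); tissue filtering drops nodes absent from the
expressed-gene list, then isolates; analysis continues on the largest
connected component (ties broken by smallest node id). Selected modules
are unioned and mapped as the order-0 induced subgraph with isolates
dropped ("directly adjacent" genes only); order-1 ego expansion exists
behind `expand_neighbors` but is off by default.

MCL is implemented directly: weighted adjacency plus self-loops (loop
weight = max incident weight), column normalization, expansion (matrix
power 2), inflation (elementwise power, default 1.2), pruning below 1e-5
with renormalization, convergence when the flow matrix changes < 1e-6
(max 200 iterations; non-convergence returns the current interpretation
with a warning and a flag). Clusters are the attractor supports, with
overlapping supports merged and multiply-attracted nodes assigned to the
lowest cluster id; the result is invariant to node insertion order.
Inflation 1.2 is a very coarse granularity: on 4×25 planted-partition
graphs it merges everything, so the recovery benchmarks run MCL at 1.4
(the pipeline default stays 1.2, the operating point the analysis is parameterized for). "FN" is
implemented as Newman-style greedy modularity maximization — the method
behind that name in the cited package, although the name suggests a fuzzy
method; this ambiguity is unresolvable from the text and is resolved in
favor of the package's actual algorithm. Spectral clustering uses the
weighted adjacency as precomputed affinity with deterministic
("discretize") label assignment, seed 0; disconnected graphs are clustered
per component with k apportioned by size (largest remainder, ≥1 each).
The spectral k defaults to the MCL cluster count on the same graph (≥2) to
keep the three methods comparable.

## Scoring conventions

* **Modularity** sums over all ordered pairs including i=j with A_ii=0;
  binary adjacency by default (scoring parity across algorithms), weighted
  behind a flag. Q of the all-in-one partition is identically 0.
* **Silhouette** needs a distance the source analysis never specifies; the
  convention here is unweighted shortest-path hops with d = n (node count)
  for disconnected pairs, singletons scoring 0. A precomputed matrix
  (e.g. 1−TOM) can be supplied instead.
* **BHI** generalizes "same functional class" to "share ≥1 class" for
  multi-annotated genes; unannotated genes are excluded and clusters with
  <2 annotated genes are skipped.
* **Wang similarity** uses contribution factors 0.8 (`is_a`) / 0.6
  (`part_of`) — the method's published defaults — with S-values computed by
  max-product propagation over the ancestor closure (a Dijkstra-style
  relaxation, exact because all factors < 1) and best-match-average
  aggregation per gene pair; cluster scores are means over unordered
  annotated pairs.

## Differential expression and enrichment

"Fold change > 1.0" is read as |log2FC| > 1 on the already-log2 matrix
(2-fold linear), the standard microarray reading; the linear-ratio reading
is available by configuration. The DEG filter is strict (> and <); the
enrichment significance boundary is inclusive (FDR ≤ 0.05) — an intentional asymmetry between the two filters. "FDR" is Benjamini–Hochberg. The t-test
is Student (equal variance) by default, Welch behind a flag; zero-variance
genes get p = 1 with a warning rather than failing the cohort. The
enrichment universe is the set of genes on the analyzed expression matrix,
not the whole genome — chosen as the statistically defensible option, and configurable. The test itself is the plain
one-sided hypergeometric tail, implemented here rather than delegated.

## Submodule selection, validation, drugs

Submodules qualify with ≥10 genes and ≥1 DEG; they are ranked by the mean
of min-max-normalized (BHI, Wang-BP, Wang-MF) — an explicit, reproducible
operationalization of "pick the rows with the highest biological scores",
invariant to affine rescaling of any single metric. A biomarker is
concordant when at least one independently analyzed validation cohort
reproduces its training direction. The action-type vocabulary maps
{inhibitor, antagonist, blocker} to inhibitory and {agonist, activator} to
activating; inhibitory actions are kept for up-regulated targets and
activating ones for down-regulated targets; unknown action strings skip
the row with a warning.

## Problem sizes used in the benchmarks

The recovery and calibration benchmarks run at the reference conditions
(2000 genes × 120 samples; 4×25-node planted graphs; 2000-gene null for
p-value uniformity; 20 × 500-gene null cohorts for false-discovery
control; a 60-sample independent validation cohort). These sizes were
chosen so the planted structure is comfortably identifiable — effect sizes
at which a practitioner would consider the analysis adequately powered —
while the whole suite runs in well under a minute per benchmark.

## Known limitations

* The static cut cannot resolve nested modules of very different density
  the way adaptive tree cutting can; heavily overlapping modules merge.
* The EB adjustment without a phenotype covariate attenuates signal in
  phenotype-unbalanced batch designs.
* Dense TOM computation is O(n²) memory; ~20k genes ≈ 3.2 GB, beyond which
  block-wise computation (not implemented) would be required.
* MCL is dense-matrix; graphs beyond a few thousand nodes need a sparse
  implementation.
* Wang similarity caches per-term S-values; very deep ontologies with tens
  of thousands of terms would need an explicit traversal order instead of
  the LRU cache.
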