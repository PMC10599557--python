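# Methods

## The preserve/remove design

The pipeline asks whether a per-sample genomic score (a polygenic score for a
trait such as schizophrenia risk, with a second trait like height as negative
control) contributes to the *architecture* of a gene co-expression network, not
merely to the expression of individual genes. The device is a pair of cleaned
expression matrices per score. Each gene is fit once by ordinary least squares,

    expression ~ β₀ + β₁·score + Σ βc·covariate_c ,

with covariates of non-interest (age, sex, neuronal/astrocytic/endothelial
proportions, observed RNA quality: RIN, assigned-gene fraction, mitochondrial
rate, ancestry genomic PCs, and quality surrogate variables). The *preserve*
transform subtracts the fitted nuisance terms and keeps the intercept and
score term; *remove* additionally subtracts the score term. Because the
coefficients come from a single joint fit, two identities hold exactly and are
enforced by tests: refitting the model on a preserved matrix returns nuisance
coefficients of zero and the original score coefficient, and a removed matrix
is numerically orthogonal to the score. With two modes and four score columns
(two SNP-inclusion thresholds per trait) the adjustment stage emits eight
inputs.

Networks built from the preserved and removed matrix of one score are combined
into a *background*: each topological overlap matrix is scaled so its upper
quantile (default 0.95) matches the smaller of the two — a symmetric variant of
consensus scaling chosen so the consensus is commutative — and the background
TOM is the entrywise minimum. Co-expression that survives score removal lives
in the background; co-expression mediated by the score does not. Preserved
modules are then classified against the background modules by one-sided Fisher
tests on the gene-overlap contingency (Bonferroni across all module×background
pairs at α = 0.05 by default, Benjamini–Hochberg available): `strong` =
exactly one significant counterpart; `weak` = two or more (the module is
*fragmented*); `none` = no significant non-grey counterpart or more than half
of the module's genes in background grey ("majority" made concrete as > 50%).
The fragmentation fraction of a network is (weak + none)/total. Fragments —
the overlap gene sets of weak modules strictly larger than 20 genes — can be
exported for enrichment.

## Network construction

The weighted-network core is self-contained and deterministic. Signed
adjacency `((1 + r)/2)^β` is the default (anti-correlated genes are not
connected); Pearson correlation throughout. Topological overlap uses the
standard shared-neighbour normalisation with unit diagonal. Soft-threshold
selection tabulates the scale-free fit R² (regression of log10 p(k) on log10 k
over ten connectivity bins, negative slope required) and picks the smallest
power in 1..20 reaching R² ≥ 0.8, falling back, with a warning, to the
best-fitting power.

Module detection clusters `1 − TOM` with average linkage and cuts the tree
with a dynamic procedure (see `gscoex.treecut`): thresholds are derived from
the dendrogram's own height range; branches are accepted as modules when they
are tight and separated from their surroundings by a minimum merge-height gap,
junctions gluing two real branches are split, each module is re-cut recursively
on its own sub-dendrogram (which resolves small tight blocks sitting just under
the global noise floor), and peripheral genes are returned to grey unless they
correlate with the module core beyond the expected maximum chance correlation
among G genes at n samples, √(2·ln G / n). A module-membership filter then
greys out genes with own-module kME < 0.3 (the usual WGCNA guard), and modules
whose eigengenes correlate above 1 − merge_cut_height (default 0.25) are merged
iteratively. Both the unmerged and merged labellings are kept, since
correspondence is reported for both. Defaults follow WGCNA convention:
min_module_size 30, deep_split 2, merge height 0.25. The deliberate omission
of the PAM-like reassignment stage means borderline genes go grey rather than
to their nearest module.

Module eigengenes are first principal components of the standardized
within-module expression, sign-oriented to correlate positively with the
module's mean profile and scaled to unit sample variance. Background-network
eigengenes are computed on the elementwise mean of the preserved and removed
matrices (a symmetric choice; the background has no matrix of its own).

## Synthetic studies

The generator (`gscoex.synth`) emulates the statistical design the pipeline
assumes, with full ground truth. Defaults define the study conditions:

* 80 samples, 2000 genes, 12 modules of 150 down to 40 genes (1140 placed,
  860 pure-noise genes);
* gene–eigengene correlation 0.8 within modules (all genes alike — the
  generator plants block structure, not hub structure);
* two modules coupled to the schizophrenia-risk score at eigengene–score
  correlation 0.4; within each, half the genes (frac_gs_driven_genes = 0.5)
  load on a *score-mediated* shared factor z = 0.9·s + √(1−0.81)·ε instead of
  the module eigengene, so their co-expression travels through the score and
  dissolves under score removal — fragmentation by construction;
* four score columns, two per trait, drawn bivariate-normal with within-trait
  correlations 0.72 (risk) and 0.94 (height) and independent across traits;
* nuisance covariates with realistic structure: age ~ N(43, 15.8²), sex
  binary at 64/78 male, three cell proportions by stick-breaking with a
  dominant neuronal component, ten ancestry PCs, and a shared latent
  "degradation" axis tying RIN, assigned-gene fraction, mitochondrial rate and
  the leading quality surrogate variables together (the collinearity the
  screening stage must survive); per-gene covariate effects are mean-zero
  normal with covariate-specific scales (0.15–0.5 log-units per SD);
* residual scale noise_sd = 1 on an approximately Gaussian log-expression
  scale with baseline means ~ N(5, 1.5²). The expression scale is a modelling
  choice of this package, documented rather than inherited.

The truth record keeps the gene→module map, the gene→latent-factor map (the
score-driven subset of a coupled module is its own latent factor), the latent
time courses, the coupled-module list, and all true coefficients. Because the
score-driven subsets are genuinely distinct latent factors, partition-recovery
metrics are evaluated against the latent-factor partition.

What the generator does **not** emulate: read counts and library-size effects,
batch structure beyond the listed covariates, hub (heterogeneous-loading)
architecture within modules, correlated module eigengenes, and
ancestry-score confounding (scores are independent of the simulated PCs).
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the assumed design, not performance on any real cohort.
One practical consequence: with homogeneous loadings the planted networks are
not scale-free, so analyses of synthetic studies fix the soft power at the
conventional 6 instead of using the scale-free criterion (which is exercised
separately on hub-structured data).

## Shuffled-score null model

Internal validation shuffles the score across samples (50 times at study
scale; ensembles are reducible), re-cleans expression with each permuted
score, builds the preserved networks, averages the per-mode adjacency matrices,
and derives an *artifact background* from the averaged adjacencies by the same
consensus construction. Each shuffled network's fragmentation against the
artifact background, together with the original network's fragmentation
against its own background, enters a k-sample equality-of-proportions test
(Pearson X² on the 2×(1+k) table, df = k, no continuity correction — the
standard choice for k > 2). Per-shuffle networks reuse the originally chosen
soft power so that score shuffling is not confounded with power re-selection.
The artifact background's grey count is reported, not asserted.

### Calibration caveats (measured, not assumed)

Two statistical properties of the design surfaced during validation and are
deliberately documented rather than patched:

1. **The proportion test is conservative within an ensemble.** All 1+k groups
   of one ensemble share a single expression matrix; their fragmentation
   proportions are therefore nearly identical by construction and the
   between-group variance is far below binomial. On *independent* groups of
   the same sparsity the X² test rejects at 4–5% (4000-table simulation); on
   shared-expression ensembles at reduced scale (300 genes, 5 shuffles) the
   empirical type-I error is ≈ 0. The test is implemented exactly as
   specified; its rejections on real data should be read as strong evidence,
   its non-rejections as weak evidence.

2. **Preserve-mode cleaning inflates null ME–score correlations.** The
   preserved matrix retains each gene's *estimated* score term; with ~25
   regressors at n = 80 the estimate's overfitting noise creates an artificial
   score direction in expression space, and eigengenes of preserve-cleaned
   data correlate with the preserved score more often than chance (~18% of
   null modules at α = 0.05 in simulation, vs 5–5.4% for raw-data or
   truth-module eigengenes). The correlation machinery itself is calibrated
   (KS-uniform on directly simulated null modules); the inflation is a
   property of the preserve design and argues for interpreting marginal
   ME–score p-values cautiously and leaning on the negative-control trait.

## Convergence statistics

ME–score tables report Pearson r with two-sided p per (module, score), joined
to the correspondence pattern. Gene-set enrichment is a permutation test:
overlap of a module with a user-supplied set (GMT) versus overlaps of uniform
same-size draws from the expressed-gene universe, p = (1 + #{null ≥ obs})/(N+1),
N = 100,000 by default, seeded and bitwise reproducible (sampling is by random
keys and partial selection, chunked to bound memory). The kME-distribution
comparison between preserved and removed networks adds a two-sample
Kolmogorov–Smirnov statistic and a median shift per module as quantitative
companions to visual histogram overlap; these are extensions and labelled as
such in reports. Cross-run module overlap (intersection sizes + Fisher
enrichment + multi-set shared core) supports replication-style comparisons.

## Numerical and engineering choices

* All OLS fits are batched QR solves; rank deficiency raises an error naming
  the dependent columns.
* Variance screening is a two-step OLS incremental-R² partition (technical
  covariates + ancestry PCs first, biological covariates on the residuals;
  each covariate's fraction is its drop-one R² loss on the stage-2 input
  scale). A mixed-model partition would differ in detail; the two-step OLS
  version is deterministic and oracle-checkable. VIF uses the 1/(1−R²)
  definition with constant and perfectly collinear columns flagged as
  removable instead of raising.
* Ties: covariate selection breaks ties by column order; module names are
  assigned by decreasing size; the tree cut inherits scipy's leaf ordering.
* Degenerate inputs: an all-zero TOM yields all-grey labels with a warning;
  one-gene modules use the gene's standardized profile as eigengene with a
  warning; flat dendrograms are protected by a strictly positive gap floor.
* Determinism: there is no randomness in the network path; all stochastic
  stages (generator, permutation tests, shuffles) consume explicit seeds, and
  the pipeline derives per-stage seeds from one master seed by hashing.
* Scale: the shuffled-ensemble builder accumulates running mean adjacencies
  (memory stays at two gene×gene matrices) and refuses gene counts above a
  configurable cap unless overridden. Validation analyses use 20 full-scale
  studies (2000 genes) for recovery and 200 reduced ensembles (300 genes,
  5 shuffles) for null calibration — sizes chosen to estimate the reported
  rates with Monte-Carlo error well below the decision margins.

## Known limitations

* No PAM stage: grey is preferred over nearest-module assignment, so gene
  counts in modules run slightly lower than WGCNA with PAM on.
* The OLS cleaning has no shrinkage; with many covariates relative to samples
  the preserve-mode caveat above grows.
* Consensus is pairwise (preserved/removed); multi-set consensus is out of
  scope.
* Gene identifiers are matched as exact strings; no symbol/ID mapping.
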