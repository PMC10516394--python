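# Methods

## Inference model

Each expression feature y (n samples) is modelled as a linear function of
its prior-restricted predictors, partitioned into m groups by omics layer
(expression neighbours, CNV, methylation, covariates). The base estimator
is the sparse-group Lasso

    min_β ½‖y − Σ_l X⁽ˡ⁾β⁽ˡ⁾‖₂² + (1−α)λ Σ_l √p_(l)‖β⁽ˡ⁾‖₂ + αλ‖β‖₁,

which yields both groupwise sparsity (whole layers dropped) and
within-group sparsity. The mixing parameter α defaults to 0.5; α = 1 is
the Lasso, α = 0 the group Lasso. Networks are assembled from all models
with R² strictly greater than 0.1 (per-model, in-sample, against the
completed or mean-imputed design), taking one edge per nonzero
coefficient. Covariate (age, sex) effects are estimated in every model
but excluded from the assembled graph by default, since they are
confounder corrections rather than regulatory links. Only expression
features are used as responses; CNV and methylation features appear as
predictors, which matches how the inferred graphs are populated in
practice.

## Missing-data estimators

**knnSGLasso.** Each layer is imputed independently by feature-space kNN
(k = 10): a missing cell is the unweighted mean of the k nearest features
with an observed value in that sample, using Euclidean distance over
co-observed samples divided by the number of co-observed samples (so
distances computed over different overlap sizes are comparable). Features
missing more than `rowmax` = 50 % fall back to the per-sample mean over
observed features; cells with neither kNN donors nor a per-sample mean
fall back to the feature mean, and only when that is also empty is an
error raised. Samples missing ≥ `colmax` = 80 % of a layer are excluded
from distance computation. Feature sets larger than `maxp` = 1500 are
recursively bisected by 2-means clustering of features (a contiguous-chunk
splitter is available via `KnnConfig(split="chunk")`). In the inference
pipeline, features whose missing fraction exceeds `rowmax` are dropped
from the model specs before imputation — under block-missingness this is
what removes a substantial share of features from the resulting network.

**Stacked Lasso (SLasso/SALasso).** The D ngMICE-completed copies are
concatenated row-wise with uniform observation weights o_i = 1/D, so the
effective sample size stays n rather than nD, and a single coefficient
vector solves

    min_β 1/(2nD) Σ_d ‖y_d − X_d β‖² + λ Σ_j ŵ_j |β_j|.

Adaptive weights ŵ_j = (|β⁰_j| + 1/n)^(−γ) come from the CV-selected
non-adaptive fit; γ = ⌈2v/(1−v)⌉ + 1 with v = log p / log n (the ceiling
is guarded against floating-point noise; v ≥ 1 is an error since the
formula is undefined there).

**Grouped Lasso (GLasso/GALasso).** One coefficient vector per copy, with
the D coefficients of each covariate forming one group:

    min 1/(2n) Σ_d ‖y_d − X_d β_d‖² + λ Σ_j ŵ_j √(Σ_d β²_{d,j}),

ŵ_j = (√(Σ_d β̂⁰²_{d,j}) + 1/(nD))^(−γ), γ via v = log(pD)/log(nD).
Group soft-thresholding guarantees identical supports across the D copies
by construction; the pooled (mean) coefficient is reported for network
assembly.

**CoCoLasso / HMLasso.** Both avoid imputation by rewriting the Lasso in
second moments computed over co-observed rows (S^pair, ρ^pair; ρ^pair for
a pair (column, response) uses rows where both are observed, because
responses are themselves omics features with missingness). S^pair is
generally indefinite and is replaced by its nearest PSD surrogate — under
the elementwise max norm (CoCoLasso) or the weighted Frobenius norm
‖W∘(Σ−S^pair)‖²_F with W = R^α (HMLasso), both solved by ADMM with an
eigenvalue-clipping step. The final problem is

    min_β ½ β'Σβ − ρ^pair'β + λ‖β‖₁.

The ½ on the quadratic term is a deliberate choice: with it, the complete
-data pipeline reproduces the residual-form Lasso coefficient-for-
coefficient, which the tests assert to 1e-6. R²/RMSE for these fits are
computed against the zero-filled (mean-imputed) standardized design Z,
the object HMLasso itself introduces, since some completed design is
needed for the R² network threshold. With α = 0 (W ≡ 1) the HMLasso
covariance step coincides with the unweighted Frobenius projection, whose
closed form — eigenvalue clipping — serves as the internal correctness
oracle for the ADMM.

**ngMICE.** Multiple imputation by chained equations whose predictor set
per incomplete feature is its prior neighbourhood filtered by
pairwise-complete |Pearson r| ≥ 0.1; if fewer than k = 5 survive, the 5
most correlated features over the whole dataset are used instead. Each of
the D = 5 runs initialises missing cells by random draws from the
feature's observed values and performs 5 sweeps in fixed feature order;
each sweep refits an OLS (with a 1e-8 ridge for near-collinear predictor
sets) on rows where the target is observed and fills missing cells by
predictive mean matching with 5 donors, so every imputed value is an
observed value of the same feature. Methylation imputations are clipped
to [0, 1]. The iteration count, visit order and donor count are
implementation choices (the chained-equations literature default of 5
each); imputation draws a fresh seed per run from a spawned seed
sequence, so runs are independent but fully reproducible.

## Cross-validation protocol

All estimators share one protocol: a geometric path of 50 λ values from
λ_max down to λ_max·`lambda_min_ratio` (1e-4 for the stacked/grouped
variants, 1e-1 for the covariance-form estimators, 1e-2 for the
sparse-group Lasso), 5-fold CV with a seeded shuffle split, held-out mean
squared error (covariance-form: β'S_val β − 2ρ_val'β + mean y², the
moment-form prediction error), warm starts down the path, and ties broken
towards the larger λ (sparser model). λ_max is the smallest λ with an
all-zero solution, taken over the full data and every training fold so
the top of the grid is empty in every fit; for the sparse-group penalty
the per-group zero threshold is found by bisection on the soft-threshold
condition. HMLasso selects its weight power α ∈ {0.5, 1.0, 1.5, 2.0}
jointly with λ by the same CV (ties resolve to the earlier grid entry).

## Numerical choices

Coordinate descent runs in Gram form (numba-compiled), so a whole λ path
costs O(p²) per sweep independent of n; convergence is declared at a
maximum coefficient change below 1e-10 (1e-9 for the sparse-group
solver), with iteration caps surfaced as errors, never silenced. λ = 0
problems are solved directly by least squares. The ADMM projections use
penalty 1.0, a 2000-iteration cap and primal/dual tolerance 1e-7; the
max-norm proximal step is computed through the Moreau identity with an
exact l1-ball projection. Columns are standardized to zero mean and unit
population SD over observed entries before every fit (zero-variance
columns dropped and recorded), and coefficients are reported back on the
raw scale. Per-response CV seeds derive from a stable hash of
(base seed, method, response), so results are independent of the order
in which models are fitted and reproducible across runs.

## Synthetic data generator

The generator emulates matched triple-omics cohorts in two layer-
dimension regimes: `imbalanced` (500 genes / 30 CNVs / 80 methylation
sites, mirroring cohorts with few CNV features) and `balanced`
(200/200/200), at configurable sample size. Gene-gene prior links are
drawn with Pareto-distributed endpoint propensities (hub genes, mean
degree 3 by default); each CNV and methylation feature maps to exactly
one gene. 70 % of prior links carry a true effect — generic interactome
priors always contain links irrelevant to a given expression dataset, so
decoy edges are part of the study conditions — with effect magnitudes
uniform on [0.3, 1.0], random sign, acting on standardized predictors in
an acyclic structural model. Gene noise SDs are uniform on [0.3, 0.8];
CNVs are standard normal; methylation beta values are a logistic
transform of a Gaussian latent (respecting the [0, 1] invariant);
covariates are age ~ N(60, 10²) and sex ~ Bernoulli(0.5).

Perturbations follow the benchmark definitions: random missingness
removes exactly round(m·n_entries) observed entries per targeted layer
(fixed count, not Bernoulli-per-entry — an explicit choice where either
reading is defensible); block missingness blanks whole layers for
⌊m·n⌋ samples per layer, assigned round-robin over a seeded shuffle under
the constraint that every sample keeps at least two layers — when that
constraint makes the requested count infeasible (e.g. three layers at
m = 0.5) the achievable count is used and the shortfall logged rather
than erroring; noise adds N(0, a·σ_g²) per observed entry with σ_g
estimated from the feature's observed entries (override map available),
clipping methylation back to [0, 1]; downsampling keeps a uniform sample
subset consistently across layers.

What the generator does *not* emulate: copy-number segmentation along the
genome, probe-level methylation correlation structure, batch effects,
non-linear regulation, and missingness that depends on the unobserved
values (MNAR). Passing recovery tests on these data therefore shows the
estimators handle the stated missingness patterns on linear signal; it
does not certify performance on real cohorts where these complications
coexist.

## Benchmark harness and problem sizes

The harness runs generate → perturb → infer → evaluate from a single
config with derived seeds (suite → cell → repeat), caches the full-data
reference network per method, records per-repeat rows (nodes, edges,
median R², precision/recall/F1 against full-data and optional
stability-selected references, transitivity, mean betweenness) and
reports mean ± SD per cell; failed cells are recorded in an `error`
column and do not abort the suite. Stability selection averages
coefficients and R² elementwise over repeated fits with distinct derived
seeds (a predictor absent from a repeat contributes zero; more than 10 %
failed repeats is an error) before thresholding.

Tests and the acceptance script run at desk scale — hundreds of features
and 120–200 samples — chosen so the full suite completes on a single CPU
while keeping every per-model regression in the statistically meaningful
n > p regime that the method targets.

## Known limitations

- The max-norm ADMM can hit its iteration cap for poorly co-observed
  moment matrices; the model is then skipped with a warning, mirroring
  the known failure mode of covariance-estimation methods on layers with
  few features at high missingness.
- ngMICE draws imputations by PMM without posterior draws of the
  regression coefficients, slightly understating between-imputation
  variance.
- The eQTM baseline fits one simple regression per candidate pair; it is
  not meant for transcriptome-wide scans.
- Betweenness and transitivity are computed on the unweighted undirected
  graph; coefficient magnitudes are deliberately ignored for topology.
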