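# misonet

Prior-guided multi-omics regulatory network inference that keeps working
when the data have missing entries — or entire missing omics layers.

## The problem

Regulatory networks are commonly inferred from matched multi-omics
profiles (transcriptomics, copy-number variation, DNA methylation) by
regressing each gene's expression on a set of candidate regulators taken
from a prior-knowledge network (protein-protein interactions plus CNV and
methylation sites annotated to the gene), then assembling every reliable
nonzero effect into a multi-omics graph. Real cohorts, however, are rarely
complete: assays fail for single entries, and combined studies often
measure different layer subsets per patient (block-missingness). Classical
sparse regression silently breaks or forces complete-case analysis.

`misonet` implements the two-step prior-guided inference scheme of the
KiMONo family together with five sparse estimators that tolerate missing
data, a network-guided multiple-imputation engine, and a benchmark harness
that stress-tests all of them under controlled missingness and noise.

## The models

Every expression feature *y* is fitted against its prior-restricted
predictors, grouped per omics layer, with the sparse-group Lasso

```
min_β  ½‖y − Σ_l X⁽ˡ⁾β⁽ˡ⁾‖₂² + (1−α)λ Σ_l √p_(l) ‖β⁽ˡ⁾‖₂ + αλ‖β‖₁
```

An edge (response, predictor) enters the network when the coefficient is
nonzero and the model's R² > 0.1. Missing data are handled by one of:

| method | strategy |
|---|---|
| `knnSGLasso` | feature-space kNN imputation per layer, then sparse-group Lasso |
| `SLasso` / `SALasso` | Lasso on the row-wise stack of D multiply-imputed copies (observation weights 1/D), optionally with adaptive weights `(|β⁰_j| + 1/n)^(−γ)` |
| `GLasso` / `GALasso` | one coefficient vector per imputed copy, with a group penalty `Σ_j α̂_j √(Σ_d β²_{d,j})` that forces identical variable selection across copies |
| `CoCoLasso` | pairwise second moments `S^pair_{jk} = (1/n_jk) Σ_{i∈I_jk} X_ij X_ik`, nearest-PSD surrogate under the max norm (ADMM), then `min_β ½β'Σβ − ρ'β + λ‖β‖₁` |
| `HMLasso` | as CoCoLasso, but the PSD surrogate minimises the observation-rate-weighted Frobenius norm `‖W∘(Σ−S^pair)‖²_F`, `W = R^α`, `R_jk = n_jk/n` |

Multiple imputations come from **ngMICE**: chained equations with
predictive mean matching whose predictor set per incomplete feature is
restricted to its prior-network neighbours (|Pearson r| ≥ 0.1, top-5
fallback), which is what makes MICE tractable at omics scale.

All estimators collapse to the classical Lasso / group Lasso on complete
data — this is verified to 1e-6 in the test suite.

## Worked example

Simulate an imbalanced triple-omics cohort (500 genes / 30 CNVs / 80
methylation sites, 120 samples), remove 30 % of entries in every layer,
infer networks, and compare against the full-data network:

```
$ misonet simulate --preset imbalanced --n-samples 120 --seed 7 --out demo/data
wrote imbalanced dataset (120 samples) to demo/data

$ misonet infer --data demo/data --prior demo/data/prior.tsv \
      --method knnSGLasso --seed 1 --out demo/net_full.tsv
knnSGLasso: 527 nodes, 815 edges -> demo/net_full.tsv

$ misonet infer --data demo/missing --prior demo/data/prior.tsv \
      --method CoCoLasso --seed 1 --out demo/net_m30.tsv
CoCoLasso: 504 nodes, 672 edges -> demo/net_m30.tsv

$ misonet evaluate --network demo/net_m30.tsv --reference demo/net_full.tsv
nodes=504 edges=672 transitivity=0.0085 mean_betweenness=0.00754
vs reference: precision=0.987 recall=0.813 f1=0.892
```

Reading: at 30 % random missingness CoCoLasso keeps almost every edge it
reports correct (precision 0.99) but recovers 81 % of the full-data edges,
for an F1 of 0.89; the network shrinks from 815 to 672 edges. A few
per-gene models fail to converge at this missingness level and are
skipped with a logged warning — the covariance-estimation methods are
known to degrade this way on layers with few features.

The same pipeline is scriptable from Python (`misonet.fit_all_models`,
`misonet.assemble_network`) and the benchmark harness
(`misonet benchmark --config suite.yaml`) sweeps missingness kinds
(`single_random`, `multi_random`, `block`, `downsample`), missingness
fractions m ∈ [0, 0.5] and noise scales a per method, with per-repeat
rows and mean ± SD summaries.

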