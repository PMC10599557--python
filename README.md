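# gscoex

Do polygenic trait scores shape the architecture of gene co-expression networks?
`gscoex` implements a complete, testable pipeline for that question, built around
the *preserve/remove* design used in postmortem-brain transcriptomics: per-gene
linear models clean expression of nuisance covariates (demographics, cell-type
proportions, ancestry PCs, RNA-quality measures and surrogate variables) while a
genomic score's contribution is either **preserved** or also **removed**; WGCNA-style
weighted co-expression networks are built from both; their consensus forms a
**background** network free of the score's influence; and the divergence of
preserved modules from that background — *fragmentation* — is quantified and
validated against a shuffled-score null model.

The intended users are computational biologists analysing bulk expression cohorts
with per-sample genomic scores (e.g. schizophrenia risk and height as a negative
control, with two SNP-inclusion thresholds per trait: four score columns, eight
adjusted expression inputs).

## The method in brief

For gene *g* with expression *y_g*, score *s* and nuisance design *X*:

```
y_g = β₀ + β₁ s + X βₙ + ε          (one OLS fit per gene)
preserve:  y* = y_g − X β̂ₙ            (intercept and score kept)
remove:    y* = y_g − X β̂ₙ − s β̂₁
```

For each adjusted matrix: signed adjacency `a_ij = ((1 + cor(x_i, x_j))/2)^β`,
topological overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
average-linkage clustering of `1 − TOM`, dynamic tree cut, module eigengenes
(first PCs), eigengene-similarity merging, and module membership `kME_gm =
cor(x_g, ME_m)`. The background of a score is the quantile-scaled entrywise
minimum of the preserved and removed TOMs. Every preserved module is
cross-tabulated against the background modules and classified by one-sided
Fisher tests: **strong** (one significant counterpart), **weak** (significant
overlap with ≥ 2 background modules — fragmented), or **none** (no counterpart /
majority in background grey). Convergence statistics (ME–score correlations,
permutation gene-set enrichment with `p = (1 + #{null ≥ obs})/(N + 1)`,
N = 100,000 by default) and a shuffled-score ensemble with a k-sample
equality-of-proportions test (`X²`, df = number of shuffles) complete the
pipeline.

No real cohort is bundled; the `synth` module generates studies with the same
statistical design (≈ 78–80 samples, thousands of genes, block-correlated
modules, score-coupled modules with a score-mediated latent factor, realistic
nuisance collinearity) and full ground truth, so every stage is testable.

## Worked example

```python
from gscoex import (SimulationConfig, generate_study, fit_gene_models,
                    clean_expression, build_network, NetworkParams,
                    consensus_background, correspondence_report,
                    correlate_me_scores, BackgroundParams)

study = generate_study(SimulationConfig(seed=1))   # 2000 genes x 80 samples
fits = fit_gene_models(study.expression, study.covariates, "GS3_SCZ")
pres = clean_expression(study.expression, fits, "preserve")
rem  = clean_expression(study.expression, fits, "remove")

params = NetworkParams(power=6)
net_p, net_r = build_network(pres.data, params), build_network(rem.data, params)
bg = consensus_background(net_p, net_r, BackgroundParams(), params,
                          (pres.data + rem.data) / 2)
rep = correspondence_report(net_p.merged_labels, bg.merged_labels)
print(rep.pattern.value_counts())
print(correlate_me_scores(net_p.mes, study.covariates.data[["GS3_SCZ"]])
      .query("p_value < 0.05"))
```

Output:

```
pattern
strong    12
none       1
Name: count, dtype: int64
   module    score         r       p_value
2      M3  GS3_SCZ -0.245495  2.816896e-02
6      M7  GS3_SCZ  0.959958  7.372463e-45
7      M8  GS3_SCZ  0.256577  2.159713e-02
9     M10  GS3_SCZ  0.305871  5.794343e-03
10    M11  GS3_SCZ  0.606389  2.504131e-09
11    M12  GS3_SCZ  0.382280  4.664673e-04
```

Thirteen preserved modules are detected; twelve match a single background module
(strong), and one (M7) — the module carried by the score-mediated latent
factor — loses its background counterpart (pattern `none`: its genes drop to
background grey once the score is removed). M7's eigengene correlates with the
schizophrenia-risk score at r ≈ 0.96, and the two coupled planted modules'
remaining halves (M11, M12) at r ≈ 0.61 and 0.38 around the generator's target
coupling of 0.4. The three weak correlations near |r| ≈ 0.25–0.31 illustrate a
caveat of the preserve design discussed in `docs/methods.md`: retaining the
estimated score term makes null ME–score correlations anticonservative.

The full pipeline (screening → eight adjusted inputs → eight networks → four
backgrounds → convergence → optional null model) runs from a YAML config:

```
gscoex run --config config.yaml
gscoex report <run_dir>
```

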