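# fibromarker

Transcriptomic biomarker analysis for fibrostenotic Crohn's disease. In the
underlying study design, each patient contributes matched ileal resection
samples from three sites — the fibrotic **stricture** and the non-strictured
**proximal** and **distal** margins — and the goal is a small gene panel that
separates stricture from non-stricture tissue. `fibromarker` implements the
full analysis as a tested, reusable pipeline:

1. **Preprocessing** — TPM values are transformed to log2(TPM + 1); genes
   with a transformed value < 1 in any sample are excluded, then genes in
   the lowest decile of variance.
2. **Differential expression** — per gene, an empirical-Bayes *moderated t*:
   the per-gene variance s²_g (df_g residual d.f.) is shrunk toward a prior
   fitted across genes by moments of log s²,
   s̃² = (d₀s₀² + df_g s²_g)/(d₀ + df_g), t = Δ/√(s̃²·c), with
   Benjamini–Hochberg FDR per contrast. DEG ⇔ adjusted P < .05 and
   |log2FC| ≥ 1. The stricture-vs-proximal and stricture-vs-distal DEG sets
   are intersected with sign consistency ("overlap DEGs").
3. **PLS-DA / VIP selection** — NIPALS partial least squares on autoscaled
   expression vs the binary stricture label; genes with Variable Importance
   in Projection VIP > 1 are selected (Σ_j VIP²_j = p by construction);
   R²/Q² are reported per component from leave-one-out cross-validation.
4. **Panel classification** — a bagged random forest (500 trees) scores
   samples from a gene panel; AUC is the Mann–Whitney pair probability on
   pooled stratified-5-fold out-of-fold scores, with a stratified
   percentile-bootstrap 95% CI.
5. **Power / sample size** — expression is modelled as multivariate
   log-normal; a Cohen's-d shift (d × the gene's log-scale SD) is applied to
   a target gene (and optionally its highly correlated neighbours,
   |r| ≥ 0.8); per-replicate one-way ANOVA on the target gene yields power
   over a sample-size grid (5, 10, 15, 20, 50, 100) and the smallest n
   reaching 75% power.
6. **qPCR validation** — relative expression by 2^(−ΔΔCt) against a
   housekeeping gene and the patient's proximal-margin calibrator;
   Kruskal–Wallis across sites; medians with bootstrap CIs.

A synthetic-cohort generator (`fibromarker.synthetic`) reproduces the study
geometry — 9 patients × 3 sites, ~2,000 genes, multivariate log-normal
expression with block correlation, per-patient intercepts, and a known set
of 81 injected DEGs (64 up, 17 down) — so every stage is testable end to
end with ground truth.

## Worked example

```python
import numpy as np
from fibromarker import (CohortDesign, ContrastSpec, generate_cohort,
                         log_transform, filter_genes, moderated_t, overlap_deg)

matrix, meta, truth = generate_cohort(CohortDesign(seed=11))
filtered, report = filter_genes(log_transform(matrix))
print(report.n_input_genes, len(report.retained_genes))
r_sp = moderated_t(ContrastSpec("sp", "stricture", "proximal"), filtered, meta)
r_sd = moderated_t(ContrastSpec("sd", "stricture", "distal"), filtered, meta)
ov = overlap_deg(r_sp, r_sd)
print(ov.n_overlap, ov.n_up, ov.n_down)
```

prints

```
2000 1400
24 22 2
```

i.e. of 2,000 simulated genes 1,400 survive the filters, and 24 genes (22
up-, 2 down-regulated in the stricture) are significant with consistent
sign in both stricture-vs-margin contrasts at FDR < .05 and ≥ 2-fold
change. With nine patients and the default injected effect (1.5 log2
units over per-sample noise SD 1.0), the matched design recovers roughly a
third of the 81 injected DEGs — the overlap is conservative (its empirical
false-discovery proportion is essentially zero), which is exactly what the
power module quantifies: single-gene power rises above 75% only around
n ≈ 20 patients for effects of this size.

The same run from the shell:

```bash
fibromarker simulate --seed 11 --out cohort/
fibromarker preprocess --in cohort/expression_tpm.tsv --out filtered.tsv
fibromarker deg --in filtered.tsv --log-scale --meta cohort/metadata.tsv \
    --contrast stricture:proximal --out deg_sp.tsv
```

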