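# Methods

## Study design and data model

The pipeline targets a matched three-site design: each patient contributes
one sample from an ileal stricture and one from each non-strictured margin
(proximal and distal). Inputs are a genes × samples matrix of normalized
TPM and a sample table (sample id, patient id, site). All modelling happens
on the log2(TPM + 1) scale; base 2 was chosen (the transform's base being
otherwise a free choice) so that a fold change of 2 equals a mean log
difference of 1, which is how the DEG fold-change gate is implemented.

## Preprocessing

`log_transform` maps v → log2(v + 1). `filter_genes` first removes any gene
whose transformed value is < 1 in *any* sample (the rule is applied
literally per sample), then removes survivors in the lowest
`variance_quantile` (default 0.10) of per-gene variance; zero-variance
genes are always removed when the quantile is positive, and the
`variance_quantile=0` configuration is an exact no-op, making the filter
idempotent. The filter report accounts separately for the two rules.

## Moderated-t differential expression

For each pairwise site contrast (oriented stricture − margin, so positive
log2FC means higher in stricture), the per-gene variance s²_g on df_g
residual degrees of freedom is shrunk toward a prior by empirical Bayes
under a scaled inverse-χ² prior with hyperparameters (d₀, s₀²):

    s̃²_g = (d₀·s₀² + df_g·s²_g) / (d₀ + df_g)
    t_g  = log2FC_g / sqrt(s̃²_g · c),   p from t on d₀ + df_g d.f.

with c = 1/n_pairs for the paired design (statistics computed on
within-patient differences, df_g = n_pairs − 1) and c = 1/n_A + 1/n_B with
pooled variance (df_g = n_A + n_B − 2) unpaired. The prior is fitted by the
method of moments on log s²: with e_g = log s²_g − ψ(df/2) + log(df/2), the
excess of var(e) over the sampling variance ψ′(df/2) identifies d₀ through
the inverse trigamma (Newton iteration), and mean(e) identifies s₀².
When the excess is non-positive d₀ is flagged infinite and s₀² = exp(mean e);
the fully degenerate input (all variances identical) short-circuits to
(∞, that value). The implementation reproduces Bioconductor limma's
lmFit/eBayes to machine precision on a shared fixture (tested via Rscript).

Benjamini–Hochberg adjustment is applied across genes within each contrast
(standard cumulative-minimum step-up; ties need no special handling — tied
raw P receive equal adjusted P). A gene is a DEG iff adjusted P < α
(default .05) and |log2FC| ≥ log2(2). The signature set is the
*sign-consistent overlap*: genes DEG in both stricture-vs-proximal and
stricture-vs-distal with agreeing fold-change sign, partitioned into up-
and down-regulated.

Pairing defaults to paired-by-patient because the samples are matched
resections; the unpaired mode remains for external cohorts without matched
sampling. The fold-change gate is evaluated on log2(TPM+1) means,
consistent with the transform.

## PLS-DA and VIP selection

Gene selection regresses the binary label (stricture = 1 vs pooled margins
= 0; the margins are pooled because selection targets stricture vs
non-stricture) on autoscaled expression by univariate-response NIPALS PLS.
The algorithm is deterministic — the label vector is the starting score —
and deflates X and y per component; scores are orthogonal by construction.
Components are capped at 2 by default (n = 27), with leave-one-out
cross-validation producing Q²_a = 1 − PRESS_a/TSS per cumulative component
count and argmax-Q² as the recommended count; R² comes from the full fit
and always dominates Q². VIP_j = sqrt(p·Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a),
so mean VIP² = 1, and selection keeps genes with VIP strictly > 1
(autoscaling is what makes that threshold interpretable). Zero-variance
genes are excluded from the fit with a warning; a label orthogonal to X
yields VIP ≡ 0 with a warning. The study additionally filtered VIP-selected
genes by biological relevance — a manual literature-driven step — which the
package exposes as an explicit user-supplied panel rather than automating.

## Random-forest panel AUC

Panels are evaluated with a bagged random forest (500 trees, √p features
per split, unlimited depth — the canonical defaults, all exposed). Because
how out-of-sample scores are obtained materially changes small-n AUC, three
labelled schemes exist: pooled stratified 5-fold CV probabilities (default;
least optimistic of the common choices), out-of-bag votes, and
resubstitution (flagged optimistic). AUC is computed by average ranks
(exactly the all-pairs Mann–Whitney count with ties as half-wins), and the
95% CI by 2,000 stratified percentile-bootstrap resamples of the pooled
score/label pairs. Fold counts reduce automatically (with a warning) when a
class is too small for 5 folds.

## Power and sample-size simulation

`fit_lognormal` estimates per-gene means and the covariance of log2(TPM+1);
sampling-noise-indefinite covariances are repaired to the nearest
positive-semidefinite matrix by eigenvalue clipping at 0 (simplest
reproducible repair), with a flag. Effects are injected as Cohen's d on the
log scale: the shifted group's mean for the target gene moves by d × that
gene's log-SD — stated prominently because a d defined on the TPM scale
would differ. "Highly correlated" neighbours (|r| ≥ 0.8 on the model
correlation, configurable) are shifted too when propagation is on;
threshold 1.0 reduces to the target alone. Power at each grid n (default
5, 10, 15, 20, 50, 100 per group — the grid includes 20, the headline
sample size of the design question) is the fraction of replicates (default
1,000) in which the target gene's one-way two-group ANOVA (identical to the
pooled two-sample t: F = t²) rejects at α; the Monte-Carlo SE
√(p(1−p)/reps) is reported, and `required_n` returns the smallest grid n
reaching the target power (default 75%), or None.

Only the target gene's marginal is drawn inside `power_curve`: the readout
depends on that gene alone and marginalisation of a multivariate normal is
exact, so this is a pure vectorisation, verified against scipy's ANOVA
per replicate. The full multivariate path (correlated draws, per-variable
ANOVA sweep) is exercised by `simulate_two_groups` + `anova_sweep`.

## qPCR quantification

ΔCt = Ct(target) − Ct(housekeeping) per sample (technical replicates
averaged on the Ct scale first); ΔΔCt subtracts the same patient's
calibrator-site ΔCt; rq = 2^(−ΔΔCt), identically 1 for calibrator samples.
The calibrator defaults to the proximal margin: the source analysis does
not name one, and a within-patient calibrator mirrors the matched design
and cancels patient effects. Patients lacking a calibrator sample are
excluded per gene with a warning. Sites are compared by the tie-corrected
Kruskal–Wallis H (χ² on k−1 d.f.; all-identical values return H = 0, p = 1
by convention) and summarised as medians with seeded percentile-bootstrap
CIs (the CI method being unstated upstream, the bootstrap is the explicit
choice here).

## Synthetic cohort generator

The generator emulates the features the analysis actually relies on:
log-normal marginals (log2 values are exactly Gaussian; TPM = 2^x),
within-patient pairing via an additive per-patient intercept (SD 0.5,
log2 scale), exchangeable correlation ρ = 0.6 within contiguous 50-gene
blocks (shared block factor construction — the simplest structure that
exercises the correlated-neighbour logic of the power module), gene
baselines log-uniform on [0, 10] log2 units, and a ±1.5 log2-unit stricture
shift for 81 injected DEGs (64 up, 17 down). Injected DEGs draw baselines
from [3, 10]: a signature gene is by nature well-expressed (it must be
qPCR-quantifiable), and without this floor the <1-count filter would censor
a material fraction of the truth set by construction, confounding recovery
estimates. One master seed is split through `numpy.random.SeedSequence`
into independent streams (0: expression, 1: qPCR) so tables regenerate
independently. The real data's correlation magnitude is unknown; ρ = 0.6
is a convention and configurable.

What the generator does *not* emulate: count-level sampling noise (it
produces TPM directly), library-size artefacts (inputs are declared
normalized), gene-length effects, batch structure, and heavy-tailed
outliers. Passing recovery tests therefore demonstrate correctness of the
pipeline's statistics under its own assumptions, not robustness to real
RNA-seq pathologies.

Under the default conditions (effect 1.5 log2 units, per-sample noise SD
1.0, nine patients), the paired-difference noncentrality per contrast is
1.5/√(2/9) ≈ 3.2; after BH across ~2,000 genes, the ≥2-fold gate, and the
two-contrast sign-consistent intersection, expected recovery of the
injected DEGs is ≈ 30% — the overlap is a deliberately conservative caller
(its empirical false-discovery proportion in simulation is ~0) — while the
VIP > 1 set recovers ≳ 90% and the 8-gene panel AUC approaches 1. This
asymmetry (selection-oriented stages recover what the FDR-controlled caller
leaves behind) is the expected behaviour at n = 9, and is exactly why the
power module locates ≥75% single-gene power near n ≈ 20 for effects of
this magnitude.

## Numerical choices and problem sizes

- Inverse trigamma by Newton iteration (tolerance 1e-10 relative).
- BH ties: stable mergesort; adjusted values clipped at 1.
- P values floored at the smallest positive double before BH.
- PSD repair tolerance 1e-8 on the smallest eigenvalue.
- Test-suite simulations use 1,000–2,000 Monte-Carlo replicates and
  desk-scale cohorts (300–2,000 genes); these sizes give Monte-Carlo SEs
  well inside the asserted tolerances while keeping the default test run
  fast on a single CPU.

## Known limitations

- The moderated model assumes (approximate) normality on the log scale and
  homogeneous variance between groups; no robust/trend variant
  (limma-trend/voom-style) is provided.
- PLS-DA is strictly two-class; three-site score plots are a convenience,
  not a multi-class model.
- The power procedure addresses single-gene, unadjusted α — it does not
  model multiplicity-adjusted discovery power.
- External cohort evaluation (e.g. a GEO series) requires the user to
  export the expression table to the documented TSV shape; no downloader
  is included by design.
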