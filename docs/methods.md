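# Methods

## The screening cascade

The package tests whether cord-blood DNA methylation mediates
exposure–outcome associations using a sequential, biology-first design. The
mediator variable throughout is the **M-value residual**: array beta-values
(methylated fraction in [0, 1]) are logit2-transformed, `M = log2(β/(1−β))`,
and estimated cord-blood cell-type proportions are regressed out per CpG
(OLS with intercept, one cell column dropped to avoid the sum-to-one
singularity). Coverage QC precedes the transform: samples with <95%
non-missing CpGs are dropped, then CpGs with <70% non-missing samples, then
CpGs on sex chromosomes. Exposures and outcome scores (never methylation)
are trimmed at 4 SDs from the mean in a single pass — the rule is not
iterated; with mean and SD computed once, a second application can remove
further points, and the single pass is the deterministic reading of a
"remove extreme outliers" rule. Boundary betas are clamped to
[1e-6, 1−1e-6] before the logit, with the clamp count reported.

The cohort is split once into discovery and validation sets (default 70/30,
seeded). The discovery-size convention is round-half-up of `fraction·n`,
with an explicit `n_discovery` override for studies that fixed the count
outright rather than deriving it from the fraction. All selection happens on
the discovery set; the validation set is used only for sign-replication
refits, with no FDR and no pass/fail rule (estimates, raw p-values, and
sign-agreement flags are reported side by side).

### Stage 1 — keyword-driven universe reduction

Each outcome's keyword profile is matched against pathway text metadata
(name, description, disease, reference titles) by case-insensitive
substring. Substring rather than whole-word matching is deliberate: it is
deterministic, monotone in the keyword set (adding a keyword can only grow
the selection), and needs no tokenizer; its cost is occasional generous
matches ("neuron" inside "neuronal"), which only widen the universe.
Genes are matched between gene sets and the array manifest by symbol
equality, with no alias resolution; a CpG annotated to several genes
(semicolon dialect) is selected if *any* of its genes is selected.

### Stages 2–4 — FDR-screened regressions

All tests are Wald tests on the predictor coefficient. Model families:

* continuous outcomes (IQ-like): Gaussian, identity link, OLS, t reference;
* count outcomes (CBCL/DSM-like): NB2 negative binomial, log link, normal
  reference. Variance `μ + αμ²`; the dispersion α is estimated per fit by
  profile maximum likelihood (alternating IRLS for the coefficients with a
  bounded one-dimensional ML update of log α until the log-likelihood
  stabilises at 1e-9 relative). α and the coefficients are
  information-orthogonal, so coefficient standard errors come from the
  observed information of the coefficient block,
  `Σ μ(1+αy)/(1+αμ)² xxᵀ`. An α estimate at the lower bound is the
  Poisson special case (flagged, valid); at the upper bound the fit is
  flagged as dispersion-divergent. The fitter matches a tightly converged
  statsmodels Newton fit to ~1e-5 in coefficients; it exists in-package
  because screening runs on the order of 1e5 such models, which demands a
  ~1 ms fit.

Failed fits (rank deficiency, <20 complete cases after listwise deletion,
non-convergence) are flagged, enter their FDR family at p = 1, and never
abort the cascade; per-fit sample sizes and convergence flags are carried
into the reports and the run log.

Benjamini–Hochberg families are step-specific: stage 2 uses the outcome's
full universe of attempted tests; stage 3 uses exposures × surviving CpGs
per outcome; stage 4 uses the exposure–outcome tests actually run across
outcomes. The stage-4 convention (tests run, not outcomes × exposures in
the abstract) makes a lone surviving test's adjusted p equal its raw p,
which is the behaviour a single-survivor cascade must have to advance.
Ties in p are broken by stable sort; adjusted values are unaffected.

### Stage 5 — effect decomposition

The primary estimator is **difference of coefficients on the link scale**:
total from `Y ~ X + covs`, direct from `Y ~ X + mediators + covs`,
`IE = total − direct`. This choice is well defined for the NB log link,
where product- and difference-based definitions no longer coincide. In the
linear-Gaussian case with identical covariate sets in the mediator and
outcome models, the difference equals the sum of per-mediator products
`a_k·b_k` exactly (Frisch–Waugh), and the tests assert that identity to
1e-10. The covariate asymmetry of the screens is preserved by default
(mediator models: sex, ethnicity; outcome models: sex, ethnicity, age at
testing), so the identity is exact only when equal covariate sets are forced.
Per-mediator contributions are the products `a_k·b_k` rescaled to sum to IE.

The summary statistic is `p = |IE| / (|IE| + |DE|)` — in [0, 1] by
construction, undefined (flagged NaN) only when both effects are zero, and
invariant to positive rescaling of the exposure in the linear case.
Uncertainty comes from a nonparametric bootstrap over individuals
(default 500 resamples, percentile intervals, no stratification); BCa was
not used because percentile intervals are the simplest seeded-reproducible
choice at these sample sizes. A result with >20% failed resamples is
flagged unstable.

## The synthetic cohort generator

The generator emulates the statistical structure the cascade assumes, at the
scale of the motivating study: 341 samples (240-ish discovery), ten exposure
analytes, four outcomes (one continuous, three count), 500 CpGs by default.

* **Exposures** are log-normal; the table carries raw and log columns and
  planted effects act on the log scale. With Gaussian log-exposures and
  Gaussian CpG noise, both identity and log links are collapsible over the
  mediator, which yields closed-form truths for every screened coefficient:
  stage 3 recovers `a`; stage 4 recovers `c′ + ab`; stage 2 (which omits
  the exposure) recovers the projection slope
  `b + c′·a·σ_x² / (a²σ_x² + σ_m²)`.
* **Methylation** is generated on the M scale — bimodal per-CpG baselines
  (hypo/hyper-methylated, ±3), additive cell-composition shifts proportional
  to centred Dirichlet cell proportions (seven cord-blood cell types,
  granulocyte-dominated), planted `a·X` effects, Gaussian noise
  (σ_m = 0.25) — then mapped to beta-values by the inverse logit2. The
  preprocessing stack therefore recovers the generative scale exactly, and
  cell residualization is a testable de-confounding step.
* **Outcomes** share the linear predictor
  `intercept + covariates + b·(true M-residual) + c′·X`; continuous scores
  add Gaussian noise (IQ-like: intercept 100, σ = 12), count scores are NB2
  draws (θ = 5, intercepts 1.2–1.5, giving CBCL-like means of ~4–6 with
  variance ≈ 2× the mean). Sex and ethnicity are Bernoulli(0.5); ages at
  testing are uniform within a year of the nominal instrument age and are
  outcome-specific columns.
* **Canonical planted triangle:** a = 0.6, b = 0.7, c′ = 0.48 on the
  log-PAH → CpG → CBCL-social path, so the true mediated proportion is
  0.42/0.90 = 46.7% and the standardized indirect effect `a·b·σ_x` is 0.42.
* **Pathway fixture:** ≥20 pathways — two per outcome theme whose metadata
  contains that outcome's specific keywords, two shared neuro-development
  pathways matching every profile, and keyword-free decoys (checked at
  construction). Planted CpGs' genes are forced into a pathway matching
  their target outcome, so planted mediators are always inside the searched
  universe. The manifest maps CpGs to genes five-to-one with occasional
  two-gene annotations, autosomal chromosomes, 1-based positions.

What the generator does **not** emulate: array probe-type bias, batch
effects, detection p-values, correlated CpG blocks, non-Gaussian exposure
measurement error, or missingness patterns (missing data enter tests by
explicit injection). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
array artefacts — probe-bias correction and reference-based cell deconvolution
are upstream of this package's inputs.

## Operating characteristics (recomputed by `scripts/acceptance.py`)

The simulation studies in `epimitm.simstudy` run the real pipeline code on
generated cohorts at n = 240: coefficient recovery within 3 SEs of the
closed-form truths across seeded replicates for both families; the
full-cascade false-triple rate on all-null cohorts with every CpG in every
universe (the most adversarial family); and planted-triple recovery plus
bootstrap interval coverage of the true mediated proportion. Replicate
counts are 25–50 in the tests and the reproduction script — enough for the
binomial bounds being asserted while keeping a full run in the minutes
range on one CPU.

Two known estimator-level caveats, both visible in the simulation output:
the stage-3 slope is attenuated by roughly k/n (the cell-projection degrees
of freedom over the sample size, ~3% at n = 240) because residualization
removes the in-sample cell-correlated part of the exposure signal; and the
difference-of-coefficients indirect effect under the NB log link inherits a
small downward shift from the same source, so the mean estimated proportion
sits a few points below the closed-form 46.7% while the bootstrap interval
covers it at close to nominal rates. Neither affects the Gaussian
identities, which are exact.

## Defaults worth knowing

| parameter | default | meaning |
| --- | --- | --- |
| `alpha` | 0.05 | BH-adjusted significance threshold at every stage |
| `split.fraction` | 0.70 | discovery share; round-half-up, `n_discovery` overrides |
| `bootstrap.n_boot` | 500 | resamples (≥100 enforced) |
| `bootstrap.ci_level` | 0.95 | percentile interval level |
| `MIN_N` | 20 | fewest complete cases any single fit accepts |
| beta clamp ε | 1e-6 | logit2 boundary protection |
| NB dispersion bounds | α ∈ [1e-8, 1e4] | outside: Poisson limit / divergence flag |
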