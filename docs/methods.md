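# Methods

This note documents the statistical models in `tamtil`, the defaults of
the synthetic-cohort generator, and the design choices made where more
than one reasonable option existed.

## Deconvolution model

Bulk tumor methylation at a CpG is treated as a convex mixture of
cell-population methylomes.  If sample *j* is composed of tumor cells,
TAMs and TILs with fractions summing to one, the expected β value is

    μ_ij = f_tumor,j·β_tumor,i + f_TAM,j·β_TAM,i + f_TIL,j·β_TIL,i.

At a CpG where the immune population is unmethylated and the tumor
methylated (an immune-lineage marker), μ is *linear in the immune
fraction* with slope −Δβ.  This linearity is what justifies both the
per-CpG linear models of the discovery stage and the linear scoring rule
of the trained signature; no constraint forces predicted scores into
[0, 100], they are calibrated to the %TCC scale by the training outcome.

## Differential methylation with moderated t-statistics

Per CpG *g*, OLS regresses β on measured infiltration (continuous,
%TCC) with WHO grade as a covariate.  Grade is treatment-coded with
grade 1 as reference rather than ordinal-linear: grade effects on
methylation need not be monotone, and the dummy coding matches standard
linear-modeling practice for categorical confounders.  Age and sex are
excluded by default (available via `extra_covariates`): grade is the
dominant confounder of infiltration in this setting.

Residual variances s²_g (d = n − p df) are shrunk under the conjugate
scaled-F model s²_g ~ s₀²·F(d, d₀):

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
    t̃_g = β̂_g / (c·s̃_g),  with d₀ + d degrees of freedom,

where c = √[(XᵀX)⁻¹]_kk for the infiltration column.  (d₀, s₀²) are
estimated by closed-form method of moments on log s² using di-/trigamma
functions; a non-positive excess dispersion yields d₀ = ∞ (full pooling,
z-like statistic).  The implementation is cross-checked in the test
suite against Bioconductor limma's `lmFit`/`eBayes` on a shared fixture
(agreement to 1e-6 in t, p, d₀ and s₀²).  CpGs with exactly zero
residual variance (possible in synthetic data) are floored at machine
epsilon and flagged.

Multiple testing uses Benjamini–Hochberg (the standard reading of
"adjusted p"), via `statsmodels.stats.multitest`.

Selection takes the top K = 300 CpGs per direction by moderated t (ties
broken lexicographically on CpG id for determinism); an optional
adjusted-p pre-filter can restrict candidates first.  Only the
hypomethylated direction — β falling as infiltration rises, i.e. loci
unmethylated in the immune lineage — enters signature training: immune
hypomethylation is the direct, mixture-proportional signal, whereas
relatively hypermethylated sites mostly reflect tumor-intrinsic
methylation diluted by immune DNA and generalize poorly.  TAM and TIL
run as fully independent analyses (two designs, two selections, two
models).

## Elastic-net signatures

Training minimises the glmnet-parametrised objective

    (1/2n)·Σ_j (y_j − b₀ − Σ_i x_ij·b_i)² + λ·[α·Σ|b_i| + (1−α)/2·Σ b_i²]

with α = 0.1: mostly ridge, so groups of correlated marker CpGs are
retained together, with enough lasso to drop uninformative sites.
Numerics are delegated to scikit-learn (`ElasticNet`/`enet_path`), whose
penalty parametrisation maps one-to-one onto the above (alpha = λ,
l1_ratio = α); the test suite verifies the solutions against an
independent FISTA minimiser and the KKT subgradient conditions.

Choices that the objective does not fix:

- **λ path and rule** — 100 log-spaced values from
  λ_max = maxᵢ|⟨xᵢ, y − ȳ⟩|/(nα) down to 10⁻³·λ_max; chosen by minimum
  mean 20-fold CV error (`one_se` available).  The final model is refit
  on all training samples at the chosen λ.
- **Folds** — stratified by outcome quartile (seeded) so that 20-fold CV
  at n = 100 does not produce folds empty of high-infiltration samples;
  falls back to plain shuffled K-fold when stratification is infeasible.
- **Standardization** — predictors are standardized internally;
  coefficients are returned on the original β scale.
- **Intercept** — trained and stored explicitly.  A pure dot product of
  weights on β values cannot land on the %TCC scale; setting the stored
  intercept to 0 recovers the intercept-free scoring variant.
- **Missing probes at scoring time** — imputed with stored
  training-cohort means when ≤ 10% of the signature's CpGs are absent,
  otherwise an error listing the missing ids.  This makes signatures
  portable across array platforms with slightly different probe sets.

## Survival stratification

Cohort filters mirror survival-study practice: newly diagnosed tumors,
macroscopically complete resection (Simpson I–III or a GTR flag), and a
minimum follow-up applied to *event-free records only* — censored
patients observed for less than the threshold carry almost no
information and bias the tail, whereas excluding early *events* would
bias survival upward, so events are always retained.

Median splits label a sample `high` iff its value is strictly greater
than the cohort median (ties at the median go to `low`); the identical
rule applies to measured and predicted infiltration.  The 2×2 cross of
TAM and TIL levels gives four groups; Cox models of the combined
grouping use low TAM/high TIL (the clinically most favorable profile)
as reference.  Kaplan–Meier, log-rank and Cox (Efron ties; Breslow by
flag) are delegated to lifelines; auxiliary tests (Pearson chi-square
without continuity correction, Mann–Whitney U with an exact/asymptotic
switch at combined n = 20, Wilcoxon signed-rank) to scipy.  Hand-built
oracles in the test suite check each against first-principles
tabulations on small fixtures, plus a 200-replicate Wald-CI coverage
experiment.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: a bulk
methylation cohort with paired cytometry counts and long-term follow-up.

- **References** — a bimodal tumor baseline (mixture of Beta(1.5, 8) and
  Beta(8, 1.5), as on real arrays); per immune type, disjoint marker
  sets of 150 hypomethylated + 64 hypermethylated CpGs (≈ 70/30, so the
  direction filter has both directions to discriminate).  The
  hypomethylation effect is Δβ = 0.7, the magnitude of lineage-specific
  hypomethylation seen between sorted leukocytes and solid-tissue
  genomes in reference deconvolution panels; hypermethylated markers use
  Δβ = 0.3.
- **Fractions** — lognormal with grade-dependent medians.  TAM medians
  1.9/2.4/4.1 %TCC for WHO grades 1/2/3 and σ = 1.0, which reproduces a
  cohort span of roughly 0.01–30 %TCC; TIL median 0.64 %TCC (all
  grades) and σ = 1.4, giving a comparable span relative to its median.
  Tumor content is kept ≥ 60% (the usual inclusion criterion for bulk
  profiling) by re-drawing infeasible pairs, with proportional rescaling
  as a last resort; fractions always sum to one.
- **Noise** — observed β ~ Beta(μκ, (1−μ)κ) with concentration κ = 100
  (mean-preserving, strictly inside (0, 1); additive Gaussian noise
  would escape the unit interval).  Measured infiltration is
  100·fraction × multiplicative lognormal noise with CV 0.15 — the
  counting error of tissue cytometry is not published, so this is a
  simulator knob, not an estimate.
- **Survival** — exponential proportional hazards on z-standardized
  *log* fractions and grade (per-SD log hazard ratios; defaults
  ln 2 for TAM, −0.4 for TIL, 0.4 for grade; baseline ln 2/100 per
  month ⇒ 100-month median at the covariate mean; administrative
  censoring at 180 months plus a small random censoring hazard).
  Fractions enter on the log scale because they are lognormal: a hazard
  on the standardized raw fraction would act almost entirely through a
  handful of extreme samples and make cohort-level summaries
  non-monotone in the effect size.
- **Platform emulation** — `split_platforms` drops an independent random
  CpG subset from each half-cohort so the merge-by-intersection path is
  exercised; probe chemistry, batch and dye effects are out of scope.
- **Seeding** — a single cohort seed fans out through
  `numpy.random.SeedSequence` children per stage (references, cohort,
  survival), so each stage is independently reproducible.

What passing tests on this generator do and do not show: the simulated
mixture is exactly linear, markers are conditionally independent given
the fractions, and noise is exchangeable across samples — real data add
probe-specific artefacts, cell-type substructure (e.g. M1/M2
polarization), batch effects and copy-number distortions.  Synthetic
recovery (held-out r ≈ 0.95) is therefore an upper bound, a correctness
check of the machinery rather than a claim about clinical performance;
published applications of this design report observed-vs-predicted
correlations nearer 0.8 on real cohorts.

## Problem sizes and numerical notes

The default experiment (200 samples × 5,000 CpGs, 150 planted
hypomethylated markers per type, train/test split 100/100) is the
smallest configuration at which all pipeline stages operate in their
intended regime — top-300 selection against a ~4,700-CpG null
background, 20-fold CV at n = 100 — while a full run stays under a
minute; Monte-Carlo checks use 100–200 replicates.  Tolerances: OLS vs
normal equations 1e-10; elastic net vs independent minimiser 1e-4
(KKT 1e-6); scoring vs dense dot product 1e-12; moderated t vs limma
1e-6.  Degenerate inputs are errors, not silent results: constant
outcomes, rank-deficient designs, all-zero residual variances,
zero-variance median splits and correlation on constant vectors all
raise with a description of the offending input.

## Known limitations

- Single-task signatures; no joint TAM+TIL penalty or sum-to-one
  constraint across cell types.
- Scores are unconstrained linear predictions and can be slightly
  negative for near-zero infiltration.
- No probe-level quality weights, batch/surrogate-variable adjustment,
  or region-level (DMR) aggregation.
- Survival tooling covers right censoring only: no competing risks,
  time-varying covariates or PH diagnostics.
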