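# tamtil

DNA methylation-based deconvolution of immune-cell infiltration in bulk
tumors, with downstream prognostic stratification.

## The problem

Tumor-associated macrophages (TAMs) and tumor-infiltrating T lymphocytes
(TILs) shape tumor behavior — in meningioma, high TAM infiltration is an
adverse prognostic factor that can override the protective effect of
T cells — but counting them requires stained tissue sections.  Because
every cell type carries a characteristic DNA methylation signature that
survives in bulk tissue, infiltration can instead be *predicted* from the
methylation β values routinely generated for tumor classification.
`tamtil` implements that pipeline end to end for users who have (i) a
CpG-by-sample β matrix and (ii) cytometry-measured infiltration for a
training cohort, plus a synthetic-cohort generator with known ground
truth so that every stage can be tested without patient data.

## The method

Given β values β_ij ∈ [0, 1] (CpG *i*, sample *j*) and measured
infiltration *y_j* (% of total cell count, %TCC):

1. **Preprocess** — merge platforms by common CpG identifiers and drop
   CpGs with a missing value in any sample.
2. **Differential methylation** — per CpG, fit OLS of β on *y* with WHO
   grade as a treatment-coded covariate; shrink residual variances with
   the empirical-Bayes scaled-F prior, s̃²ᵍ = (d₀s₀² + d s²ᵍ)/(d₀ + d),
   and rank CpGs by the moderated t-statistic t̃ᵍ = β̂ᵍ/(c·s̃ᵍ) on d₀ + d
   degrees of freedom.  The prior (d₀, s₀²) comes from closed-form
   moments of log s² (cross-checked against limma's `eBayes`).
3. **Select** — take the top 300 hyper- and 300 hypomethylated CpGs and
   keep only the hypomethylated direction (immune-cell-specific
   unmethylated loci) for modeling.
4. **Train** — elastic net in the glmnet parametrisation,
   (1/2n)‖y − b₀ − Xb‖² + λ[α‖b‖₁ + (1−α)/2·‖b‖₂²], with α = 0.1 and
   λ chosen by 20-fold cross-validation; one signature per target.
5. **Score** — Score_j = b₀ + Σᵢ β_ij·wᵢ over the signature CpGs; apply
   to any cohort sharing the probes (missing probes are mean-imputed up
   to 10%).
6. **Stratify** — median-split predicted TAM and TIL scores, cross them
   into four groups (low TAM/high TIL … high TAM/low TIL), and compare
   survival by Kaplan–Meier, log-rank and Cox proportional-hazards
   models (Efron ties), after filtering to newly diagnosed, completely
   resected (Simpson I–III) patients with events or sufficient follow-up.

See `docs/methods.md` for model assumptions, parameter defaults and the
synthetic-data design.

## Worked example

```python
from tamtil import synthetic as syn, learn_signatures
from tamtil.signature import TrainingConfig, score_samples, validate_predictions
from tamtil.survival import (filter_survival_cohort, median_split,
                             combine_tam_til_groups, logrank_test, kaplan_meier)

cfg = syn.CohortConfig(n_samples=200, n_cpgs=5000, seed=1)
refs, beta, clinical, truth = syn.simulate_study(cfg)

train, test = beta.columns[:100], beta.columns[100:]
learned = learn_signatures(beta[train], clinical.loc[train],
                           training=TrainingConfig(alpha=0.1, n_folds=20, seed=1))
for target, res in learned.items():
    scores = score_samples(res.model, beta[test])
    rep = validate_predictions(scores, clinical.loc[test, f"{target}_pct"])
    print(f"{target}: {len(res.hypo_cpgs)} hypomethylated CpGs -> "
          f"{res.model.n}-CpG signature; held-out r = {rep.r:.3f} (p = {rep.p:.2g})")

cohort = filter_survival_cohort(clinical, min_followup_months=60)
tam_lvl, _ = median_split(score_samples(learned["tam"].model, beta[cohort.index])["score"])
til_lvl, _ = median_split(score_samples(learned["til"].model, beta[cohort.index])["score"])
groups = combine_tam_til_groups(tam_lvl, til_lvl)
chi2, dof, p = logrank_test(cohort, groups)
print(f"four-group log-rank: chi2 = {chi2:.1f}, df = {dof}, p = {p:.2g}")
for g, est in kaplan_meier(cohort, groups).items():
    print(f"  {g}: n = {est.n}, median = {est.median:.1f} months")
```

prints

```
tam: 300 hypomethylated CpGs -> 171-CpG signature; held-out r = 0.953 (p = 1.4e-52)
til: 300 hypomethylated CpGs -> 164-CpG signature; held-out r = 0.952 (p = 5.1e-52)
four-group log-rank: chi2 = 28.4, df = 3, p = 3e-06
  lowTAM_highTIL: n = 37, median = inf months
  lowTAM_lowTIL: n = 50, median = 105.0 months
  highTAM_highTIL: n = 50, median = 35.7 months
  highTAM_lowTIL: n = 37, median = 44.3 months
```

The held-out correlations say the signatures trained on 100 samples
track the measured infiltration of 100 unseen samples; the log-rank test
and group medians recover the planted prognostic structure (TAM harmful,
TIL protective, with the low-TAM/high-TIL group never reaching median
survival).

The same stages are exposed as a CLI:

```sh
tamtil simulate --n-samples 200 --n-cpgs 5000 --seed 1 --out-prefix cohort
tamtil dm --beta cohort.beta.tsv --clinical cohort.clinical.csv \
          --outcome tam --out-stats tam.stats.tsv --out-selected tam.cpgs.txt
tamtil train --beta cohort.beta.tsv --clinical cohort.clinical.csv \
             --cpgs tam.cpgs.txt --outcome tam --out tam.signature.tsv
tamtil score --signature tam.signature.tsv --beta cohort.beta.tsv --out tam.scores.tsv
tamtil survival --clinical cohort.clinical.csv --tam-scores tam.scores.tsv
```

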