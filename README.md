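# cohortmeta

Cross-cohort meta-analysis of diet-associated species-level genome bins
(SGBs) in the mouse gut microbiome.

Shotgun-metagenomic mouse studies of high- vs low-fat diets are small,
heterogeneous, and dominated by between-study effects: which lab ran the
experiment explains more compositional variance than the diet itself.
Single-cohort differential-abundance tests therefore generalise poorly.
`cohortmeta` implements the multi-cohort strategy that addresses this:
per-dataset covariate-adjusted effect models pooled by random-effects
meta-analysis, plus a leave-one-dataset-out (LODO) classification
harness that measures cross-study generalisation directly. It is aimed
at microbiome researchers who need these statistics as tested, reusable
building blocks, and it ships a synthetic multi-cohort generator with
known ground truth so every stage can be validated end to end without
downloading any sequencing data.

## The statistics at the core

For SGB abundance *y* (percent scale), samples are transformed with the
variance-stabilising arcsine square root, *g(y) = arcsin √(y/100)*. In
each dataset *i* an OLS model

&nbsp;&nbsp;*g(y) ~ diet + age + sex + strain + body site + antibiotics*

yields the diet-term t statistic, converted to a standardised mean
difference (Cohen's d scale) with group sizes n₁, n₂ and residual df:

&nbsp;&nbsp;*d = t (n₁+n₂) / (√(n₁n₂) √df)*,&nbsp;
*SE(d) = √( ((n₁+n₂−1)/(n₁+n₂−3)) · (4/(n₁+n₂)) · (1 + d²/8) )*

Per-study effects *dᵢ* with variances *vᵢ* are pooled by a
random-effects model: between-study variance τ² from the iterative
Paule–Mandel moment estimator (solving Σ wᵢ(τ²)(dᵢ−μ̂)² = k−1 with
wᵢ = 1/(vᵢ+τ²)), pooled effect μ̂ = Σwᵢdᵢ/Σwᵢ, SE = 1/√Σwᵢ, normal 95%
CIs, and Benjamini–Yekutieli FDR (valid under arbitrary dependence)
at q < 0.2. Continuous exposures (dietary fat percentage, diet
duration) use partial Spearman correlations pooled on the Fisher-Z
scale with variance 1/(n − #covariates − 3). Fold changes are pooled by
a fixed-effect model on log2 values (zeros replaced by 1e-4).
Beta-diversity structure is tested by PERMANOVA on Bray–Curtis
distances (exact by enumeration when feasible) and a sequential
variance partition with Ezekiel-adjusted R².

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (6 datasets, 40 samples per diet arm, 200 SGBs, 8 injected
biomarkers with true SMD 1.0):

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_cohort_overview.py
python analysis/03_binary_meta.py
python analysis/05_ml_matrix.py --seed 1
```

which prints (abridged):

```
variance partition (adjusted R2):
  dataset_id: 0.393 (p=0.005)
  diet_class: -0.014 (p=0.005)
199 SGBs analysed; 15 significant at FDR < 0.2
  15 high-fat-associated, 0 low-fat-associated
strongest effect: SGB9005 aSMD=1.15 [0.94, 1.35], q=1.04e-25, fold change 1.6
all: CV mean AUC 0.906, LODO mean AUC 0.918
known_only: CV mean AUC 0.581, LODO mean AUC 0.631
LODO gain from unknown SGBs: +0.287
```

Reading this: study identity dominates compositional variance (adjusted
R² 0.39) while diet explains almost nothing marginally — exactly the
regime where naive pooling fails and meta-analysis is needed. The
pooled models recover the 8 injected biomarkers (15 hits at q < 0.2
include all 8; the extra hits are fat-correlated features that also
separate the arms) with pooled aSMD near the injected 1.0. Because the
simulated biomarkers are all unknown SGBs, restricting the classifier
to known SGBs collapses cross-study AUC from 0.92 to 0.63 — the
full-vs-reference-only contrast the multi-cohort design is meant to
expose. `analysis/04_correlation_meta.py` and
`analysis/06_trajectories.py` add the fat-percentage/duration
correlation meta-analyses and the longitudinal phase-shift validation.

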