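# Methods

This note documents the statistical procedures implemented in
`cohortmeta`, the choices made where the design was genuinely open, and
what the synthetic validation does and does not establish.

## Data model

Profiles follow the merged-table dialect of marker-based taxonomic
profilers: rows are full taxonomy paths ending in a species-level
genome bin (SGB) token, columns are samples, values are relative
abundances in percent. An SGB is *known* (kSGB) when its species
epithet is a Linnaean name and *unknown* (uSGB) when the epithet is a
bin placeholder (`GGB…`/`SGB…`); a sidecar override table can correct
the inference. An `UNCLASSIFIED` row, when present, carries the read
mass not assignable to any SGB; it is dropped on reading and column
sums are *not* renormalised, so abundances stay comparable across
samples. Detection means abundance strictly greater than 0 throughout
(prevalence, richness); no profiler-specific detection floor is
assumed.

Feature filters mirror the reporting conventions of cross-cohort
analyses: average prevalence strictly above 20% (unweighted mean over
all analysis datasets, absent datasets contributing 0) and detection in
at least 5 datasets for the binary meta-analysis, 4 for fat-percentage
correlations, 3 for duration correlations. Filters run before the FDR
step so the correction family is exactly the reported feature set.

## Per-dataset effect models

Within one dataset, every retained SGB is modelled by OLS of its
arcsine-square-root abundance on a diet indicator (high-fat = 1, so
positive effects mean higher abundance under high fat) plus age, sex,
strain, body site and antibiotic use. Categorical covariates are
one-hot encoded against a first-level reference; covariates constant
within a dataset are dropped (with a warning) because they are
inestimable there; a design left rank-deficient after dropping raises
an error naming the collinear terms. Sex is included by default even
though it is sometimes omitted from model formulae in this literature —
the covariate list is a single argument, so either convention is one
call away. Datasets lacking two samples in either diet arm are skipped;
features with zero within-dataset variance return a missing record
rather than a fabricated t = 0.

All features share the dataset's design matrix, so the fits are
computed as one multi-response least-squares solve; t, p and df are
numerically identical to per-feature OLS (asserted against statsmodels
in the test suite) at a small fraction of the cost, which is what makes
200-replicate calibration studies practical on one CPU.

The t-to-SMD conversion uses d = t(n₁+n₂)/(√(n₁n₂)√df) with the
adjusted standard error √(((n₁+n₂−1)/(n₁+n₂−3))(4/(n₁+n₂))(1+d²/8)).
Several SE variants circulate for this estimator; this adjusted form is
centralised in `t_to_smd` so an alternative can be swapped in one
place.

## Meta-analytic pooling

Random-effects pooling follows the standard inverse-variance procedure
with Paule–Mandel τ² (iteration tolerance 1e-10, 100 iterations,
truncation at 0, DerSimonian–Laird fallback with a warning on
non-convergence — bounded behaviour on pathological inputs), normal
95% CIs and a Wald z test. Cochran's Q is reported from fixed-effect
weights. With τ² = 0 the random-effects pool reduces exactly to the
fixed-effect pool (a tested identity).

Correlations are pooled on the Fisher-Z scale with per-study variance
1/(n − #covariates − 3), the classic 1/(n−3) adjusted for the
residualised covariates, then back-transformed. Partial Spearman
itself is the Pearson correlation of rank residuals: all variables are
rank-transformed (average ranks on ties), response and exposure are
residualised on an intercept plus ranked covariates, and significance
uses the t transform with n − #covariates − 2 df (matching pingouin to
1e-10 in tests).

Log2 fold changes replace zeros with 1e-4 before the log, orient the
ratio by the sign of the pooled SMD, take the per-dataset variance as
the sum of the two group-mean variances, and pool by fixed effect. The
reported meta SE divides the fixed-effect SE by √k and the CI uses the
t quantile with k−1 df; this reporting convention is nonstandard but
implemented as printed, with `printed_se=False` restoring the standard
fixed-effect SE and normal CI.

Benjamini–Yekutieli adjustment is applied within each analysis family
(binary, fat, duration) separately at q < 0.2. Whether the per-dataset
p-values should share one correction family with the pooled p-values is
ambiguous in this literature; per-family correction of the pooled
p-values is implemented.

## Diversity and variance partitioning

Shannon (natural log), Gini-Simpson and richness operate on
renormalised detected-taxon proportions. Bray–Curtis distances come
from scipy; the undefined 0/0 case of two all-zero samples is set to 0
with a warning. PERMANOVA uses the classic among/within decomposition
of squared dissimilarities with p = (1 + #{F* ≥ F}) / (1 + B); when the
number of distinct label arrangements does not exceed the requested
permutation count (default 999) the test enumerates them all and the
p-value is exact. The variance partition is the variance-fraction part
of a distance-based RDA: sequential (type-I) increments of explained
Gower-centred sum of squares over a *user-specified* term order, with
per-term Ezekiel-adjusted R² (cumulative model df) and p-values from
permuting the term while earlier terms stay fixed. A fixed order
replaces stepwise selection deliberately: it is deterministic and
testable, and only the final importance ranking is of interest.
Exact numerical equality with a specific constrained-ordination
implementation is not claimed — tests assert rank-order behaviour
(study identity first on study-dominated data) rather than magnitudes.

## Classification harness

Random forests with Shannon-entropy impurity, 1000 trees, minimum leaf
size 5, unlimited depth and √p features per split ("maximum number of
samples per leaf" in the source convention is read as scikit-learn's
`min_samples_leaf`, the only parameter consistent with that stack).
Evaluation: stratified 10-fold CV with 10 repeats (matrix diagonal),
cohort-to-cohort transfer with 10 repeats (off-diagonals), and LODO
(bottom row). Transfers align feature spaces by union with zero fill —
absence in a relative-abundance profile is a true zero. Eligibility
keeps baseline timepoints per mouse, optionally drops antibiotic
samples, and requires at least 20 samples *per diet class* (the
ambiguous "20 from both diets" is read per-class, with a switch for the
total reading). AUC CIs use the t distribution; the matrix assembler
sets df = D·20 − 1 for D datasets, the literal form of the convention
it reproduces. Feature rankings average impurity-importance ranks over
LODO *training* models only; a test asserts that perturbing a held-out
cohort cannot move the ranking computed while it is held out. Across
repeats only the ensemble seed varies; all seeds derive from one
`RfConfig.seed` via `SeedSequence`.

## Synthetic cohorts

The generator emulates the structure of pooled mouse diet cohorts, not
any particular dataset. Reference conditions (the defaults): 6 datasets
× 40 samples per diet arm; 200 SGBs with 57% flagged unknown; 8
biomarkers with true SMD 1.0; per-dataset high-fat arms at 40–60% of
calories from fat vs 5–17% for low-fat arms (±3 points per-sample
jitter), matching the formulation spread of published cohorts; diet
duration 21–112 days; ages 56–140 days; between-study shifts of 1.5×
the residual sd so study identity dominates variance; per-feature
detection probability 0.3–0.95.

Three constructions keep the injected parameters equal to what the
pipeline estimates:

- **Effects on the analysis scale.** Diet effects are added on the
  arcsine-sqrt scale as (SMD × residual sd), so the true SMD is the
  estimand by definition.
- **Residual mass instead of re-closure.** Inverted abundances are not
  renormalised to 100% over SGBs; the remainder is an unclassified
  residual pool (as real profilers report). Closing over SGBs alone
  couples every feature to the diet-driven biomarker mass shift and
  measurably attenuates recovered SMDs.
- **Rank-scale fat correlations.** Fat percentage is bimodal within a
  dataset (two arm formulations), so fat-correlated features ride on
  within-dataset normal scores of fat with the Greiner relation
  ρ_P = 2 sin(πρ_S/6), making the requested partial *Spearman*
  coefficient the estimand.

Biomarkers default to detection probability 1 (zero-inflating them
would shrink the estimand by an unknown factor) and are flagged unknown
by default, which is what gives the known-only feature space its
handicap in the classification contrast. Longitudinal trajectories
relax biomarker latents geometrically (factor 0.4 per timepoint) toward
phase-appropriate means over an ordered N/LFD/HFD/LLFD schedule.

What the generator does not emulate: phylogenetic correlation between
features, sequencing-depth variation, compositional interactions beyond
the shared residual pool, overdispersed (non-Gaussian) latent noise,
and covariate distributions that differ systematically between arms.
Passing recovery tests therefore demonstrate the estimators are
correct and calibrated under a realistic covariance structure — not
that real mouse cohorts satisfy these assumptions.

## Validation results computed by the suite

`tests/test_acceptance.py` and `scripts/acceptance.py` compute (not
assert from constants): exact closed forms for the meta-analytic core;
brute-force-oracle agreement (τ² grid search within 2e-4; partial
Spearman rank-residualisation within 1e-10); over 200 replicate
reference studies a mean pooled SMD within [0.85, 1.15] of the injected
1.0 with 95% CI coverage in [0.90, 0.98] and average sensitivity ≥ 7 of
8 biomarkers at q < 0.2; zero discoveries in ≥ 75% of global-null
replicates; PERMANOVA null p-values uniform (fraction < 0.05 within
[0.02, 0.10] over 200 nulls) and the exact two-cluster enumeration
p = 0.1; LODO AUC ≥ 0.95 on separable cohorts, chance ± 0.1 under label
permutation, and a strict LODO drop when the (unknown) biomarkers are
excluded from the feature space. Problem sizes are chosen so the whole
suite runs in a few minutes on one CPU: replicate studies at the
reference conditions, classification checks at 200 trees with 20
samples per arm.

## Known limitations

- The LFC meta SE convention (÷√k) narrows CIs relative to the
  standard fixed-effect SE; both are available but the printed form is
  the default.
- PERMANOVA assumes exchangeability under the null; repeated measures
  are handled upstream by baseline selection, not by restricted
  permutations.
- No mixed-effects or meta-regression models; heterogeneity beyond τ²
  (e.g. moderators) is out of scope.
- The variance partition's term p-values condition on preceding terms;
  they are order-dependent by construction, like any type-I
  decomposition.
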