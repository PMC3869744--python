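# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of `cgsreclass`.

## Score construction

Dosages count the literature risk allele (0/1/2), not the minor allele, so
every association β is expected positive.  Missing dosages (the generator
default is 2.7%, completely at random) are filled with the SNP's mean
observed dosage over the combined case + control cohort — filling per
group would leak case status into the score.  Imputation preserves each
SNP's mean dosage exactly.

Weights for the weighted score are w<sub>j</sub> = β<sub>j</sub>/β̄ with
β estimated in-sample from sex/age/BMI-adjusted per-SNP additive logistic
fits.  Normalizing to mean 1 keeps the weighted score on the allele-count
scale, so unweighted and weighted scores have comparable ranges and the
unweighted score is the exact special case of equal betas.  A negative β
is treated as a misorientation error rather than silently flipped.

Scores are rounded to the nearest integer with halves away from zero;
banker's rounding would be equally defensible but the away-from-zero rule
is fixed here for bit-reproducibility.  Quartile grouping places integer
cut-points where the cumulative score distribution is nearest to
25/50/75% (ties toward the lower score); all subjects sharing a rounded
score share a quartile, so group sizes are unequal by construction and,
under heavy ties, fewer than four groups can result.

## Association testing

Per-SNP and per-score tests use maximum-likelihood logistic regression
(Newton iterations, tolerance 1e-8, ≤50 iterations, via statsmodels) under
the additive model, with Wald 95% CIs exp(β ± 1.96·se).  Separation and
non-convergence raise a fit error rather than returning unstable numbers.
Quantitative traits use OLS.

Permutation correction shuffles case/control labels and refits; the
family-wise adjusted p for predictor *i* is
(1 + #{b : max<sub>j</sub> |Z<sub>j</sub><sup>(b)</sup>| ≥ |Z<sub>i</sub>|}) / (B+1).
The max-statistic (family-wise) scheme is the headline column; a
pointwise variant is available.  The pipeline default is B = 10,000; test
and acceptance runs use smaller B (10–100) as a problem-size choice, since
the adjusted p-values there are exercised for correctness, not precision.

Heterogeneity across strata uses Cochran's Q with inverse-variance weights
and I² = max(0, (Q−df)/Q); interaction uses the Wald test of the
score-by-stratum product term.  The score-distribution comparison uses the
classical pooled-variance Student's t-test.

The two-sided exact Hardy-Weinberg test conditions on the allele margins
and sums the probabilities of all heterozygote counts whose probability
does not exceed the observed count's (no mid-p).  Probabilities are
computed by the stable two-directional recurrence anchored at the mode;
tests verify exact agreement with rational enumeration for every
configuration with n ≤ 50.  QC (call rate > 0.95, control HWE P > 0.01)
flags SNPs rather than dropping them, and HWE pools all controls; a
per-subcohort option exists.

## Risk prediction and NRI

Three in-sample models (no cross-validation, matching the emulated
analysis): clinical (sex, age, BMI), score only, clinical + score.  All
share the prevalence adjustment log[ρ(1−ρ)⁻¹ · n<sub>ctrl</sub>/n<sub>case</sub>]
with default ρ = 0.10; setting ρ to the sample case fraction recovers the
raw fitted probabilities exactly.  Risk categories are half-open with
inclusive lower bounds ([5%, 10%) etc.), per the conventional category
labels.  AUC is the Mann–Whitney probability with ties counted ½; its CI
uses the Hanley–McNeil asymptotic variance.

The categorical NRI is computed from paired 5×5 cross-tabulations per
status group.  The default CI is the asymptotic two-proportion formula;
the published interval for the emulated study (7.5–14.5 around 11.0) is
wider than that formula implies from the printed proportions, so a
percentile-bootstrap CI (2000 resamples within status groups, seeded) is
available by configuration and the discrepancy is noted here rather than
silently matched.

Complete-case filtering on covariates is applied before model fitting with
the exclusion count logged, mirroring the small analysis-N shortfall seen
in published reclassification tables.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes, and its
defaults are the study conditions: 5882 cases and 2569 controls (1057
adolescents, 586 adults, 926 elderly), prevalence 0.10, the 14-SNP
beta-cell-function panel with control risk-allele frequencies and allelic
odds ratios as published, and 2.7% missing dosages.

Controls draw genotypes genotype-wise from Hardy-Weinberg proportions at
p<sub>control</sub>; cases from Hardy-Weinberg proportions at
p<sub>case</sub> = p·OR/(1−p+p·OR), the frequency implied by the allelic
odds ratio.  This allelic-independence construction matches the additive
parameterization used throughout and is exactly invertible, which the
parameter-recovery tests exploit.  It implies slightly different case
genotype frequencies than a liability-threshold model would give; the
published covariate-adjusted ORs are treated as allelic ORs, which makes
the implied case allele frequencies (hence the expected case mean score,
≈7.7 vs the published 7.60) a few percent higher than the printed case
frequencies.

Covariates are drawn independently of genotype (the emulated analysis
adjusts for sex/age/BMI but posits no genotype-covariate dependence):
per-cohort normal age and BMI and Bernoulli sex with the published
means/SDs; fasting glucose normal and fasting insulin log-normal
(parameters back-calculated from published medians/IQRs) in the adolescent
and adult control cohorts only; waist tracks BMI with a sex offset; HbA1c,
creatinine and age-at-diagnosis use plausible clinical distributions.
Because case/control separation in age and BMI drives the clinical model,
the simulated clinical AUC lands at ≈0.75, matching the emulated study.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, genotype-covariate confounding (available via config in principle,
off by default), informative missingness, age-structured incidence or
future conversion of adolescent controls to diabetes (a config flag can
drop the adolescent cohort, mirroring the study's sensitivity analysis),
and family structure.  Passing tests therefore demonstrate correctness of
the estimators under the stated sampling model, not robustness to these
real-data features.

All draws come from a single `numpy` Generator stream seeded from one
integer, so identical configs and seeds reproduce cohorts bit-for-bit —
the determinism the pipeline's byte-identical-output contract relies on.

## Units and conversions

Glucose mmol/l; insulin recorded in pmol/l and converted to mU/l with the
conventional divisor 6.0 before the HOMA formulas (HOMA-IR =
FPI·FPG/22.5, HOMA-β = 20·FPI/(FPG−3.5), undefined and returned missing
at FPG ≤ 3.5); creatinine µmol/l with the 0.011 factor converting to the
mg/dl scale of the MDRD equation; eGFR ml/min/1.73 m².  Log transforms of
insulin-derived traits are natural logs.  Winsorization replaces values
beyond mean ± 4 SD (single pass, pre-replacement moments, per stratum).
Central obesity: waist ≥ 90 cm male / ≥ 80 cm female; overweight:
BMI ≥ 25 kg/m² — boundaries inclusive.

## Problem sizes in the test suite

Monte-Carlo tests state their sizes explicitly as the package's chosen
conditions: per-SNP OR recovery uses 100 replicates at the full study
sample sizes; null calibration of the interaction and NRI tests uses 200
replicates at n = 4000 and n = 2000 respectively; confidence-interval
coverage under OR = 1 uses 200 replicates at n = 600.  Pipeline
determinism and CLI tests run scaled-down cohorts (hundreds of subjects,
B ≤ 20 permutations) since they check bookkeeping, not precision.

## Known limitations

* No LD-aware scoring or external GWAS-catalog weights; weights always
  come from the analysis cohort, so they are mildly overfit in-sample.
* The NRI z-test is asymptotic; in small samples its type-I error drifts
  above nominal (the null-calibration test bounds it at n = 2000).
* The VCF dialect is read-only and GT-based; the primary interchange
  format is the TSV dosage table.
* In-sample AUC and NRI are optimistic relative to external validation; a
  cross-validation mode is deliberately out of scope to match the emulated
  analysis.
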