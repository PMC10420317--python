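# Methods

## CERT1 scoring

The score sums six quartile-membership subscores: the plasma
concentrations of Cer 16:0, Cer 18:0 and Cer 24:1, and the three ratios
of Cer 16:0, Cer 18:0 and Cer 24:1 to Cer 24:0.  Cer 24:0 is measured but
contributes only as the ratio denominator; six components is the only
reading consistent with a 0–12 total at 0/+1/+2 points per component.

Two conventions are deliberately fixed because the verbal scoring rule
does not determine them:

* **Tie handling.**  Quartile membership uses half-open intervals:
  `[Q2, Q3)` earns +1, `[Q3, ∞)` earns +2.  A value exactly at the 75th
  percentile therefore belongs to the fourth quartile.  This is
  deterministic and total on the reals.
* **Quantile estimator.**  Cut-offs are linear-interpolation quantiles of
  the order statistics (the common default in scientific software); the
  estimator is configurable in `fit_quartile_reference`.

The reference population defaults to the analyzed cohort itself, pooled
across groups — the natural choice for a self-contained cross-sectional
study.  A `QuartileReference` can also be serialized and reused so new
individuals can be scored against a frozen population.  Whether the
original clinical score used fixed derivation-cohort cut-offs is not
documented in our sources; external tables cover that use case.

A useful structural consequence of self-referencing: on a tie-free cohort
with n divisible by 4, exactly n/2 subjects lie at or above each median
and n/4 at or above each Q3, so every subscore averages exactly 0.75 and
the cohort mean CERT1 is exactly 4.5.  The test suite exploits this as an
exact identity.

## Clinical scores

**HOMA-IR** converts glucose with the exact molar factor 1/18.016
(mg/dL → mmol/L) rather than the rounded 0.06 sometimes quoted in assay
documentation; the rounded factor would bias HOMA-IR by ~8% and is kept
only behind `convert_glucose(..., rounded=True)` for replication work.

**Metabolic syndrome** defaults to a plain ≥3-of-5 rule over abdominal
obesity (Europid waist cut-offs 80/94 cm F/M), triglycerides ≥ 150 mg/dL,
HDL-C < 50/40 mg/dL F/M, blood pressure ≥ 130/85 mmHg, and fasting
glucose ≥ 100 mg/dL, with any specific treatment satisfying its
criterion.  The canonical IDF variant — central obesity mandatory plus
≥ 2 of the remaining 4 — is available via
`MetSThresholds(rule="idf_central_obesity_mandatory")`.  All cut-offs are
configurable; ethnicity-specific waist thresholds can be substituted.

**Framingham 2008 general-CVD risk** uses the published sex-specific Cox
coefficients over ln(age), ln(TC), ln(HDL-C), ln(SBP) (separate
coefficient under antihypertensive treatment), smoking and diabetes:
risk = 1 − S0(10)^exp(LP − mean LP).  The coefficient table ships as a
checksummed CSV; a test reproduces the source publication's worked
example (10.48% for a 61-year-old female smoker, TC 180, HDL 47,
untreated SBP 124) and a hand-computed male profile, so any accidental
edit of the table fails loudly.

**Vascular age** inverts the risk curve of an "all-normal" subject
(non-smoker, non-diabetic, untreated, TC 160 mg/dL, HDL-C 50 mg/dL, SBP
110 mmHg — configurable via `NormalProfile`) by Brent root-finding on age
to 0.1-year tolerance.  The search bracket [5, 130] years intentionally
exceeds the model's published 30–74 validity range: young, low-risk
cohorts produce vascular ages well under 30, which requires extrapolating
the risk curve.  Risks outside the achievable range are clamped to the
bracket end and flagged.  The subject-level API warns on out-of-range
ages; the batch pipeline extrapolates silently.

## Statistics battery

* **Group tests**: Kruskal–Wallis with tie correction; Dunn's pairwise
  z-tests on pooled mid-ranks with the matching tie term.  Pairwise
  p-values are Bonferroni-adjusted across the three group pairs by
  default (`holm` and `none` available); the post-hoc procedure itself
  does not prescribe an adjustment.  Cohorts where a variable is constant
  are reported as degenerate with H = 0, p = 1.
* **Regressions**: OLS with intercept; outcomes are the four ceramides,
  three ratios and CERT1; predictors are WC, SBP, DBP, HOMA-IR, HDL-C,
  TG and CRP (both pressures included).  Rank-deficient designs raise,
  naming the collinear predictors.
* **Rank ANCOVA**: "nonparametric ANCOVA" is not a single method; the
  default realization is Conover–Iman-style rank transformation — outcome
  and covariates replaced by pooled mid-ranks, then
  `rank(y) ~ group + rank(covariates)` by OLS with treatment coding
  against the normal-weight reference; each group dummy's t-test is the
  adjusted contrast.  Quade's variant (group comparison on the residuals
  of rank(y) on rank(covariates)) is available via
  `AnalysisConfig(ancova_method="quade")`.  With strong, near-separating
  covariates the two variants can disagree on borderline contrasts;
  adjusted results should be read qualitatively (significance pattern),
  not as precise p-values.
* **Association**: Spearman rho with tie-corrected p, reported together
  with an ordinary least-squares line of y on x (descriptive, as risk
  scores are conventionally summarized by such equations).
* **Contingency**: the 3×4 group-by-risk-category table keeps all four
  categories as columns even when empty, so df is always 6; empty columns
  contribute nothing to the Pearson statistic.  When any expected count
  falls below 5, the p-value switches to a seeded Monte Carlo permutation
  estimate of the exact conditional test (no closed-form exact test
  exists for r×c tables in our dependency set); the method used is
  recorded in the result and the whole pipeline stays deterministic given
  its configuration.

`run_full_analysis` chains the stages in a fixed order and records a
stage that cannot run on the given cohort (e.g. group tests on a
single-group cohort) under `stage_errors` instead of aborting, so partial
cohorts still yield scoring output.

## Synthetic cohorts

The generator exists because the subject-level data behind the three-group
summaries (normal weight n=30, obese MetS− n=24, obese MetS+ n=30; 84
subjects) are not public.  It emulates:

* **Marginals** — every positive analyte is lognormal with
  `mu = ln(median)`, `sigma = ln(Q3/Q1)/1.3490`, fitted to the packaged
  summary table.  The fit matches the median and the quartile *ratio*
  exactly; when the printed quartiles are asymmetric about the median in
  log space the individual quartiles deviate (reported by
  `quartile_fit_deviation`), so the simulated IQR *difference* can differ
  from the printed one by several percent for tight, skewed summaries
  such as waist circumference.  Age uses a normal truncated to the
  printed IQR bounds.  A printed lower quartile of 0 (CRP in lean
  subjects — values censored at the assay detection limit) is floored to
  0.03 mg/dL, the assay sensitivity, before fitting.  Blood pressures are
  rounded to the 5-mmHg reporting grid.
* **Dependence** — a Gaussian copula over the latent normals, with target
  Spearman correlations mapped through ρ = 2·sin(π·ρs/6) and repaired to
  the nearest positive semi-definite matrix by eigenvalue clipping.
  Defaults: 0.4 between each of {Cer 18:0, Cer 24:1} and each of
  {WC, insulin, CRP}; 0.3 among the clinical trio; −0.3 between Cer 24:0
  and WC; zero elsewhere.  These are invented calibration values chosen
  to embody the qualitative association pattern the analysis is meant to
  recover, not measured correlations.  HOMA-IR is never simulated — it is
  derived from simulated insulin and glucose, so insulin carries the
  insulin-resistance dependence; likewise the ratios are always computed
  from the simulated concentrations.
* **Fixed counts** — group sizes, sex splits (19F/11M, 18F/6M, 19F/11M)
  and smoker counts (7, 9, 9) are assigned exactly, in a seeded random
  order.  Treatment and diabetes prevalences default to zero: the study
  population excluded medicated or diseased participants.

What the generator does **not** reproduce: the true joint covariance of
ceramides and clinical variables (unknown), measurement error and assay
CVs, within-subject correlation of repeated BP readings, or the exact
regression coefficients and correlation magnitudes of the real cohort.
Passing pipeline tests on synthetic cohorts therefore demonstrates that
the machinery recovers patterns planted under the documented dependence
model — not that the real-world effect sizes are reproduced.

A known consequence of the summary-calibrated design: waist
circumference, HOMA-IR and CRP all separate the groups strongly, so in a
pooled 84-subject sample they are heavily collinear.  Their *partial*
regression coefficients against CERT1 share one between-group signal, and
per-covariate significance replicates in only a minority of simulated
cohorts even though the score itself separates groups essentially always.
Covariate-adjusted contrasts inherit the same sensitivity; the Quade
variant is noticeably more conservative than the rank-linear default
there.

## Problem sizes and determinism

Simulation-based tests use 100 seeded replicates of the 84-subject
design; calibration checks use single groups of 10,000; the scorer/oracle
equivalence sweep uses 1,000 random cohorts of 8–200 subjects.  All
randomness flows through `numpy.random.default_rng` seeded per test or
derived via `SeedSequence.spawn`, so every reported number is
reproducible bit-for-bit; hypothesis runs derandomized.  The acceptance
script derives three independent child seeds from its `--seed` argument.

## Known limitations

* The CERT1 reference defaults to study-internal quartiles; scores are
  not comparable across cohorts unless an external reference table is
  shared.
* Framingham risk extrapolated below age 30 is outside the model's
  validated range and should be treated as a ranking device, not a
  calibrated probability — vascular age inherits this caveat.
* The metabolic-syndrome classifier implements threshold rules only; it
  does not model medication use beyond the boolean treatment flags.
* The Monte Carlo contingency fallback estimates the exact p-value to
  Monte Carlo error (~1/√permutations); raise `mc_permutations` for
  publication-grade p-values near a decision boundary.
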