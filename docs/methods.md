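# Methods

## Scope and model

The package analyses cross-sectional associations between four folate/B12
biomarkers (RBC folate, serum total folate, 5-methyltetrahydrofolate,
vitamin B12) and four cognitive scores (CERAD word learning 0–30, CERAD
delayed recall 0–10, Animal Fluency, Digit Symbol Substitution 0–133) in
an elderly cohort, under the working hypothesis of an inverted-U
dose–response: cognition improves with biomarker concentration up to a
change point and declines beyond it.

All regression models are ordinary least squares with Gaussian errors;
the profile log-likelihood of a fit with residual sum of squares RSS is
`ll = −(n/2)(ln(2π·RSS/n) + 1)`, so likelihood-ratio statistics reduce to
`LR = n·ln(RSS_reduced/RSS_full)` and are referred to the χ² distribution
with df equal to the parameter-count difference. p-values are two-sided
with a flat 0.05 significance rule and no multiplicity correction across
the 16 marker × test combinations — the analysis is descriptive, and a
correction would change which combinations are flagged, not the fitted
curves.

### Restricted cubic splines

The exposure enters as a 3-knot restricted cubic spline, knots at the
empirical 10th/50th/90th percentiles (linear interpolation of order
statistics; the quantile rule is fixed and documented because knot values
feed the reported basis). With 3 knots the basis has one linear and one
non-linear column,

```
R(x) = [(x−t1)₊³ − (x−t2)₊³·(t3−t1)/(t3−t2) + (x−t3)₊³·(t2−t1)/(t3−t2)] / (t3−t1)²
```

(Harrell's truncated-power restricted form, normalised by (t3−t1)²), so
the non-linearity LR test has df = 1 and the fitted curve is linear
beyond the boundary knots. The adjustment set is age, age², sex,
race/ethnicity, marital status, education, smoking, drinking,
hypertension, hyperlipidemia, diabetes, eGFR, and the four folate-related
intakes (total folate, dietary folic acid, food folate, DFE). Education
is collapsed from five recorded levels to three (less than high school /
high school or GED / more than high school) in the regression models;
the five-level variable is kept for description.

Adjusted dose–response curves are population-average (g-computation):
at each grid value the exposure columns of every observed design row are
replaced and predictions averaged; because the model is linear this
equals prediction at the covariate mean row, and the 95% band is
`x̄ᵀΣx̄` by the delta method. Curves fixed at covariate means rather than
averaged are available through the same function (the two coincide for
OLS, so population-average is the reported default).

The B12-status interaction test compares the spline model plus status
main effect against the same model plus both basis-by-status product
columns (df = 2). Subgroup (stratified) fits rerun the whole pipeline
within each status stratum, recomputing knots per stratum; strata smaller
than the parameter count are skipped with a warning.

### Change-point model

Where the dose–response is non-linear, a continuous two-line (hinge)
model `y = b₀ + b₁x + b₂(x−c)₊ (+ covariates)` is profiled by exhaustive
search: candidates are the unique observed exposure values inside the
5th–95th percentile window with at least 10 observations on each side
(untrimmed extremes give degenerate one-sided fits), each candidate is
fit by least squares, and the RSS-minimising candidate wins, ties going
to the smallest candidate for determinism. Continuity at the change
point is imposed because a biological dose–response curve is continuous.
Covariates are included by default (the surrounding analyses are
adjusted); a residual-based unadjusted fit is the `covariates=None` path.
The profile search uses a direct LAPACK least-squares loop rather than a
model-object fit per candidate purely for speed; tests pin it to an
explicit normal-equations oracle.

### Clustering

The four biomarkers are min–max scaled to [0,1]
(`(v − v_min)/(v_max − v_min)`) and partitioned by K-means (Lloyd,
k-means++ seeding, `restarts` independent initialisations keeping the
best within-cluster SS; Lloyd capped at 300 iterations, tolerance 1e−6;
empty clusters are re-seeded by the solver). A large iteration budget
such as "10,000 iterations" is interpreted as 10,000 independent random
restarts, since one Lloyd run converges in far fewer steps; desk-scale
analyses default to 100 restarts, and the full budget is a parameter. K
is selected
over 2..8 by the Calinski–Harabasz score `[B/(K−1)]/[W/(n−K)]`, ties to
the smaller K.

Stability is clusterboot-style: B case-resamples with replacement at
full n, each re-scaled (min–max is a per-dataset definition; reusing the
original scaler is a toggle) and re-clustered at the same K; each
original cluster is scored by its maximum Jaccard similarity over the
resample clusters, restricted to the record ids present in the resample;
a score below 0.5 counts as a dissolution. Desk scale is B = 200 against
a full-scale 2000 — the per-cluster mean Jaccard is an average of
bounded quantities, so 200 resamples give it a Monte-Carlo SE below 0.03.

## Synthetic cohort

The generator emulates an NHANES-like population of adults aged 60+:
demographics, comorbidity flags and BMI drawn from representative
marginal frequencies of US adults aged 60+; biomarkers from a
3-component log-normal mixture (log-normal because concentrations are
positive and right-skewed). Component log-means are the natural logs of
reference marker means for the low/intermediate/high folate-B12 status
strata of such a cohort. Two geometry parameters are the package's own
choices:

* **weights (0.30, 0.65, 0.05)** — a low-status majority, an intermediate
  stratum, and a small high-B12 stratum. The smallest stratum carries 5%
  mass because a variance-ratio criterion cannot resolve a component with
  negligible mass: extracting it adds almost no between-cluster SS while
  costing a degree of freedom, so the default would otherwise not be a
  recoverable 3-component structure.
* **within-component log-SD 0.12** — stratum SDs reported from k-means
  partitions describe truncated clouds, not mixture components, and
  overstate component spread; 0.12 makes the default mixture well
  separated (pairwise centroid separations of several component SDs),
  which is the regime the clustering validation is designed to probe.
  Overlapping mixtures are a parameter change, and the stability tests
  use them as the contrast case.

Cognitive scores are built as intercept + two-line hinge contribution of
one driver biomarker per test + linear age/sex/education effects +
Gaussian noise (default residual SDs 4.5/2.0/4.5/11.0 points, in line
with observed score dispersions). Scores are not clipped to their
instrument ranges: clipping would break the exact zero-noise identities
the tests rely on, at the cost of occasional out-of-range values in
extreme tails. The low-B12 fraction (default 0.288) is injected exactly:
deficient records draw MMA above 210 nmol/L, non-deficient records draw
MMA at or below 210 and serum B12 at or above 148 by inverse-CDF
truncation, so the flagged fraction is Binomial(n, fraction) with no
leakage. Dietary intake variables carry 3% independent log-normal
tabulation noise; exact DFE identities would make the intake adjustment
block perfectly collinear, which real dietary tables are not.

The generator does **not** emulate: survey weights, strata or PSUs;
biomarker correlation beyond cluster membership; measurement error or
assay platform effects; informative missingness (missingness is MCAR,
sufficient for testing a complete-case filter). Passing tests therefore
show the estimators recover known structure under clean conditions; they
do not certify behaviour under survey design effects or differential
measurement error.

## Validation studies and problem sizes

The reference studies (in `folcog.evaluation`, rerun by
`scripts/acceptance.py` and the acceptance tests) use: 50 instances of
n = 500 for change-point/oracle equivalence; 20 cohorts of n = 2204 for
breakpoint recovery; 2000 replicates of n = 500 for LR type-I
calibration; 100 seeds for K selection; B = 200 for stability. These
sizes give Monte-Carlo error comfortably inside the acceptance margins
while keeping a full validation run under a minute.

Breakpoint recovery calibrates the noise to half the range of the hinge
contribution over the 5th–95th percentile exposure window (the candidate
window); the full-sample range is dominated by the log-normal tail and
grows with n, which would make the signal-to-noise definition unstable.
Recovery counts a success when the estimate falls within the width of
the candidate-grid decile bin containing the true change point. The
recovery cohorts use within-component log-SD 0.35 so the profiled marker
has continuous support across the hinge; the separated default would
leave a density gap at the change point.

## Numerical choices and degenerate inputs

* Perfect fits (RSS = 0) floor the variance at machine-epsilon × Var(y)
  before the log, keeping log-likelihoods finite.
* Rank-deficient designs raise an error naming the collinear columns
  (QR-pivot diagnostics); zero-variance design columns are dropped with
  a warning before fitting.
* Degenerate knots (ties from discrete exposures) and constant features
  in min–max scaling raise errors rather than producing NaN bases.
* Candidate designs that are singular at a particular change point are
  skipped and logged in the profile, not fatal.
* All cutoffs are strict inequalities as printed (<148, >210, <17, <5,
  <14, <34; eGFR < 60 excluded).
* Eligibility reasons are assigned in the fixed order age →
  completeness → eGFR → stroke, one reason per record, so audit counts
  are reproducible; the order is a package convention.
* Every stochastic operation takes an explicit integer seed; a cohort,
  a clustering, and a bootstrap are each reproducible bit for bit from
  (config, seed).

## Known limitations

* The change-point model reports no confidence interval for c beyond the
  likelihood profile; no bootstrap CI is implemented.
* Survey-weighted estimation is out of scope throughout; results on real
  survey data are unweighted complete-case analyses.
* The eligibility completeness rule is a fixed field list; cohorts whose
  completeness definition differs will reproduce different audit counts.
* B12-status classification requires both serum B12 and MMA; records
  missing either are excluded from stratified analyses rather than
  imputed.
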