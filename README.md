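# folcog

Non-linear dose–response analysis of folate and vitamin-B12 status against
cognitive performance in older adults, with unsupervised biomarker-status
subgrouping.

## The problem

Both low and high folate/vitamin-B12 status have been associated with worse
cognition in adults aged 60+, but there is no consensus threshold at which
the association turns. This package implements, as a tested and fully
reproducible pipeline, the statistical machinery such a study needs:

1. **Cohort derivation** — CKD-EPI (2009 creatinine) eGFR, a low-B12 rule
   (serum B12 < 148 pmol/L or methylmalonic acid > 210 nmol/L),
   cognitive-impairment flags (CERAD-WL < 17 and CERAD-DR < 5; Animal
   Fluency < 14; DSST < 34), dietary folate equivalents
   (DFE = food folate + folic acid / 0.6), and an eligibility filter
   (age ≥ 60, complete analysis fields, eGFR ≥ 60, no stroke history) with
   a per-record exclusion audit.
2. **Restricted cubic spline regression** — for each biomarker *x* and
   cognitive score *y*, OLS of *y* on the 3-knot RCS basis (knots at the
   10th/50th/90th percentiles) plus the full covariate set; non-linearity
   tested by the likelihood ratio `LR = n·ln(RSS_linear/RSS_spline) ~ χ²₁`;
   effect modification by B12 status tested by an LR test on the
   basis-by-status products (df = 2); adjusted curves are
   population-average with delta-method 95% bands.
3. **Change-point estimation** — where the dose–response is non-linear, a
   continuous two-line model `y = b₀ + b₁x + b₂(x − c)₊` is profiled over
   every admissible observed exposure value and the likelihood-maximising
   breakpoint `c` reported.
4. **Status subgrouping** — min–max normalisation of the four biomarkers
   (RBC folate, serum total folate, 5-methyltetrahydrofolate, vitamin B12),
   K-means with many random restarts, K selected by the Calinski–Harabasz
   score, cluster stability by bootstrap Jaccard similarity
   (clusterboot-style), and cluster phenotyping by ANOVA / chi-square.

A synthetic NHANES-like cohort generator with known ground truth (latent
3-component biomarker mixture, piecewise-linear inverted-U effects,
controlled low-B12 fraction) replaces the survey download, so every stage
is testable end to end.

## Worked example

The analysis is a sequence of numbered drivers; each reads the previous
stage's output under `results/`:

```bash
python analysis/01_simulate.py     # synthetic cohort, n = 2204, seed 0
python analysis/02_derive.py      # flags + eligibility
python analysis/03_splines.py     # RCS models, LR tests, adjusted curves
python analysis/04_changepoint.py # two-line breakpoints
python analysis/05_cluster.py     # K-means subgroups + stability
python analysis/06_report.py      # baseline tables
```

Selected output from a run at seed 0:

```
eligible: 1998 of 2204; exclusions: {'egfr<60': 134, 'stroke': 72}
low vitamin-B12 status: 549 (27.5%)

driver pair rbc_folate -> cerad_wl: true breakpoint 1400, estimated 1356
driver pair five_methyl_thf -> cerad_dr: true breakpoint 50, estimated 51.53
driver pair serum_total_folate -> af: true breakpoint 55, estimated 57.1
driver pair vitamin_b12 -> dsst: true breakpoint 500, estimated 493.3

selected K = 3 by Calinski-Harabasz score
cluster sizes: {'C1': '603 (30.18%)', 'C2': '1293 (64.71%)', 'C3': '102 (5.11%)'}
bootstrap stability (B=200): mean Jaccard per cluster [1.0, 1.0, 1.0]
agreement with latent strata (best-match): 1.000
```

The estimated breakpoints sit within a few grid points of the generating
change points; the Calinski–Harabasz criterion recovers the three latent
biomarker strata exactly, and every cluster is maximally stable under
bootstrap resampling. The same pipeline runs from a shell via the
`folcog` CLI (`folcog all --seed 0 --out results/run`), and
`analysis/07_nhanes_integration.py` documents how to point it at a real
NHANES 2011–2014 extract.

## Layout

```
src/folcog/        library: synthetic, derivations, splines, changepoint,
                   clustering, descriptives, evaluation, pipeline, cli
analysis/          numbered narrative drivers (01..07)
tests/             pytest suite incl. the validation studies
scripts/           acceptance.py
docs/methods.md    modelling assumptions, parameter choices, limitations
```
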