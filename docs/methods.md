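# Methods

`histphen` turns non-orthogonal historical phenotype records — single-plot
observations collected as a side product of genebank seed regeneration —
into quality-checked best linear unbiased estimates (BLUEs) of accession
performance. This note documents the statistical model, the numerical
choices, the synthetic-data generator that stands in for confidential
institutional data, and the known limitations.

## The model

All record-level analyses are variants of the additive mixed model

    y_ij = mu + g_i + a_j + e_ij,

where `y_ij` is the observation of accession `i` in regeneration year `j`,
`g_i` the accession effect, `a_j` the year effect and `e_ij` the residual.
Residual variances are heterogeneous across years, `e_ij ~ N(0,
sigma2_e*j)`: seasons differ in data quality, and a single pooled variance
both masks bad years and miscalibrates outlier tests. Three roles of the
model differ only in which factors are fixed:

* **BLUEs and record-level outlier testing** — accession fixed (cell
  means, so estimates live on the trait scale), year random.
* **Variance components and heritability** — accession and year both
  random, intercept fixed.
* **Year effects (YE) for the weather regression and CV** — year fixed
  (cell means), accession random.

Validation trials are analysed with the multi-factor random model
`y = mu + g_i + v_j + (gv)_ij + t_k + r_l(k) + b_m(kl) + e`, with fixed
accession effects and random environment, accession x environment, trial,
replicate-in-trial and block-in-replicate effects, each expressed as a
plain (possibly nested) grouping factor.

Heritability is reported on an entry-mean basis,

    h2 = sigma2_G / (sigma2_G + sigma2_e / n_years),

with `sigma2_e` the *average* residual variance (unweighted mean over the
year-specific variances; the record-weighted pooled variance is available
as an option) and `n_years` the mean number of years each accession was
tested.

## REML machinery

Variance parameters (one per random factor plus one per residual group)
are estimated by restricted maximum likelihood. The restricted
log-likelihood, its analytic gradient and the BLUE/BLUP solutions all come
from the mixed-model equations. Because any one-hot factor block of the
coefficient matrix is diagonal, the largest factor (typically thousands of
accession equations) is absorbed via a Schur complement; the remaining
dense system has at most a few hundred columns, so a fit with ~70 residual
variance groups takes well under a second at 5,000 records.

Optimization runs in two phases: 15 expectation-maximization iterations
(monotone in the restricted likelihood, robust far from the optimum),
then L-BFGS-B on log-variance scale with the exact gradient (convergence
when the relative likelihood change is below 1e-12 or the projected
gradient below 1e-6; a line-search stall triggers up to two EM-polish
restarts). The log parameterization enforces positivity; a variance that
ends on the floor (1e-6 of the response variance) is reported as a
boundary estimate. Non-convergence raises an error carrying the
likelihood trajectory.

Residual groups that cannot support their own variance estimate are tied
to a pooled estimate before fitting. A group qualifies when it has fewer
than 5 records or fewer than ~10 effective residual degrees of freedom
(records discounted by the leverage of their accession-side level). Below
~10 df a REML variance estimate has non-negligible mass near zero, which
would make studentized residuals in that group degenerate; the real
historical series (minimum 37 records per year) is far above this
threshold, so pooling only fires on very sparse inputs.

Studentized residuals divide each raw residual by the model-based standard
deviation of the observed-minus-fitted value, `sqrt(sigma2_e*g - h_i)`
with `h_i` the record's leverage under the fitted model. Full
case-deletion refits are not performed; the approximation error is
bounded empirically by the family-wise-error simulation below. Records
whose conditional variance is numerically zero (an accession fitted
exactly) carry no outlier information and are assigned a studentized
residual of zero.

## Three-step quality control

1. **Plausibility rules.** Configurable, applied in a fixed order (taxon,
   availability, sowing window, physiological trait bounds); each dropped
   record carries the first violated rule. The shipped winter-wheat
   defaults are FT 100-220 days after Jan 1, PH 20-200 cm, TGW 10-80 g,
   sowing Sep 1-Nov 30. These bounds are deliberately generous: the step
   removes impossibilities, not unusual phenotypes.
2. **Record-level outliers.** Two-sided standard-normal p-values of the
   studentized residuals, Bonferroni-Holm step-down at family-wise level
   alpha = 0.05 across all records of the trait, one pass (flag, remove,
   refit). The normal reference is slightly anticonservative when a
   residual group has few effective degrees of freedom; with the pooling
   rule above and realistic year sizes the measured family-wise error is
   ~5.4 %.
3. **Year-level outliers.** The coefficient of variation of the
   year-specific error variance, `CV_j = sqrt(sigma2_e*j) / YE_j` (SD
   convention; `YE_j` the fixed-year estimate of the year level, positive
   on these trait scales), is cross-checked against an aggregated weather
   index: a forward-stepwise regression of year effects on standardized
   monthly weather variables. A year is excluded only under the
   *conjunction* rule — CV above `k_cv = 2` times the mean CV of the other
   years *and* weather index more than `k_w = 3` of the other years'
   standard deviations from their mean. Statistical noise alone therefore
   never removes a season; both thresholds are configuration, not
   constants.

The stepwise entry rule admits a predictor only when its partial F-test
p-value clears a Bonferroni-corrected threshold across the candidate pool
(family-wise entry level 0.05 per step), with a hard cap of one selected
term per three years. A plain AICc criterion is available but overfits
badly when five dozen candidate month x variable predictors chase a few
dozen year effects, which both dilutes the index anomaly of a genuine bad
year and manufactures spurious R². Predictors with missing years (the
historical temperature gap of the 1990s is emulated by simply dropping
incomplete series) are excluded from the candidate set rather than
imputed.

## Synthetic data

The generator draws directly from the model above. Defaults emulate a
flowering-time-like trait of a large winter wheat collection: mu = 160 d,
sigma2_G = 15.6, sigma2_Y = 72, mean sigma2_e = 6.5 with log-normal
between-year dispersion (log-SD 0.3), 70 regeneration years, and ~4
observed years per accession so that more than 93 % of the accession x
year matrix is empty. Year effects may carry a deterministic temporal
trend and a weather-driven component (linear in standardized simulated
monthly weather); a "bad year" switch multiplies one year's residual
variance and injects an extreme weather anomaly, exercising the year-level
QC. Missingness patterns mirror regeneration practice: whole blocks of
accessions (by origin, or random blocks of the same sizes) sharing year
subsets, versus independent per-accession subsets.

Study conditions fixed in `histphen.experiments`:

* **Parameter recovery** — 1,000 accessions, mean 5 of 70 years, 20
  seeds; every component is recovered within ~2 % on average (15 % is the
  documented tolerance).
* **Family-wise error** — 160 accessions x 10 fully observed years,
  homogeneous residual, 1,000 datasets. This size is chosen so the
  normal reference is adequate (~1,400 residual df); much smaller designs
  push the realized family-wise error toward 7 %.
* **Scenario study** — the balanced 160-accession x 6-year subset with
  eight origin blocks (51, 42, 27, 15, 7, 6, 6, 6 accessions), three of
  six years observed per block, 100 replicates per scenario. Origin mean
  shifts span -18 to +12 d (between-origin variance ~72 d², i.e.
  southern landraces flowering 2-3 weeks before Scandinavian material in a
  central-European garden); the six years carry fixed residual variances
  {2, 3.5, 5, 7, 10, 14} — six seasons of distinctly different quality.
  Replicate refits use a homogeneous residual by default (a 480-record
  subset does not support six stable variance estimates); heterogeneous
  refits are a flag away.
* **Bad-year detection** — 250 accessions over 55 years (8 observed
  each), April rainfall explaining 38 % of the year-effect variance, the
  bad year with 8x inflated residual variance and an +8 SD April rainfall
  anomaly.

## What the simulations do and do not show

Passing tests demonstrate that the estimation machinery is correct and
well calibrated *under the generating model*: Gaussian effects, additive
year structure, no accession x year interaction, exact missingness
mechanisms. Real regeneration data add non-Gaussian tails, management
changes, spatial field structure and selection effects that the generator
does not emulate. Two consequences are documented rather than hidden:

* The precision penalty of Scenario A (origin-blocked regeneration)
  reproduces and collapses when origin means are equalized, confirming
  the causal mechanism; its size varies considerably between base
  datasets at 100 replicates.
* Scenario B (random blocks) is essentially as precise as fully random
  regeneration (C) under the generating model: with independent
  equal-variance residuals, which year columns a random block shares is
  statistically irrelevant, and even strong year-heteroscedasticity moves
  the SD ratio only a few percent. A substantial B-vs-C penalty observed
  on real data therefore reflects structure outside this model family.
  The recommendation that curators regenerate accessions in a random,
  unblocked fashion rests on the A-vs-C contrast, which is robust here.

Mean biases of components and BLUEs across replicates are fractions of a
percent in all scenarios, consistent with REML's unbiasedness under
missing-at-random patterns.

## Numerical and design choices worth knowing

* Duplicate (accession, year, trait) records are rejected at load (the
  model admits one residual per cell); averaging is available behind a
  flag.
* The normalized rank product (NRP) comparator scales within-year ranks
  to (0, 1] and aggregates by geometric mean (arithmetic available); it
  exists to quantify the contrast with metric-scale BLUEs, not as a
  faithful reimplementation of any specific historical software.
* BLUEs, not BLUPs, are the default deliverable: predictions shrunk
  toward the mean would be shrunk a second time by any downstream
  genomic analysis.
* Temporal trends are ordinary least-squares slopes of year effects on
  calendar year; with ~70 years the slope standard error under the
  default calibration is ~0.05 d/yr.
* All randomness flows from explicit integer seeds; identical seeds give
  byte-identical datasets.
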