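# Methods

## The study design being emulated

The package models a cross-sectional serum-metabolomics aging study: ~138
apparently healthy, non-obese (BMI < 30 kg/m²) adults aged 20–70, about 56%
male, profiled for ~10 clinical markers, ~47 NMR-quantified metabolites and
~128 LC-HRMS features.  The scientific questions are (i) which serum
variables are associated with age after adjusting for BMI, (ii) which
metabolic pathways those variables implicate, (iii) how much age variance a
small metabolite panel explains out of sample, and (iv) whether the
metabolism–age relationship has a breakpoint — an age where its slope
changes.

## Synthetic cohort generator

Concentrations are generated on the log scale:

    log y = baseline + trend(age) + l·η + s·ε  (+ sex effect, default 0)

with η a cohort-wide latent factor shared by the branched-chain amino acid
family (inducing their strong mutual correlation) and ε idiosyncratic
Gaussian noise.  Log-normal noise keeps concentrations positive and
right-skewed, giving the Box-Cox search a non-trivial optimum.  `trend` is a
hinge, continuous at the breakpoint age τ (default 32 y): by default the
declining amino-acid panel *rises* 0.4%/yr before τ and falls 1%/yr after —
a peak profile motivated by lean mass peaking in the third decade — while
the urea-cycle pair mirrors it.  The choice of a peak rather than a monotone
shallow-then-steep profile is substantive: the r²-product split criterion
(below) is ill-posed for monotone profiles whose first regime is nearly
flat, because lengthening the first segment with points from the dominant
regime *raises* its r².

When a target BMI-partialled correlation r is specified, the hinge is
rescaled so the partial correlation of log y with age equals r in
expectation: with g the standardized BMI-residualized trend shape, a the
standardized BMI-residualized age and ρ = corr(g, a), the trend coefficient
is c = q/√(1−q²)·√(l²+s²) with q = r/ρ.  Targets beyond |ρ| are a
configuration error.  Calibration is exact in the linear-Gaussian sense on
the log scale; the Monte-Carlo check (200 replicates) verifies the mean
realized partial r within ±0.05 of target.

Ages are drawn uniformly over the range (only a median and range are
typically reported for such cohorts; uniform is an assumption, not an
inference).  BMI is linear in age (slope chosen so corr(BMI, age) ≈ 0.22)
with resampling below the 30 kg/m² truncation.  Missingness is MCAR at 2%
by default; MNAR mechanisms are out of scope.  Sex is generated but has no
effect by default (an optional per-variable sex effect exists for power
studies).

The feature-table generator lays out an LC-MS batch (blanks first, QC
triplicate groups spread evenly among sample injections) with a smooth
sinusoidal multiplicative drift, and can plant features that violate each
inclusion rule — blank contamination at 50% of sample signal, deterministic
QC group factors spanning ~60% CV, 25% sample missingness — giving the
filters an exact ground truth.

## Feature QC

The blank rule is read as contaminant exclusion (mean blank < 5% of mean
sample signal); the alternative signal-presence reading (sample exceeds
blank by > 5%) is available behind `blank_rule="presence"`, because the
underlying convention is genuinely ambiguous.  QC CV% averages each
triplicate before the CV, so within-triplet injection noise does not inflate
it.  LOESS drift correction (degree 1, span 0.75, statsmodels `lowess`) is
anchored on QC injections, interpolated linearly between them and held
constant beyond the outermost QCs; intensities are divided by curve/median,
which preserves QC medians exactly when the curve interpolates the QCs
(noiseless QCs, e.g. pure linear drift) and to first order otherwise.
Features whose fitted curve is non-positive anywhere are left unnormalized
and reported, never silently altered.

## Imputation

A small Gibbs-style sampler: each incomplete column is regressed on its
`max_predictors` (15) most-correlated companions — a quickpred-style
restriction that keeps the conditional models well-posed when variables
outnumber subjects — and missing entries are drawn from N(prediction, σ̂²).
Positive variables are modeled on the log scale and exponentiated back, so
imputed concentrations are positive.  Five chains are averaged into a single
analysis table (no Rubin's-rules variance pooling; downstream analyses are
single-table by design).  Convergence is judged on the conditional means,
relative to each column's observed SD (the draws themselves never settle);
non-convergent chains are used at their last sweep with a warning.  In the
noiseless limit (an exactly collinear pair) σ̂ = 0 and the imputed value
equals the regression prediction.

## Box-Cox

λ is selected on a grid (step 0.1) over [−10, 10] minimizing the SD of the
geometric-mean-scaled transform — the profile-likelihood-equivalent form.
The literal unscaled criterion is degenerate (SD shrinks without bound as
|λ| grows; in practice it runs to the grid edge) and is available behind
`scaled=False` for comparison only.  Two numerical points: the grid SD is
computed from sd(y^λ) directly, since for large |λ| the textbook expression
(y^λ − 1) absorbs the informative term below float precision and
collapses the SD to 0; and grid values are rounded to 12 decimals so
persisted λs survive text round-trips exactly.  Ties break toward λ = 1,
then smaller |λ|.  All transform constants (λ, shift, GM, mean, SD) are
fitted on the training arm only and replayed verbatim elsewhere; the test
arm therefore has non-zero mean after scaling, by design.

## Screening and the dual rule

Partial correlation is computed as the Pearson correlation of OLS residuals,
with df = n − 2 − k (the standard partial-correlation degrees of freedom).
Significance requires both Benjamini–Hochberg step-up rejection at q = 0.2
and raw p < 0.05; since the α cap only removes rejections from the BH set,
FDR control at q is inherited.  Clinical markers and metabolites are tested
as one family (no per-platform split).  An alternative non-step-up reading —
each p against its own rank's critical value i·q/m — is available behind
`rule="per_rank"`.

## Enrichment

One-sided upper-tail hypergeometric test per pathway; the universe is the
library union (query members outside it, e.g. unidentified LC-HRMS
compounds, are dropped and counted).  The bundled GMT is a small synthetic
SMPDB-style toy library (12 pathways) sufficient for the pipeline and tests;
it is not a substitute for a curated pathway resource.

## Age model

Pure forward selection (no removal step) with BMI forced in and entry at
partial-F p < 0.05; ties break by larger |t|, then name, making the path
deterministic and input-order invariant.  Coefficients are reported on the
standardized-predictor scale (years per SD, since the target is age in
years and predictors are train-standardized).  VIF is 1/(1−R²_j); exact
collinearity reports ∞.  Test-arm evaluation freezes the train model and
reports corr(predicted, observed age).

## Breakpoint detection

Subjects are sorted by age (ties by subject ID — the only ordering under
which "the first k points" defines an age breakpoint).  For every split size
k from `min_segment` to n − `min_segment` (default floor(n/3), i.e. 35 of
105), OLS lines are fitted to both sides and the r² product recorded; the
maximizing split (ties → smaller k) defines two lines whose intersection is
the breakpoint age.  Parallel lines (|Δslope| < 1e−10) are flagged
no-intersection; intersections outside the observed age span are reported
with an `extrapolated` flag rather than clamped.

Two structural properties of this estimator, established by simulation with
the package's own recovery harness, matter for interpretation:

* **Identifiability boundary.**  The one-third minimum segment means a hinge
  below the cohort's 33rd age percentile (≈ 36.7 y for uniform ages 20–70)
  cannot be isolated: the first fitted line necessarily mixes both regimes
  and the estimate is biased upward toward the boundary (noiseless mean
  error +4.6 y over planted hinges 28–45; essentially exact, RMSE ≤ 0.07 y,
  for hinges ≥ 37 y).  Cohorts whose age distribution is denser at young
  ages move this boundary down.
* **Noise behaviour.**  RMSE decreases monotonically with noise (14.6 →
  8.0 y across the ladder from moderate noise to noiseless in the recovery
  study).  At realistic per-metabolite effect sizes (|r| ≈ 0.21–0.37) the
  PC1-vs-age signal is weak and the two fitted lines are often nearly
  parallel, so extrapolated or unstable intersections are common — the
  `extrapolated` flag should always be checked before interpreting a
  breakpoint age.

The recovery harness standardizes log concentrations rather than re-running
the Box-Cox grid: the planted hinge lives in the log-scale latent trend, and
on noiseless hinge data the SD criterion is flat in λ, so an arbitrary
tie-broken λ would confound detector error with transform curvature.
Location statistics exclude no-intersection and out-of-range seeds (counted
separately); a breakpoint outside the observed ages is not interpretable as
a cohort breakpoint.

PCA is an eigendecomposition of the correlation matrix; loadings are
eigenvectors scaled by √eigenvalue (variable–component correlations), and
component signs are oriented so the anchor variable (largest mean |loading|)
loads non-negatively.  The test arm is refit separately and sign-aligned to
the train loadings; both refit and projection views are possible, but refit
matches the practice of reporting separate per-arm loadings.

## Pipeline

Stages persist their outputs as TSV/JSON in the run directory and downstream
stages consume only persisted inputs, so each stage is independently
re-runnable; a missing upstream file raises an error naming the stage.  The
aging panel passed to the model and breakpoint stages is the set of
significant variables belonging to an enriched pathway (≥ 2 hits and
enrichment ratio > 1; with none qualifying, all significant variables are
used).  Summaries contain no timestamps or paths and are byte-identical for
identical configuration and seed.  No statistic is ever computed on the test
arm during fitting; this is asserted by permutation tests in the suite.

## Problem sizes in the test suite

The simulation studies use the sizes the analyses themselves prescribe:
n = 105 (training-arm size) for screening, stepwise and breakpoint studies;
200 seeds for recovery and selection rates; 1000 all-null screens of 175
variables for FDR control; 500 screens in the acceptance script.  The
generator's defaults (n = 138, 2% missingness, |r| = 0.21–0.37, τ = 32 y)
are the study conditions, not tuning knobs.

## Known limitations

* The synthetic cohort is linear-Gaussian on the log scale: no MNAR
  missingness, no batch structure in the cohort table, no nonlinear
  confounding; passing tests show the estimators behave correctly under the
  assumed structure, not that real serum data satisfies it.
* The breakpoint procedure provides no inference (no confidence interval or
  changepoint test); the recovery harness quantifies its sampling behaviour
  instead.  Hinges below the one-third boundary are structurally
  unidentifiable (see above).
* Forward stepwise selection at the effect sizes typical of this design
  (combined R² ≈ 0.27 over four predictors at n = 105) recovers the full
  true support in only ~50–60% of cohorts — per-predictor partial-F power is
  ~0.85, so joint recovery cannot approach 1 — and occasionally admits a
  false predictor, consistent with its entry α.  Reported models should be
  read as one plausible support, not the support.
* The toy pathway library is deliberately tiny; enrichment p-values on it
  are weak (small universe) and the pipeline's "enriched pathway" rule is
  hits/ratio-based rather than p-based for that reason.
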