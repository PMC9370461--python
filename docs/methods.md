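# Methods

## Overview

`senspi` classifies individuals as *sensitive*, *resilient* or *neutral* to
lifestyle risk factors by comparing each person's observed cardiometabolic
trait with the conditional 90% prediction interval a quantile regression
forest (QRF) assigns them given their exposures, then estimates the excess
disease hazard carried by each class and pools it across cohorts. This note
documents the statistical machinery, its assumptions, the parameters that
matter, and the choices made where the design was genuinely open.

## Synthetic cohorts

Individual-level data for analyses of this kind are access-restricted, so
the generator in `senspi.synth` is a first-class part of the package: it
produces cohorts with the dependence structure the analysis assumes and
known ground truth, which is what the test suite and the calibration
script exercise.

Structure and defaults (`SynthConfig`):

- **Exposures** — a Gaussian copula with block-diagonal correlation
  (blocks of 5, within-block r = 0.5 by default; `block_correlation` up to
  0.9 is used in tests to exercise the >0.8 correlation filter). A
  configurable fraction (default 20%) is dichotomized at the latent median
  to emulate dummy-coded questionnaire items. Visit-2 exposures follow an
  AR(1) with coefficient 0.8 on the latent Gaussians, keeping the two
  examinations realistically correlated while preserving the marginals.
- **Latent class** — each subject is permanently *sensitive* (8%),
  *resilient* (8%) or *neutral*. Stability over the ~10-year visit gap is
  an assumption, made so that the persistence rule has a recoverable
  target; whether real sensitivity is stable on that horizon is unknown.
- **Traits** — trait = effects·exposures + class shift + N(0, noise_sd),
  with the shift ±2.5·noise_sd (adverse sign configurable per trait). The
  default effect vector (0.4 on the first third of exposures) gives the
  linear predictor roughly 60% of the trait variance.
- **Survival** — exponential event times with rate
  baseline_hazard·exp(β_S·1[sensitive] + γ′covariates), β_S = log 2,
  baseline 0.03/year, small age and sex effects, administrative censoring
  uniform between 50% and 100% of a 15-year horizon, events split
  CVD/T2D/death 60/25/15. These event-process values were fixed once, as a
  plausible middle-aged-cohort regime that yields a composite event
  fraction near 30%.

What the generator does *not* emulate: real marginal distributions of
questionnaire items, nutrient semantics, registry coding, measurement
drift between instruments, or informative censoring. Passing tests
therefore demonstrate that the *pipeline recovers what it assumes*, not
that the assumptions hold in any particular cohort.

## Preprocessing

- Medication corrections add published constants to treated subjects
  (+0.208 TG, +1.347 TC, −0.060 HDL-C, +1.290 LDL-C mmol/L; +15/+10 mm Hg
  SBP/DBP), applied exactly once (a provenance attribute guards re-entry).
- LDL-C via the Friedewald relation ldl = tc − hdl − tg/2.2 (mmol/L),
  invalid and set missing at TG ≥ 4.52 mmol/L (400 mg/dL).
- Rank-based inverse-normal transform with the Blom offset 3/8 (the common
  epidemiological default; ties share mid-ranks, missing values pass
  through).
- Residual-method energy adjustment: OLS residual of nutrient on total
  energy intake plus the nutrient mean — exactly uncorrelated with TEI,
  mean-preserving.
- Implausible energy reporters excluded outside the cohort's 5th–97.5th
  percentile of food intake level (TEI/BMR).
- Predictor filtering: zero-variance columns dropped, then pairwise
  |r| > 0.80 broken by removing the member with the larger mean absolute
  correlation (deterministic, caret-style); design-matrix multicollinearity
  then controlled by iterative VIF > 10 removal.

## Quantile regression forest

Trees are CART regression trees grown on bootstrap resamples (growth
delegated to scikit-learn's seeded splitter; `mtry` = ⌈p/3⌉ features per
split, nodes of ≤ `min_node_size` = 5 become leaves, 500 trees by default —
the quantile-forest conventions). For a query x, each tree spreads weight
1/leaf-size over the **original** training observations in the leaf
containing x; weights are averaged over trees and define the conditional
CDF, inverted as an inf-type quantile (always an observed training
response, no interpolation). Using all training observations rather than
bootstrap multiplicities matters: observations a tree did not resample
land in leaves whose boundaries were drawn without looking at their noise,
which keeps the conditional distribution essentially unbiased.

Covariate adjustment (age, age², sex, questionnaire version, fasting
status) is by inclusion as ordinary predictors.

Variable importance: %IncMSE is the per-tree out-of-bag MSE inflation
under permutation of one feature, averaged over trees (×100); IncNodePurity
is the total SSE reduction attributed to splits on the feature. Importance
permutation is OOB-based, the standard random-forest convention.

Numerical notes: weights row-sum to 1 within 1e−10; quantile ties broken
by the inf convention; a constant response produces single-leaf trees and
zero-width intervals (with a warning). The default leaf size is tuned for
the usual many-predictor setting; for *low-dimensional* conditional
distribution estimation (e.g. one predictor) leaves must be much larger
(the 1-D test uses `min_node_size` = 200 at n = 10 000), since tiny leaves
on a single axis isolate a handful of neighbors and inflate quantile
noise.

Calibration: on held-out halves of simulated homoscedastic cohorts
(5000/5000, p = 10), empirical coverage of the 90% interval is ≈ 90% and
the upper-tail fraction ≈ 5% (`scripts/acceptance.py` recomputes both).

## Classification

With adverse direction "high": above the upper bound → sensitive, below
the lower → resilient, inside → neutral; mirrored for HDL-C-type traits
where low values are adverse. Boundary equality counts as inside (the
interval is closed; exact ties are measure-zero for continuous traits).
Persistence over two visits requires the *same* label at both
examinations; any discordant pair is neutral — the strictest reading,
chosen because it maximizes label purity at the cost of group size (with
per-visit detection ≈ 0.5 for a 2.5-SD shift, roughly a quarter of truly
sensitive subjects retain the label at both visits, and those that do are
~90% true positives). Single-visit mode labels from the baseline visit
only.

## Survival analysis

Cox partial likelihood maximized by Newton–Raphson with step-halving to a
gradient norm < 1e−8; Efron tie handling by default (Breslow available);
SEs from the inverse observed information; the neutral class is the
reference for the label dummies. Monotone likelihood (a class with no
events) is flagged and reported as non-converged rather than returning a
divergent estimate. Agreement with an independent reference implementation
is verified in the test suite to |Δβ| < 1e−6.

Proportional hazards are tested with the Grambsch–Therneau score test on
Schoenfeld residuals against g(event time) (identity by default, rank
transform available), per covariate and globally.

## Meta-analysis

Fixed weights wᵢ = 1/SEᵢ²; Q = Σwᵢ(θᵢ − θ_F)²;
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)); random-effects weights
1/(SEᵢ² + τ²); normal-approximation CIs (no Knapp–Hartung, matching the
plain DerSimonian–Laird method). When Q ≤ k−1, τ² = 0 and random- and
fixed-effects pooling coincide exactly. The sensitive-vs-resilient
subgroup test is a df = 1 Q statistic on the two pooled estimates. With
k = 2 cohorts the τ² estimate is very noisy; occasional wide random-effects
CIs in the two-cohort setting are a known cost of the estimator, not a
defect.

## Risk-score comparison

Published clinical risk algorithms are external documents, so the module
exposes a pluggable `base_score` interface and ships a deterministic
synthetic stand-in (a fixed logistic-style linear predictor in age, sex
and either SBP + total cholesterol or BMI, standardized in-cohort).
Outcomes are events within a 10-year horizon. Both logistic models
(score; score + sensitivity flag) are fitted by IRLS, and AUC is the
tie-corrected Mann–Whitney probability; the flag is the "any-trait"
sensitive indicator by default. Perfect separation is flagged as
non-convergence.

## Pipeline

Per cohort: FIL exclusion → inverse-normal transform of continuous
exposures → correlation filter → (if needed) forest imputation of
exposures with < 50% missingness (columns at ≥ 50% are excluded, not
imputed) → subject-level 50/50 train/test split (both visits of a subject
on the same side) → VIF filter on the training design → QRF fit on the
training half → prediction intervals and labels for the held-out half
(persistent or single-visit mode per cohort) → Cox on the labelled test
subjects (age and sex as covariates; the QRF-model covariates are not
repeated) → per-cohort log-HRs pooled across cohorts → AUC comparison. A
run manifest records counts at every exclusion stage; identical seeds give
byte-identical outputs.

## Problem sizes used in the test suite

The suite validates at sizes chosen for single-CPU turnaround: the
calibration checks use the full 5000/5000, p = 10, 500-tree setting; the
20-replicate end-to-end recovery study uses two cohorts of n = 4000,
p = 12 with 200 trees and the composite (any-event) outcome, which yields
roughly 300 events per test half and adequate power for the pooled
sensitive-class contrast; the global-null calibration uses 20 replicates
of two n = 1500 cohorts with all effects set to zero. The imputation,
survival and meta modules are validated on small oracle datasets where
brute-force or closed-form answers exist.

## Known limitations

- DerSimonian–Laird τ² with two studies is noisy (see above).
- The QRF provides no conformal-style finite-sample coverage guarantee;
  calibration is verified empirically on the generator's data.
- Only exposures are imputed; trait responses with missing values drop the
  corresponding subject-trait observations.
- The persistence rule assumes latent sensitivity is stable across visits;
  if it drifts in real data, persistent labels undercount true sensitives.
- No competing-risks handling: event types other than the analyzed outcome
  are treated as censoring.
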