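# Methods

This note documents the models implemented in `patcomp`, the generative
model behind the synthetic studies, the defaults and numerical choices,
and what the test suite does and does not establish about real data.

## Study design assumed throughout

Five alternating encoding/retrieval runs.  Each encoding block presents 24
word–picture pairs, balanced 12 word-face / 12 word-place; each retrieval
block probes the 24 studied words plus 6 novel foils with a 4-way decision
(Face / Place / Old / New).  A self-paced post-scan test probes
exemplar-specific recall of every studied word.  Per cohort this yields
120 studied words and 30 foils per participant.

## Quality control

A volume is flagged as an artifact when framewise displacement relative to
the previous frame exceeds 0.5 mm, or when whole-brain mean intensity
deviates from the run mean by more than five run standard deviations
(skipped, with a warning, for a zero-variance intensity series).  A run is
dropped when *more than* 25% of its volumes are flagged or its maximum FD
exceeds 2 mm — strict inequalities, so a run at exactly 25% or exactly
2 mm is retained.  A trial is excluded from every analysis when any of its
volumes is flagged or its run is dropped.  Behavioural rates are computed
on all trials by default; only neural aggregates are restricted to
artifact-free trials (whether behavioural rates should also exclude
artifact trials is ambiguous in this paradigm; the alternative is a
one-line filter upstream).

## Behaviour

Retrieval responses map deterministically onto six conditions: for
studied words, correct category → associative hit, wrong category →
associative miss, Old → item hit, New → item miss; for foils, New →
correct rejection, Old → item false alarm, Face/Place → associative false
alarm.  Missing responses are `unclassified` and excluded.

Signal-detection indices use `d′ = Φ⁻¹(hit rate) − Φ⁻¹(fa rate)`.
Old/new d′ counts any Old/Face/Place response to studied words as a hit
and to foils as a false alarm; associative d′ counts correct-category
responses to studied words against any category response to foils (the
full 30-foil denominator).  Perfect rates are replaced by `1/(2N)` and
`1 − 1/(2N)` before the inverse normal CDF; with 120 targets and 30 foils
this bounds old/new d′ at ≈ 4.77, the value the operator reproduces in
tests.  A log-linear (+0.5/+1) rule is available via `boundary_rule`.

Post-test responses are scored as correct when the normalised response
(lower-cased, diacritics and punctuation stripped, whitespace collapsed)
contains the normalised target name as a substring; non-matching responses
are routed to a review list, standing in for the human-rating arm, which
is out of scope.  The delayed-recall composite is the arithmetic mean of
the three z-scored delayed-recall subtests (logical memory, HVLT-R,
BVMT-R); z-scoring across the sample happens upstream.

## Category classification (MVPA)

Patterns are standardised per voxel across trials *within run* using the
population (ddof = 0) standard deviation, so each voxel has exactly zero
mean and unit variance within run; zero-variance voxels become all-zero
with a warning.  Feature selection ranks voxels by a two-sample Welch *t*
(face vs place) on encoding trials and takes the top k per category
(default k = 250, union ≤ 2k; the two sets cannot overlap because the
rankings run in opposite directions).  When 2k exceeds the voxel count all
voxels are used with a warning.

The classifier is scikit-learn's liblinear L2 logistic regression with
C = 1.  Every training fit sees a category-balanced subsample (asserted
inside the trainer); the probabilities of `n_subsamples = 10` fits are
averaged **on the probability scale** and transformed once —
`logit = log(p/(1−p))` after clipping to `[1e−6, 1 − 1e−6]` — because
averaging probabilities keeps the pooled value in (0,1) before the single
transform.  Evidence is signed toward the trial's correct associate
(positive = correct-category evidence regardless of face/place), and a
trial counts as correctly classified iff `p > 0.5`; exactly 0.5 counts as
incorrect, a conservative tie rule whose frequency is negligible with
continuous probabilities.

Encoding accuracy comes from leave-one-run-out cross-validation.  Feature
selection is recomputed inside each training fold by default, avoiding
selection leakage into the held-out run; a subject-level selection
(`select_within_folds=False`) exists for fidelity to pipelines that select
once per subject.  Retrieval evidence trains one classifier per subsample
on all encoding data and tests on all retrieval trials; foils (no correct
category) are excluded with a log entry.

Permutation significance: per subsample iteration, the encoding training
labels are shuffled `n_permutations = 1000` times (test labels fixed — the
null is "no learnable association in training"), the full pipeline
including feature selection is re-run by default
(`refit_selection_in_permutation=False` freezes it), and
`p = #(permuted accuracy ≥ observed)/n_permutations`, averaged over
subsample iterations.  "≥" includes ties, so the p-value is valid
(slightly conservative) at coarse accuracy granularities.

## Encoding–retrieval similarity

ERS uses the full ROI (no feature selection), by default after the same
within-run scaling as the classifier (`configurable`; whether scaling
precedes ERS is an open choice in this literature and both orders are
supported).  For retrieval trial *t* in success state *s* (associative
hit vs associative miss / item hit / item miss):

* within-event: Fisher-z correlation with the same word's encoding
  pattern;
* within-category: mean Fisher-z over other same-category encoding events
  whose own retrieval outcome shares *s* (the same-event pair — the
  diagonal of the correlation matrix — is removed first);
* between-category: the same over the other category, matched on *s*.

Correlations are clipped to ±(1 − 1e−7) before `arctanh`, and the Fisher
transform is applied before any averaging.  Cross-run pairs are allowed by
default (`exclude_same_run=True` guards against run-level similarity
inflation).  Event-level reinstatement is within-event − within-category;
category-level is within-category − between-category.

## Trial-wise mixed models

All continuous trial-level variables are z-scored within participant
across trials (sample SD, ddof = 1) before modelling; participant-level
age is z-scored across participants.  Every model has a participant random
intercept plus an **uncorrelated** random slope of the predictor of
interest.  Fixed-effect significance uses a likelihood-ratio χ² against
the nested model with the predictor's fixed term dropped but its random
slope retained (testing the fixed effect only); Wald z = estimate/SE is
reported for simultaneous inference within a model.  Nuisance sets follow
fixed rules per analysis kind: stimulus category and age always; ROI
encoding classifier strength when reinstatement logits are the IV or DV;
category-selective voxel activity when logits are the IV; whole-ROI
activity when ERS is the IV; category-level (within-category) ERS when
event-level ERS is the IV or DV.

Linear models are fitted by ML (not REML, so LRTs are valid) through
statsmodels `MixedLM`, with the random slope as a variance component to
enforce zero intercept–slope correlation.  No frequentist logistic mixed
model exists in the scientific Python stack, so logistic models use an
in-package Laplace-approximated ML fitter: per-participant 2-d posterior
modes by damped Newton, marginal likelihood by the Laplace determinant
correction, joint L-BFGS-B over fixed effects and log random-effect SDs
(bounded in [1e−4, 20]), and Wald SEs from the numerical Hessian of the
fixed-effect block at the variance estimates — the same convention as
lme4's `glmer`, against which the fitter is cross-checked in the test
suite (agreement to ~1e−3 in coefficients and log-likelihood).  Designs
are standardised to unit column variance internally and estimates mapped
back, which makes the LRT exactly invariant to rescaling the predictor;
note that *shifting* a predictor genuinely changes a model with an
uncorrelated random slope, so only pure rescaling is an invariance.
Negative LRT statistics (optimiser noise) are floored at zero with a
warning; a failed or unconverged fit is retried without the random slope
and flagged.

Age moderation adds an age × predictor fixed interaction (age itself in
the nuisance set) and compares by LRT.

## Mediation

Indirect effect = a × b, with a = treatment coefficient in the mediator
model and b = mediator coefficient in the outcome model controlling the
treatment.  Inference is a percentile bootstrap (default 5000 resamples):
the 95% CI is the 2.5/97.5 percentile of the resampled a·b, significant
iff zero lies outside.  The bootstrap resamples **participants** (whole
clusters) with replacement, preserving within-participant dependence;
trial-level resampling exists behind `cluster=False`.  By default both
path models are pooled regressions (OLS mediator model, Newton-fitted
logistic outcome model for binary outcomes) so that the estimator whose
CI is reported is exactly the estimator that is bootstrapped, and the
5000-fold loop stays fast; `engine="mixed"` fits both paths as the full
mixed models instead.  Known limitation: the percentile interval for a
product estimator undercovers in finite samples — empirical coverage
≈ 0.90 at 100 participants × 120 trials in this package's calibration
tests against the nominal 0.95, with an independent from-scratch
implementation of the same procedure measuring the same value, because
the interval's accuracy is governed by the number of resampled clusters
(~100) rather than the trial count.  This is a property of the percentile
method under cluster resampling, not of the implementation; the
corresponding calibration test documents it by failing its nominal band.

## Individual differences

Per participant: hippocampal activity = mean over associative-hit trials
minus mean over correct-rejection trials; mean signed logit and
event-level ERS contrast over associative hits per ROI; encoding
classifier strength = mean cross-validated encoding logit.  Participants
lacking a required trial cell get missing aggregates (cell threshold
configurable).  Each neural variable is adjusted by mean framewise
displacement — and reinstatement strength additionally by the ROI's
encoding strength — via linear residualisation with the grand mean
restored; collinear covariates are an error.  Regressions are OLS on
variables z-scored across participants, giving standardized β;
participants missing an outcome are dropped listwise with the count
logged.  Hierarchical comparison reports, per step,
`F = (ΔR²/Δp) / ((1−R²_full)/(n−p_full−1))` on a common complete-case
sample; literal duplicate predictors are dropped and a rank-deficient step
yields F = 0.  Two-tailed α = 0.05 throughout, with no multiple-comparison
correction — a deliberate reproduction of standard practice in this
analysis style.  Education is excluded from the hierarchical models (it
is a null screen only); sex enters only the delayed-recall age model.

## Synthetic-study generator

The generator writes the same tables and HDF5 pattern files the readers
consume and exports every latent it draws.  Per participant *i*:
age ~ U(60, 82); pattern fidelity `f_i = max(0, 1 − δ(age−60))` with
δ = 0.015/yr (fidelity 1.0 at 60, 0.67 at 82); retrieval ability
~ N(0, 0.8²); mean FD ~ logN(log 0.15, 0.4).  Per ROI, fixed unit-norm
random templates T_face, T_place and per-event vectors E_t.  Encoding
pattern: `g_roi (2.5 T_c + 1.2 E_t) + N(0, 1)` per voxel (ROI weights
VTC = 1.0, ANG = 0.7).  Trial latents: hippocampal drive h ~ N(0,1);
reinstatement `r = a_h h + √(1−a_h²) η` with a_h = 0.4.  Retrieval
pattern: `f_i · max(r, 0) ·` (the same signal) + noise — a failed
reinstatement (r ≤ 0) carries no category or event signal.  Associative
success ~ Bernoulli(logistic(0 + 0.8 h + 0.8 r + ability)); successful
trials give the correct category except a 2% cross-category error; failed
trials give a signal-free category *guess* 15% of the time (correct by
luck half the time) and otherwise Old (45%) vs New.  Foils draw
CR/item-FA/associative-FA at 0.85/0.10/0.05.  RT = 2.2 − 0.35·max(r,0) +
N(0, 0.45²), floored at 0.2 s.  Post-test recall ~ Bernoulli(logistic(−2.2
+ 1.6·assoc_hit + 0.5·r + 0.8·ability)).  Measured hippocampal activity is
h + N(0, 0.5²); foil trials carry an independent drive uncoupled from
behaviour, so the hit-vs-CR contrast is driven by the behavioural
selection of high-h trials.  QC series draw per-volume FD around the
participant's mean FD (log-sd 0.5) and intensity ~ N(1000, 2), six volumes
per trial.

Defaults were set once to produce a cohort resembling the paradigm's
published behaviour (associative d′ near 1.6, ~55% associative hit rate,
exemplar recall near 0.25, encoding classification near ceiling in the
stronger ROI, associative-hit retrieval classification near 70%).

Design choices worth flagging:

* **Guesses vs cross-category errors.**  Making most associative misses
  signal-free guesses (rather than cross-category errors on successful
  retrieval) reproduces the qualitative signature that classifier
  evidence is much weaker when associative retrieval fails.  Because the
  pattern signal scales with `max(r, 0)` regardless of the response,
  failure trials with positive latent reinstatement still carry some
  signal, so "failed" conditions sit slightly above chance rather than
  exactly at it.
* **Heterogeneity.**  Ability and fidelity are the only cross-participant
  heterogeneity; there are no run effects, which keeps mixed-model
  recovery interpretable.  Age affects *neural* fidelity only — it is not
  coupled to ability — so synthetic cohorts show an age decline in
  reinstatement strength but only a weak age decline in behaviour, and
  participant-level hippocampal summaries carry little
  individual-differences signal.  The hierarchical-regression ladder on
  synthetic data therefore exercises the machinery and its identities,
  not published effect sizes.
* **Determinism.**  Each participant has its own RNG streams (behaviour,
  patterns, QC) spawned from the master seed, so regeneration is
  bit-identical and disabling pattern synthesis (`generate_patterns =
  False`, used by fast statistical calibration runs) leaves the
  behavioural draws unchanged.
* **Oracle.**  `truth_regression_oracle` returns the estimands on the
  latent scale: the population slope of r on h is exactly a_h (mediation
  a-path) and the logistic coefficients are β_h, β_r (b-path = β_r).
  These are exact for analyses run on the exported latents with the
  response-contamination parameters (cross-category errors, guesses) set
  to zero and no participant heterogeneity; with the defaults, measured
  paths are attenuated relative to the oracle.

What passing tests on this generator do **not** show: realistic fMRI
noise structure (spatial/temporal autocorrelation, run effects, scanner
drift), hemodynamics (trial patterns are emitted directly, not extracted
from BOLD time series), item effects, or realistic cross-participant
covariance between neural integrity and behaviour.

## Problem sizes used in validation

The automated checks run on scaled-down cohorts chosen as the package's
own validation conditions: unit tests use 8–10 participants with 60–120
voxels; the acceptance script regenerates a 40-participant, 150-voxel
cohort; calibration checks use 800 zero-signal replicates (permutation
type-I), 200 replicate datasets (LRT type-I and mediation coverage at 100
participants), and 16 replicate 100-participant cohorts (age-slope
recovery power).
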