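# Methods

## Synthetic cohort model

Each patient record carries age (whole years), systolic blood pressure
(SBP, mmHg), respiratory rate (RR, breaths/min), Glasgow Coma Scale
(GCS, 3–15) and a binary major-trauma outcome (ISS > 15 indicator).

**Categories.** Vitals are generated at the category level first, using the
Revised-Trauma-Score bands (GCS 13–15 / 9–12 / 6–8 / 4–5 / 3; RR 30–67 /
10–29 / 6–9 / 0–5; SBP 90–300 / 76–89 / 50–75 / 1–49). Category marginals
are taken from the cohort spec and renormalized to sum to 1 (published
proportions are rounded to four decimals and rarely sum exactly). The raw
value is then drawn uniformly over the assigned band's integer range — the
models only ever see the band, so the within-band distribution is
inconsequential.

**Correlation modes.** By default the three vitals' categories are drawn
independently. In `latent_severity` mode a single standard-normal severity
score per patient is thresholded separately per vital, with cut points at
the normal quantiles of the cumulative (severity-ordered) marginals: the
marginals are preserved exactly by construction, and deranged vitals
co-occur. Real registries publish no inter-vital correlations, so neither
mode claims to match them; both are offered and the independent mode is the
default. Severity ordering matters only here and for the default outcome
coefficients: per the RTS, the best RR band is 10–29 (normal rate), not the
first-listed 30–67.

**Age.** Only the median and quartiles of age are published, so ages come
from a piecewise-linear quantile function through (0.25, 0.5, 0.75) =
the spec's quartiles with linear tails to 16 and 100 years, rounded to whole
years.

**Outcome.** The outcome is Bernoulli with logit = intercept + one log-odds
weight per category. Default weights are monotone in physiological severity:
GCS (0, 0.8, 1.6, 2.4, 3.0), RR (0 for 10–29, then 0.7, 1.4, 2.1 in severity
order), SBP (0, 0.7, 1.4, 2.1) and 0.5 for age ≥ 57 — sized so the
ground-truth model discriminates with AUC ≈ 0.6–0.75, the range typical of
vital-sign triage models. The intercept is not a free parameter: it is
calibrated by Brent root-finding so the population prevalence equals
`prevalence_target` exactly. The marginal prevalence is computed by exact
enumeration of the joint category distribution (an outer product in
independent mode; the piecewise-constant intervals of the shared latent
score in latent mode) combined with the exact probability of age ≥ 57 under
the quantile model, so no Monte Carlo error enters the calibration.

**Missingness.** With `missing_rate` > 0 each vital is blanked independently
and completely at random, after the outcome is drawn from the complete
record. The analysis pipeline excludes incomplete records, so the mechanism
exists only to exercise the eligibility filter; informative missingness is
deliberately out of scope.

**Randomness.** A single master seed is split into named child streams
(categories, raw values, ages, outcomes, missingness) via
`numpy.random.SeedSequence.spawn`, making every cohort byte-reproducible and
the streams mutually independent.

What the generator does **not** emulate: ordinal ISS (only the > 15
indicator), inter-registry selection effects (admission versus activation
criteria), non-random missingness, temporal drift, and any association
between age and vital-sign severity. Tests passing on these cohorts
demonstrate correctness of the machinery and the qualitative behaviour of
the learners under realistic marginals — not the numeric mistriage rates of
any real registry.

## Eligibility and encoding

Retained records satisfy age ≥ 16 ("age above 15" in whole years),
1 ≤ SBP ≤ 300, RR ≤ 67, and completeness. Exclusions are attributed to the
first failing rule in the fixed order age, SBP > 300, SBP = 0, RR > 67,
missing — the order affects only the report breakdown, never the retained
set. The RR 30–67 band's upper bound matches the RR > 67 exclusion, so the
eligible value space is partitioned exactly (verified by exhaustive
enumeration in the tests).

Records are stored as a 15-indicator vector (5 GCS + 4 RR + 4 SBP + 2 age
bands, split at 57 years). The count 15 is the number of free parameters N
used in the set-size arithmetic: round(N·X/P) reproduces every published
training-set size exactly with N = 15, which is the arithmetic evidence that
the age predictor had two levels. For fitting, the best band of each block
(GCS 13–15, RR 10–29, SBP 90–300, age < 57) is dropped as reference, giving
11 dummy columns plus intercept.

## Shrunken logistic regression

Logistic fits use an in-package Newton–Raphson solver with step halving and
a small ridge penalty (λ = 1e-4) on the slopes only; the intercept is never
penalized. The ridge exists because at 150 events the rare bands (RR 0–5
occurs at ~0.1%) are regularly absent or outcome-pure in a training draw;
the penalty keeps every one of thousands of repetition fits finite with
negligible bias at these scales, and an all-zero dummy column gets
coefficient exactly 0. With λ → 0 the solver agrees with unpenalized
maximum likelihood to 1e-4 (tested against statsmodels).

The bootstrap loop follows a documented resampling contract (sequential
`rng.integers(0, n, n)` draws; single-class resamples redrawn, hard cap
10·B) so an independent re-implementation reproduces v̄ to 1e-8, which the
test suite does. The recalibration regression of outcomes on each bootstrap
model's linear predictor is a two-parameter (intercept + slope) logistic
fit with a tiny ridge (1e-6) on the slope to guard against separation; the
slope bᵢ is extracted. B defaults to 1000; smoke and test profiles use
smaller B since v̄ is a mean whose Monte Carlo error shrinks as 1/√B.

Shrinkage modes: `default` multiplies the slopes by v̄ and re-estimates the
intercept by solving the one-parameter score equation with the shrunken
linear predictor as offset (standard uniform-shrinkage practice; preserves
calibration-in-the-large). `literal` multiplies every coefficient including
the intercept by v̄. Both modes share identical slope coefficients.

## Boosted trees and tuning

XGBoost with the binary logistic objective, `hist` tree method, single
thread (for reproducibility). Tuned hyperparameters and search ranges:
boosting rounds 10–500 (log-uniform integer), learning rate 0.01–0.3
(log-uniform), tree depth 1–6 (uniform integer), L2 penalty 0.1–10
(log-uniform); all other hyperparameters at library defaults; random-search
budget defaults to 30 draws. Candidates are scored by mean held-out
log-loss (misclassification rate available as an option) under five-fold
cross-validation on the pooled training + validation data; folds are
stratified so every training fold contains both classes at low prevalence,
and the same folds score every candidate. The winner is refitted on the
training set alone. The search ranges and scoring measure are package
defaults, configurable, not claims about any published analysis.

## Cut-off rule

Thresholds classify "major" at probability ≥ t (the boundary convention is
fixed because tied probabilities are common with categorical predictors) and
are searched on the inclusive grid 0.000–1.000 in steps of 0.001 (1001
points, decimal-rounded so grid values are exact). Primary branch: among
thresholds with validation undertriage ≤ 0.05, minimize overtriage.
Fallback: among thresholds with overtriage strictly below 0.50, minimize
undertriage. Ties break toward the largest threshold (most conservative
under drift). Note that with the default grid the primary branch is always
non-empty — at t = 0 nothing is classified minor, so undertriage is 0 — and
on these cohorts the selected cut-off typically trades near-zero undertriage
for overtriage near 1; the fallback is reachable only under restricted grids
(`grid_start` above the feasible region), which the tests exercise.

## Metrics

Undertriage = FN/(TP+FN), overtriage = FP/(FP+TN); sensitivity and
specificity are stored as exact complements (1 − rate) so the defining
identities hold to the bit. AUC is the Mann–Whitney rank statistic with
ties counted ½. Calibration clips probabilities to [1e-6, 1−1e-6] (tree
ensembles can emit hard 0/1) before the logit; the calibration slope is the
coefficient of a two-parameter logistic regression of outcomes on the logit,
and the calibration intercept is the intercept of an offset-only logistic
fit (slope pinned at 1, calibration-in-the-large). The slope model's free
intercept is kept as a secondary diagnostic since the two intercept
definitions differ. A constant classifier has an undefined slope; the
repetition harness records NaN for such repetitions rather than aborting.

## Repetition harness

Training, validation and test sets are drawn disjointly (a random
permutation sliced into the three sizes) — the conservative reading that
prevents leakage. If any of the three sets is single-class the whole
partition is redrawn, up to 100 attempts, and the event is logged; at the
study's prevalences this essentially never triggers. Both learners see the
identical training draw, choose cut-offs on the identical validation set and
are evaluated on the identical test set; paired differences are computed
within repetition. Cells whose combined sizing exceeds the cohort (the
1000 events-per-parameter level on a 16,547-record cohort needs a 125,000
training set) are skipped with a recorded reason.

Summaries report the median and 2.5/97.5 percentiles per metric using
linearly interpolated order statistics (numpy's default, type-7). R (the
number of repetitions) and B both default to 1000 and are independently
configurable; the test and acceptance profiles use R = 100, B = 100 and a
search budget of 10 at 10 events per free parameter, and smaller smoke
profiles elsewhere, which keeps the full suite to a few minutes while
leaving the Monte Carlo error of a median of ~100 draws well inside the
tolerances asserted.

Reproducibility: the master seed spawns per-cohort, per-cell and
per-repetition seed sequences, and each repetition spawns separate streams
for the data draw and the two learners. The logistic arm is bit-reproducible;
the boosted arm additionally relies on XGBoost's own single-thread
determinism (observed to hold, asserted for the tuned hyperparameters and
predictions in the tests).

## Known limitations

- The cut-off rule's primary branch dominates on realistic cohorts (see
  above); comparisons between learners remain meaningful because both are
  subjected to the same rule, but absolute overtriage rates are near 1 at
  the undertriage-first optimum on these synthetic cohorts.
- The generator's outcome model is logistic in the same dummies the logistic
  learner uses, which mildly favours logistic regression; the boosted
  learner can at best match it on this data-generating process. Qualitative
  conclusions about *relative* sample-size needs transfer; effect sizes do
  not.
- No multiple imputation, class re-balancing, early stopping or alternative
  learners; continuous-predictor modelling is out of scope by design.
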