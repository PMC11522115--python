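# Methods

This note documents the models, rules, and numerical choices the package
implements, and what its synthetic cohorts do and do not show.

## The risk score and its classifier

The vein-level ERC score is a fixed linear combination,
`0.02·TTI + 0.5·u + 0.2·nadir`, with TTI in seconds, `u` the number of
unsuccessful applications, and nadir in °C. The coefficients come from a
logistic model fitted on an earlier derivation cohort and are taken as
given; re-deriving them is out of scope. A vein is test-positive when its
score is **greater than or equal to** the cutoff — ties count as
positive. Two cutoffs are first-class: −6.7 (original) and −7.2 (the
common operating point).

Numerics: `classify` compares `score >= cutoff − 1e-9`. The guard exists
because a score reconstructed from an inverted threshold (e.g.
`0.02·10 + 0.2·(−37)`) can sit one binary ulp below `−7.2` in floats,
which would silently flip the tie rule. `tti_threshold` and
`decision_table` invert the score in exact rational arithmetic
(`fractions.Fraction` built from the shortest decimal representation of
each coefficient), so table cells are exact integers for the published
coefficients. Table semantics: threshold ≤ 0 → always test; threshold
above the display cap → no test. The cap defaults to 95 s, the last TTI
value the published table displays (the protocol repositions the balloon
after 90 s anyway); it is configurable.

When a vein has several applications, the predictors are taken from the
application that achieved isolation (consistent with TTI's definition);
callers preferring the coldest application can aggregate upstream.

## Diagnostic validation metrics

From confusion counts at a cutoff: sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), LR+ = sens/(1−spec), LR− = (1−sens)/spec
(flagged infinite at the degenerate specificities). Predictive values
use the odds form of Bayes at an **explicit** prevalence:

PPV = sens·p / (sens·p + (1−spec)(1−p)),  NPV = spec·(1−p) / (spec·(1−p) + (1−sens)·p).

The prevalence is deliberately decoupled from the complete-case sample:
the headline predictive values use the cohort-level vein prevalence
(41/774 = 5.30%), not the complete-case subset's 37/650, and the
derivation cohort's 9.22%. With `prevalence=None` the sample prevalence
is used, in which case PPV/NPV reduce exactly to tp/(tp+fp) and
tn/(tn+fn).

Expected-count projections multiply rates by class sizes
(sens·n_pos, (1−spec)·n_neg, (1−sens)·n_pos) and round half away from
zero — whole veins, matching how such tables are printed.

ROC curves sweep thresholds over the distinct scores with the same `>=`
positivity convention; the AUC is the trapezoidal area, identical to the
Mann–Whitney pair statistic with half-credit for ties. The 95% CI uses
DeLong's asymptotic variance of the placement values (the standard for
empirical ROC curves; Hanley–McNeil is available by flag). The
two-cohort comparison reports metrics per candidate cutoff in both
cohorts and recommends the cutoff maximising the **minimum** Youden
index across the two — a reproducible surrogate for visually choosing a
cutoff that performs well in both ROC curves, with ties broken toward
the lower (more sensitive) cutoff.

## Survival rules

The endpoint is freedom from atrial arrhythmia off antiarrhythmic drugs
(AADs). Per patient:

* 90-day blanking: in-blanking recurrences are ignored; the curve starts
  at blanking end.
* The survival clock counts **AAD-free days only**. Days on an AAD after
  blanking pause the clock (default); a `reset` policy instead restarts
  it after each AAD spell. Pausing is the primary reading of "AF-free
  days were not counted while on an AAD"; the choice matters only for
  patients with interleaved drug spells.
* Recurrence off AAD after blanking → event at the accrued AAD-free
  time. Recurrence on AAD → still a recurrence, but not an off-drug
  event: censored at the last AAD-free follow-up date; if the patient
  has no AAD-free follow-up after blanking at all, they never enter the
  curve (excluded, reason `aad_only`).
* Administrative censoring at the one-year horizon: 365 days
  post-ablation, i.e. 275 days on the post-blanking AAD-free clock.
* Entries + exclusions always sum to the input patient count; exclusion
  reasons (`missing_followup`, `inconsistent_dates`, `aad_only`) are
  logged.

Kaplan–Meier estimation and the two-group log-rank test (1 df
chi-square, no continuity correction, censorings after events at tied
times) are delegated to lifelines; the tests check them against
hand-computed product-limit and observed-minus-expected values.

## Trace features

All features are defined on the piecewise-linear interpolant of the
sampled curve. The freeze AUC integrates the area between the curve and
0 °C only where the temperature is below zero, inserting interpolated
zero-crossing points so the trapezoid rule is exact for piecewise-linear
data and invariant under grid refinement. Freeze magnitude divides by
the (interpolated) time below zero. Temperatures at fixed offsets are
interpolated, never extrapolated. Warming times are measured from the
global nadir (earliest sample on ties — deterministic); an explicit
thaw-start marker can replace the nadir anchor when the export provides
one. If rewarming data end at automatic balloon deflation before a
threshold is reached, the time to the last sample is reported with a
`truncated` flag rather than dropped, mirroring how warming times are
collected clinically. No resampling is performed; irregular sampling is
tolerated.

## Synthetic cohorts: what they emulate

Calibration targets are the published population summaries:

| quantity | non-ERC | ERC |
|---|---|---|
| TTI, log-normal (median, IQR) | 40 s, 27–60 s | 50 s, 38–75 s |
| nadir, normal (median, IQR) | −47 °C, [−51, −43] | −41 °C, [−45, −38] |
| P(≥1 unsuccessful application) | 0.212 | 0.366 |

Log-normal parameters come from the median and quartile ratio, normal
parameters from the median and IQR width. The unsuccessful-application
count is zero-inflated geometric: zero with the complement of the
any-failure probability, else `1 + Geometric(0.6)` — most failing veins
fail once, a few several times, matching the published "0 IQR 0–1"
pattern. Each vein gets a latent group (ERC-like law with probability
equal to the 5.3% prevalence target); the observed ERC label is then
drawn from a logistic model on the true score, with the intercept
calibrated by root-finding so the expected label prevalence hits the
target, and an optional patient-level normal random effect (default sd
0: the original model ignored within-patient clustering, and the default
reproduces that assumption). The default logistic slope, 0.73 per score
unit, was chosen once from a slope→AUC map so the score's large-sample
discrimination on generated data sits at the observed AUC ≈ 0.77.
Per-covariate missingness (default 0.053 each, independent) reproduces a
~650-of-774 complete-case fraction; whole-patient untested status is off
by default and available as a parameter.

Freeze traces are stylized: exponential approach from 20 °C toward the
nadir over the protocol ablation time (TTI + 150 s on the console's 1 Hz
grid, capped at 240 s), which holds the curve near the nadir, then a
fast-exponential-plus-slow-linear rewarm; truncated records stop at
12 °C, full records at 25 °C. Every generated trace returns its
closed-form feature values (areas and crossing times evaluated
analytically on the generating curve) as an independent oracle. Sampling
is noiseless by default — console noise artifacts are out of scope, and
jitter on the flat freeze bottom would make the sampled nadir time (the
warming anchor) ill-determined.

Follow-up is generated per category (event off AAD, censored early /
administratively, recurrence on AAD with/without an off-drug spell,
drug-covered-only, unusable) with exact counts; the default scenario
mirrors the study accounting (158 of 201 entering the curve, 35 events).

What the generator does **not** emulate: within-patient correlation of
covariates (only the outcome can cluster), vein-specific anatomy
effects, informative missingness, adenosine dosing, or realistic console
noise. Passing recovery tests therefore show the pipeline's arithmetic
and rules are right under the assumed laws — not that the model is valid
on new clinical data.

## Problem sizes and tolerances in the test suite

Desk-scale reproductions (operating-point metrics, expected counts, the
96-cell decision table) are exact to the printed precision. Stochastic
checks use fixed seeds: calibration and recovery tests run cohorts of
200–5 000 patients; the ROC pair-enumeration oracle runs instances of
n = 40 with forced ties; the log-rank type-I-error simulation uses 400
replicates of 40-per-group exponential worlds and accepts rejection
rates in [0.02, 0.08] at the nominal 0.05. These sizes keep the whole
suite under a minute while leaving Monte-Carlo margins well away from
the asserted bounds.

## Known limitations

* The decision table's display cap (95 s) is exposed rather than
  justified clinically; thresholds above it simply mean "no plausible
  TTI triggers testing".
* The survival clock is AAD-free time, not calendar time; curves are not
  directly comparable to calendar-time KM plots.
* DeLong intervals are asymptotic; with very few positive veins the
  coverage degrades.
* `metrics_from_rates` applied to rounded printed rates can differ in
  the last displayed digit from the same metrics computed on the
  underlying counts; where counts are printed, use them.
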