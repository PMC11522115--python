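# cryoerc

Validation toolkit for an early-reconnection / dormant-conduction (ERC)
prediction model in cryoballoon pulmonary vein isolation (PVI).

## The problem

Cryoballoon ablation isolates the pulmonary veins to treat atrial
fibrillation (AF). Some veins reconnect within the first 30 minutes
("early reconnection"), or harbour dormant conduction that only adenosine
unmasks; both are treated by additional applications. Detecting them
requires a 30-minute wait plus adenosine testing in every patient —
time-consuming and unpleasant. A vein-level risk score built from three
procedural parameters predicts which veins can safely skip the test:

```
score = 0.02 · TTI (s) + 0.5 · n_unsuccessful + 0.2 · nadir (°C)
```

where TTI is the time to isolation, `n_unsuccessful` the number of
cryo-applications that failed to isolate the vein, and nadir the minimum
balloon temperature. A vein scoring **at or above** the cutoff is flagged
for testing (ties positive); −6.7 is the original operating point, −7.2
the common operating point that performs well in both the derivation and
validation cohorts. Because the score is linear with a positive TTI
coefficient, the cutoff inverts to a minimal test-triggering TTI for each
(nadir, unsuccessful-count) pair — a table an operator can read at the
bench.

The package implements the full validation workflow around that score,
for biostatisticians and electrophysiology researchers who want to audit
or re-run it:

* `cryoerc.cohort_model` — vein/patient records, delimited-table IO,
  complete-case filtering;
* `cryoerc.trace_features` — freeze-curve biophysics (freeze AUC over
  the sub-zero section, freeze magnitude, warming times with
  deflation-truncation handling);
* `cryoerc.erc_model` — the score, the tie-positive cutoff classifier,
  and the bedside decision table (exact rational inversion);
* `cryoerc.validation_metrics` — confusion counts, sensitivity /
  specificity, likelihood ratios, predictive values at an explicit
  prevalence (Bayes), expected-count projections, ROC/AUC with a DeLong
  95% CI, and two-cohort cutoff comparison via a max–min Youden rule;
* `cryoerc.survival` — one-year AF-free **and AAD-free** survival with a
  90-day blanking period and drug-aware censoring, Kaplan–Meier and
  log-rank (via lifelines);
* `cryoerc.synthetic_data` — cohort / trace / follow-up generators
  calibrated to the published population summaries, with closed-form
  ground truth for oracle testing;
* `cryoerc.cli` — `cryoerc simulate | extract-features | score |
  validate | decision-table | survival | report`.

The `analysis/` directory holds the numbered drivers that run the whole
study on a simulated cohort and write their tables under `results/`.

## Worked example

Reconstruct the validation cohort's operating point at the common cutoff
from its confusion counts (27 true positives, 131 false positives, 10
missed ERC veins, 482 true negatives) and the cohort's 41/774 vein-level
ERC prevalence:

```python
from cryoerc.validation_metrics import ConfusionCounts, metrics_from_confusion

b = metrics_from_confusion(ConfusionCounts(tp=27, fp=131, fn=10, tn=482),
                           prevalence=41/774, cutoff=-7.2)
print(f"sens {b.sensitivity:.2%}  spec {b.specificity:.2%}  "
      f"LR+ {b.lr_pos:.3f}  LR- {b.lr_neg:.3f}  PPV {b.ppv:.2%}  NPV {b.npv:.2%}")
```

prints

```
sens 72.97%  spec 78.63%  LR+ 3.415  LR- 0.344  PPV 16.04%  NPV 98.11%
```

— a positive test multiplies the pre-test odds by 3.4; at a 5.3%
prevalence a negative prediction is correct 98.1% of the time, which is
what justifies skipping the wait in score-negative patients.

The bedside table comes from inverting the score at the cutoff:

```python
from cryoerc.erc_model import decision_table

t = decision_table()  # cutoff -7.2, nadir -30..-53 °C, 0..3 failures
print(t.cell(-39, 0).label(), "|", t.cell(-46, 0).label())
```

```
>= 30: ERC test | NO ERC test
```

A vein reaching −39 °C with no failed applications needs testing only if
its TTI was ≥ 30 s; one reaching −46 °C with no failures never triggers
testing within the displayed TTI range.

## The simulated study

```
python analysis/01_simulate_cohort.py    # 201 patients x 4 veins, follow-up
python analysis/02_trace_features.py     # freeze-curve features, summary medians
python analysis/03_validate_model.py     # published operating points + full run
python analysis/04_decision_table.py     # the bedside table
python analysis/05_survival_analysis.py  # KM + log-rank with AAD-aware censoring
```

Outputs land in `results/`. The cohort generator targets the published
covariate summaries (TTI median 40 s IQR 27–60 without ERC, nadir −47 °C
vs −41 °C by group, vein prevalence 5.3%) and the follow-up accounting
(158 of 201 patients entering the one-year curve).

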