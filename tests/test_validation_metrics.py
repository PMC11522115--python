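"""Diagnostic metrics, expected counts, ROC/AUC, and cutoff comparison."""

import math

import numpy as np
import pytest

from cryoerc import validation_metrics as vm
from cryoerc.synthetic_data import GeneratorConfig, analytic_operating_point, generate_cohort


# ---------------------------------------------------------------------------
# confusion counts
# ---------------------------------------------------------------------------

def test_confusion_small_enumerable():
    c = vm.confusion_at_cutoff([-8, -7, -6], [False, True, True], -7)
    assert (c.tp, c.fn, c.fp, c.tn) == (2, 0, 0, 1)


def test_confusion_all_below_cutoff():
    c = vm.confusion_at_cutoff([-9, -8], [True, False], -7)
    assert (c.tp, c.fp) == (0, 0) and (c.fn, c.tn) == (1, 1)


def test_confusion_matches_brute_force_recount():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=10_000)
    labels = rng.random(10_000) < 0.3
    cutoff = 0.25
    c = vm.confusion_at_cutoff(scores, labels, cutoff)
    tp = fp = fn = tn = 0
    for s, y in zip(scores, labels):  # independent loop recount
        pred = s >= cutoff
        tp += pred and y
        fp += pred and not y
        fn += (not pred) and y
        tn += (not pred) and not y
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


def test_confusion_length_mismatch_is_error():
    with pytest.raises(ValueError):
        vm.confusion_at_cutoff([1.0, 2.0], [True], 0.0)


# ---------------------------------------------------------------------------
# metric bundles
# ---------------------------------------------------------------------------

def test_perfect_classifier_bundle():
    b = vm.metrics_from_confusion(vm.ConfusionCounts(tp=5, fp=0, fn=0, tn=10), prevalence=0.2)
    assert b.sensitivity == b.specificity == b.ppv == b.npv == 1.0
    assert b.lr_pos_undefined and math.isinf(b.lr_pos)
    assert b.lr_neg == 0.0


def test_sample_prevalence_reproduces_raw_predictive_values():
    c = vm.ConfusionCounts(tp=20, fp=30, fn=10, tn=140)
    b = vm.metrics_from_confusion(c)  # prevalence defaults to 30/200
    assert b.ppv == pytest.approx(c.tp / (c.tp + c.fp))
    assert b.npv == pytest.approx(c.tn / (c.tn + c.fn))


@pytest.mark.parametrize("prev", [0.02, 0.053, 0.3, 0.7])
def test_bayes_consistency_of_predictive_values(prev):
    """Post-test odds = LR x pre-test odds, both directions."""
    b = vm.metrics_from_rates(0.73, 0.79, prev)
    assert b.ppv / (1 - b.ppv) == pytest.approx(b.lr_pos * prev / (1 - prev))
    assert (1 - b.npv) / b.npv == pytest.approx(b.lr_neg * prev / (1 - prev))


# ---------------------------------------------------------------------------
# expected counts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sens,spec,n_pos,n_neg,expected",
    [
        (0.3784, 0.8907, 37, 613, (14, 67, 23)),
        (0.7250, 0.7822, 40, 381, (29, 83, 11)),
        (0.7297, 0.7863, 37, 613, (27, 131, 10)),
        (1.0, 1.0, 12, 99, (12, 0, 0)),
    ],
)
def test_expected_counts_round_to_whole_veins(sens, spec, n_pos, n_neg, expected):
    e = vm.expected_counts(sens, spec, n_pos, n_neg)
    assert (e.predicted_tp, e.predicted_fp, e.predicted_missed) == expected


def test_expected_counts_half_rounds_away_from_zero():
    e = vm.expected_counts(0.5, 0.5, 5, 5)  # 2.5 -> 3
    assert e.predicted_tp == 3 and e.predicted_missed == 3


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _pair_auc(scores, labels):
    """Brute-force Mann-Whitney pair enumeration (ties count one half)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_perfect_separation():
    roc = vm.roc_curve([1, 2, 3, 10, 11], [False, False, False, True, True])
    assert roc.auc == pytest.approx(1.0)


def test_roc_uninformative_scores_near_half():
    rng = np.random.default_rng(12)
    scores = rng.normal(size=4000)
    labels = rng.random(4000) < 0.3  # independent of scores
    assert vm.roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.03)


@pytest.mark.parametrize("seed", range(8))
def test_roc_auc_equals_pair_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    # integer scores force ties, exercising the half-credit convention
    scores = rng.integers(-10, 0, size=40).astype(float)
    labels = rng.random(40) < 0.4
    if labels.all() or not labels.any():
        pytest.skip("degenerate draw")
    roc = vm.roc_curve(scores, labels)
    assert roc.auc == pytest.approx(_pair_auc(scores, labels))


def test_roc_curve_shape_and_conventions():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=60)
    labels = rng.random(60) < 0.5
    roc = vm.roc_curve(scores, labels)
    assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
    assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
    assert math.isinf(roc.thresholds[0])


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(9)
    scores = rng.normal(size=200)
    labels = rng.random(200) < 1 / (1 + np.exp(-scores))
    a1 = vm.roc_curve(scores, labels).auc
    a2 = vm.roc_curve(np.exp(scores / 2), labels).auc  # strictly monotone map
    assert a1 == pytest.approx(a2)


def test_roc_single_class_is_error():
    with pytest.raises(ValueError):
        vm.roc_curve([1.0, 2.0], [True, True])


def test_roc_matches_sklearn_reference():
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(21)
    scores = np.round(rng.normal(size=500), 1)
    labels = rng.random(500) < 1 / (1 + np.exp(-1.5 * scores))
    assert vm.roc_curve(scores, labels).auc == pytest.approx(
        sklearn.roc_auc_score(labels, scores)
    )


def test_delong_interval_behaviour():
    rng = np.random.default_rng(31)
    scores = rng.normal(size=650)
    labels = rng.random(650) < 1 / (1 + np.exp(-2 * scores - 2.8))
    auc, (lo, hi) = vm.delong_auc_ci(scores, labels)
    assert 0.5 < lo < auc < hi <= 1.0
    auc_hm, (lo_hm, hi_hm) = vm.hanley_mcneil_auc_ci(scores, labels)
    assert auc_hm == pytest.approx(auc)
    assert hi_hm - lo_hm == pytest.approx(hi - lo, rel=0.5)  # same order of width


# ---------------------------------------------------------------------------
# two-cohort comparison
# ---------------------------------------------------------------------------

def _cohort_scores(seed):
    cohort, truth = generate_cohort(
        GeneratorConfig(n_patients=250, p_covariate_missing=0.0, seed=seed)
    )
    return truth.true_scores, truth.erc_labels


def test_compare_cutoffs_identical_cohorts_identical_metrics():
    s, y = _cohort_scores(3)
    table, best = vm.compare_cutoffs(s, y, s, y, cutoffs=[-7.2, -6.7])
    a = table[table.cohort == "A"].drop(columns="cohort").reset_index(drop=True)
    b = table[table.cohort == "B"].drop(columns="cohort").reset_index(drop=True)
    assert a.equals(b)


def test_compare_cutoffs_single_candidate_single_row_per_cohort():
    s, y = _cohort_scores(4)
    table, best = vm.compare_cutoffs(s, y, s, y, cutoffs=[-7.2])
    assert len(table) == 2 and best == -7.2


def test_max_min_youden_recovers_generator_optimum():
    """Derivation/validation pair from one score model: the recommended
    cutoff performs within tolerance of the generator's own optimum."""
    cfg = GeneratorConfig(n_patients=400, p_covariate_missing=0.0, seed=6)
    sa, ya = _cohort_scores(6)
    sb, yb = _cohort_scores(7)
    grid = np.arange(-9.0, -5.0, 0.1)
    _, best = vm.compare_cutoffs(sa, ya, sb, yb, cutoffs=grid)
    # generator-implied Youden over the same grid, huge-sample evaluation
    youden = np.array(
        [
            analytic_operating_point(cfg, c, n_mc=120_000)["sensitivity"]
            + analytic_operating_point(cfg, c, n_mc=120_000)["specificity"]
            - 1.0
            for c in grid
        ]
    )
    achieved = youden[int(np.argmin(np.abs(grid - best)))]
    assert achieved >= youden.max() - 0.10
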