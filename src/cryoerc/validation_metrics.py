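"""Diagnostic-accuracy metrics for the ERC score validation.

Covers the full external-validation toolkit: confusion counts at a score
cutoff (prediction positive iff score >= cutoff, matching the
classifier's tie rule), sensitivity/specificity, likelihood ratios,
predictive values at an *explicit* prevalence (Bayes, decoupled from the
complete-case sample's class balance), the expected-count projections
(sensitivity x number of diseased veins, rounded to whole veins), the
empirical ROC curve with trapezoidal AUC and a DeLong 95% CI, and a
two-cohort cutoff comparison with a max-min Youden recommendation.

Likelihood ratios and predictive values relate through the odds form of
Bayes' theorem: post-test odds = LR * pre-test odds, i.e.
ppv/(1-ppv) = LR+ * p/(1-p). The study's headline numbers use the
cohort-level vein prevalence (41/774 = 5.30%), not the complete-case
subset prevalence — hence the explicit ``prevalence`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .erc_model import CLASSIFY_ATOL

__all__ = [
    "ConfusionCounts",
    "MetricsBundle",
    "RocCurve",
    "confusion_at_cutoff",
    "metrics_from_confusion",
    "metrics_from_rates",
    "expected_counts",
    "ExpectedCounts",
    "roc_curve",
    "delong_auc_ci",
    "compare_cutoffs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class MetricsBundle:
    """All derived diagnostic metrics at one cutoff.

    ``lr_pos`` is ``inf`` (with ``lr_pos_undefined``) when specificity is
    exactly 1; likewise ``lr_neg`` when specificity is 0.
    """

    cutoff: Optional[float]
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    ppv: float
    npv: float
    prevalence_used: float
    youden: float
    counts: Optional[ConfusionCounts] = None
    lr_pos_undefined: bool = False
    lr_neg_undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "ppv": self.ppv,
            "npv": self.npv,
            "prevalence_used": self.prevalence_used,
            "youden": self.youden,
        }


def _as_arrays(scores: Sequence[float], labels: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D sequences of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return s, y


def confusion_at_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    cutoff: float,
    atol: float = CLASSIFY_ATOL,
) -> ConfusionCounts:
    """Exact confusion counts with the >= cutoff positivity convention."""
    s, y = _as_arrays(scores, labels)
    pred = s >= cutoff - atol
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
    )


def metrics_from_rates(
    sensitivity: float,
    specificity: float,
    prevalence: float,
    cutoff: Optional[float] = None,
    counts: Optional[ConfusionCounts] = None,
) -> MetricsBundle:
    """Bundle built from sensitivity/specificity and a chosen prevalence.

    This is the form the study's printed operating points take: predictive
    values come from Bayes at the supplied prevalence, likelihood ratios
    from the rates alone.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must be in [0, 1]")
    lr_pos_undef = specificity == 1.0
    lr_neg_undef = specificity == 0.0
    lr_pos = math.inf if lr_pos_undef else sensitivity / (1.0 - specificity)
    lr_neg = math.inf if lr_neg_undef else (1.0 - sensitivity) / specificity
    p, q = prevalence, 1.0 - prevalence
    pos_mass = sensitivity * p + (1.0 - specificity) * q
    neg_mass = specificity * q + (1.0 - sensitivity) * p
    ppv = sensitivity * p / pos_mass if pos_mass > 0 else float("nan")
    npv = specificity * q / neg_mass if neg_mass > 0 else float("nan")
    return MetricsBundle(
        cutoff=cutoff,
        sensitivity=sensitivity,
        specificity=specificity,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ppv=ppv,
        npv=npv,
        prevalence_used=prevalence,
        youden=sensitivity + specificity - 1.0,
        counts=counts,
        lr_pos_undefined=lr_pos_undef,
        lr_neg_undefined=lr_neg_undef,
    )


def metrics_from_confusion(
    c: ConfusionCounts,
    prevalence: Optional[float] = None,
    cutoff: Optional[float] = None,
) -> MetricsBundle:
    """Derive the metric bundle from confusion counts.

    ``prevalence`` defaults to the sample prevalence (in which case
    ppv = tp/(tp+fp) and npv = tn/(tn+fn) exactly); pass the cohort-level
    prevalence to reproduce the study's headline predictive values.
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    if prevalence is None:
        prevalence = c.n_pos / c.total
    return metrics_from_rates(
        sensitivity=c.tp / c.n_pos,
        specificity=c.tn / c.n_neg,
        prevalence=prevalence,
        cutoff=cutoff,
        counts=c,
    )


@dataclass(frozen=True)
class ExpectedCounts:
    predicted_tp: int
    predicted_fp: int
    predicted_missed: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def expected_counts(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ExpectedCounts:
    """Projected whole-vein counts at an operating point.

    predicted_tp = sensitivity * n_pos, predicted_fp =
    (1-specificity) * n_neg, predicted_missed = (1-sensitivity) * n_pos;
    each rounded to the nearest whole vein (half away from zero).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must be proportions in [0, 1]")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    return ExpectedCounts(
        predicted_tp=_round_half_away(sensitivity * n_pos),
        predicted_fp=_round_half_away((1.0 - specificity) * n_neg),
        predicted_missed=_round_half_away((1.0 - sensitivity) * n_pos),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Empirical ROC: one operating point per distinct score threshold.

    ``fpr``/``tpr`` are monotone non-decreasing and include the (0,0) and
    (1,1) endpoints; ``thresholds`` aligns with the points ((+inf) for the
    origin). ``auc_ci`` is the 95% interval, DeLong by default.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    ci_method: str = "delong"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _delong_components(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    pos, neg = s[y], s[~y]
    # placement values: V10_i = P(score_neg < pos_i) + 0.5 P(=), and dual
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(v10.mean()), v10, v01


def delong_auc_ci(
    scores: Sequence[float], labels: Sequence[bool], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Empirical AUC with its DeLong (1988) asymptotic confidence interval.

    The AUC is the Mann-Whitney two-sample statistic (ties count one
    half); its variance combines the sample variances of the per-positive
    and per-negative placement values.
    """
    s, y = _as_arrays(scores, labels)
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    auc, v10, v01 = _delong_components(s, y)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def hanley_mcneil_auc_ci(
    scores: Sequence[float], labels: Sequence[bool], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Hanley-McNeil (1982) binormal-free variance approximation."""
    s, y = _as_arrays(scores, labels)
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    auc, _, _ = _delong_components(s, y)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci_method: str = "delong",
) -> RocCurve:
    """Empirical ROC with thresholds swept over the distinct scores.

    Positivity is score >= threshold, matching the classifier. The AUC is
    the trapezoidal area, identical to the Mann-Whitney pair statistic.
    """
    s, y = _as_arrays(scores, labels)
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("ROC needs at least one positive and one negative")

    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # index of the last occurrence of each distinct score
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / m]
    fpr = np.r_[0.0, fps / n]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))

    if ci_method == "delong":
        _, ci = delong_auc_ci(s, y)
    elif ci_method == "hanley-mcneil":
        _, ci = hanley_mcneil_auc_ci(s, y)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc, auc_ci=ci,
                    ci_method=ci_method)


# ---------------------------------------------------------------------------
# two-cohort cutoff comparison
# ---------------------------------------------------------------------------

def compare_cutoffs(
    scores_a: Sequence[float],
    labels_a: Sequence[bool],
    scores_b: Sequence[float],
    labels_b: Sequence[bool],
    cutoffs: Optional[Sequence[float]] = None,
    prevalence_a: Optional[float] = None,
    prevalence_b: Optional[float] = None,
    cohort_names: tuple[str, str] = ("A", "B"),
) -> tuple[pd.DataFrame, float]:
    """Metrics for candidate cutoffs in two cohorts, plus a recommendation.

    When ``cutoffs`` is omitted, every distinct score in either cohort is
    a candidate. The recommended cutoff maximises the minimum Youden index
    (sens + spec - 1) across the two cohorts — a reproducible surrogate
    for eyeballing overlaid ROC coordinates; ties break toward the lower
    (more sensitive) cutoff.

    Returns the long-format metrics table and the recommended cutoff.
    """
    sa, ya = _as_arrays(scores_a, labels_a)
    sb, yb = _as_arrays(scores_b, labels_b)
    for s, y, nm in ((sa, ya, cohort_names[0]), (sb, yb, cohort_names[1])):
        if y.sum() == 0 or (~y).sum() == 0:
            raise ValueError(f"cohort {nm} is degenerate (single class)")
    if cutoffs is None:
        cutoffs = np.unique(np.concatenate([sa, sb]))
    cutoffs = sorted(float(c) for c in cutoffs)

    rows = []
    best_cutoff, best_obj = None, -math.inf
    for c in cutoffs:
        bundles = []
        for s, y, prev, nm in (
            (sa, ya, prevalence_a, cohort_names[0]),
            (sb, yb, prevalence_b, cohort_names[1]),
        ):
            conf = confusion_at_cutoff(s, y, c)
            bundle = metrics_from_confusion(conf, prevalence=prev, cutoff=c)
            bundles.append(bundle)
            rows.append({"cohort": nm, **bundle.as_dict(),
                         "tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn})
        obj = min(b.youden for b in bundles)
        if obj > best_obj:  # strict: ties keep the earlier (lower) cutoff
            best_obj, best_cutoff = obj, c
    return pd.DataFrame(rows), float(best_cutoff)
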