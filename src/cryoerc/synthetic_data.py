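"""Synthetic cohorts, freeze traces, and follow-up with known ground truth.

The generator emulates the statistical structure the validation analysis
assumes, so every stage of the pipeline can be exercised end-to-end
without patient data:

* per-vein predictors drawn from group-conditional laws calibrated to the
  study population summaries — TTI log-normal (median 40 s, IQR 27-60 s
  without ERC; 50 s, 38-75 s with), nadir balloon temperature normal
  (median -47 deg C, IQR [-51, -43] without ERC; -41, [-45, -38] with),
  unsuccessful-application count zero-inflated geometric (any-unsuccessful
  probability 21.2% vs 36.6%);
* ERC labels assigned by a logistic model on the true risk score, with the
  intercept calibrated so the vein-level prevalence hits its target
  (5.30% by default) and an optional patient-level random effect for
  within-patient clustering;
* stylized temperature-time traces (exponential approach to the nadir,
  hold, exponential-plus-linear rewarm, 1 Hz sampling) whose feature
  values have closed forms, returned alongside for oracle testing;
* follow-up timelines emitted per censoring/exclusion category with exact
  counts, so the survival module's bookkeeping can be checked against
  construction.

Same seed and config give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort_model import (
    VEIN_LABELS,
    ApplicationTrace,
    Cohort,
    ErcStatus,
    PatientRecord,
    VeinRecord,
)
from .erc_model import ScoreParams
from .survival import FollowupRecord, SurvivalEntry

__all__ = [
    "GroupDistributions",
    "GeneratorConfig",
    "CohortGroundTruth",
    "generate_cohort",
    "analytic_operating_point",
    "TraceGroundTruth",
    "generate_trace",
    "FollowupScenario",
    "CATEGORY_DISPOSITION",
    "generate_followup",
    "simulate_survival_entries",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def lognormal_from_median_iqr(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching a median and quartile pair."""
    q1, q3 = iqr
    if not (0 < q1 < q3) or median <= 0:
        raise ValueError(f"infeasible log-normal calibration: median={median}, IQR={iqr}")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


def normal_from_median_iqr(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mean, sd) of a normal matching a median and quartile pair."""
    q1, q3 = iqr
    if q3 <= q1:
        raise ValueError(f"infeasible normal calibration: IQR={iqr}")
    return median, (q3 - q1) / (2.0 * _Z75)


@dataclass(frozen=True)
class GroupDistributions:
    """Covariate laws for one latent group (with / without ERC)."""

    tti_median_s: float
    tti_iqr_s: tuple[float, float]
    nadir_median_c: float
    nadir_iqr_c: tuple[float, float]
    p_any_unsuccessful: float
    unsuccessful_geom_p: float = 0.6  # count | >=1 is 1 + Geometric

    def __post_init__(self) -> None:
        lognormal_from_median_iqr(self.tti_median_s, self.tti_iqr_s)
        normal_from_median_iqr(self.nadir_median_c, self.nadir_iqr_c)
        if not (0.0 <= self.p_any_unsuccessful <= 1.0):
            raise ValueError("p_any_unsuccessful must be a probability")
        if not (0.0 < self.unsuccessful_geom_p <= 1.0):
            raise ValueError("unsuccessful_geom_p must be in (0, 1]")


#: study-population covariate summaries used as calibration targets
NON_ERC_DISTS = GroupDistributions(40.0, (27.0, 60.0), -47.0, (-51.0, -43.0), 0.212)
ERC_DISTS = GroupDistributions(50.0, (38.0, 75.0), -41.0, (-45.0, -38.0), 0.366)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator configuration; defaults emulate the study cohort."""

    n_patients: int = 201
    veins_per_patient: int = 4
    erc_prevalence_target: float = 0.053
    non_erc: GroupDistributions = NON_ERC_DISTS
    erc: GroupDistributions = ERC_DISTS
    patient_random_effect_sd: float = 0.0  # score units on the linear predictor
    # logistic slope per score unit; 0 = labels carry no signal. The default
    # puts the score's large-sample AUC near the 0.77 observed discrimination.
    outcome_slope: float = 0.73
    outcome_intercept: Optional[float] = None  # None -> calibrated to prevalence
    p_covariate_missing: float = 0.053     # per covariate, independent
    p_untested_patient: float = 0.0        # whole patients without adenosine testing
    score_params: ScoreParams = ScoreParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.veins_per_patient <= 4):
            raise ValueError("veins_per_patient must be 1..4 (standard anatomy)")
        for name in ("erc_prevalence_target", "p_covariate_missing", "p_untested_patient"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.patient_random_effect_sd < 0:
            raise ValueError("patient_random_effect_sd must be >= 0")


@dataclass
class CohortGroundTruth:
    """What the generator knows that an analyst would not."""

    config: GeneratorConfig
    outcome_intercept: float
    vein_patient_ids: list[str]
    vein_labels: list[str]
    latent_group: np.ndarray       # bool, the covariate-law group per vein
    true_scores: np.ndarray        # score before any missingness masking
    erc_labels: np.ndarray         # bool, the drawn outcome per vein
    patient_effects: dict[str, float]


def _draw_covariates(rng: np.random.Generator, dist: GroupDistributions, n: int):
    mu, sigma = lognormal_from_median_iqr(dist.tti_median_s, dist.tti_iqr_s)
    tti = rng.lognormal(mean=mu, sigma=sigma, size=n)
    mean, sd = normal_from_median_iqr(dist.nadir_median_c, dist.nadir_iqr_c)
    nadir = rng.normal(loc=mean, scale=sd, size=n)
    any_u = rng.random(n) < dist.p_any_unsuccessful
    counts = np.where(any_u, rng.geometric(dist.unsuccessful_geom_p, size=n), 0)
    return tti, nadir, counts


def _draw_population(config: GeneratorConfig, rng: np.random.Generator):
    """Vectorized draw of the vein-level population (arrays only)."""
    n_veins_total = config.n_patients * config.veins_per_patient

    latent = rng.random(n_veins_total) < config.erc_prevalence_target
    tti = np.empty(n_veins_total)
    nadir = np.empty(n_veins_total)
    counts = np.empty(n_veins_total, dtype=int)
    n_erc = int(latent.sum())
    # draw group-by-group with a single stream; order is seed-deterministic
    tti[latent], nadir[latent], counts[latent] = _draw_covariates(rng, config.erc, n_erc)
    tti[~latent], nadir[~latent], counts[~latent] = _draw_covariates(
        rng, config.non_erc, n_veins_total - n_erc
    )

    p = config.score_params  # identical arithmetic to erc_score, vectorized
    scores = p.coef_tti * tti + p.coef_unsuccessful * counts + p.coef_nadir * nadir

    if config.patient_random_effect_sd > 0:
        per_patient = rng.normal(0.0, config.patient_random_effect_sd, config.n_patients)
    else:
        per_patient = np.zeros(config.n_patients)
    eff = np.repeat(per_patient, config.veins_per_patient)

    lin = config.outcome_slope * scores + eff
    if config.outcome_intercept is None:
        target = config.erc_prevalence_target

        def gap(a: float) -> float:
            return float(np.mean(expit(a + lin))) - target

        intercept = brentq(gap, -60.0, 60.0)
    else:
        intercept = config.outcome_intercept
    labels = rng.random(n_veins_total) < expit(intercept + lin)
    return tti, nadir, counts, scores, latent, per_patient, float(intercept), labels


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> tuple[Cohort, CohortGroundTruth]:
    """Draw a cohort with ground truth.

    Veins get a latent group (ERC-like covariate law with probability
    equal to the prevalence target), covariates from that group's laws,
    and an ERC label from a logistic model on the true score (intercept
    calibrated on the drawn scores so the expected label prevalence equals
    the target). Missingness and untested status are applied after the
    ground truth is recorded, so the truth stays complete.
    """
    rng = np.random.default_rng(config.seed)
    n_veins_total = config.n_patients * config.veins_per_patient
    tti, nadir, counts, scores, latent, per_patient, intercept, labels = _draw_population(
        config, rng
    )

    patient_ids = [f"P{i:04d}" for i in range(config.n_patients)]
    effects = dict(zip(patient_ids, per_patient.tolist()))
    vein_pids = [pid for pid in patient_ids for _ in range(config.veins_per_patient)]
    vein_labels = [
        VEIN_LABELS[k] for _ in patient_ids for k in range(config.veins_per_patient)
    ]

    # observed records: mask covariates / testing status after truth is kept
    miss = rng.random((n_veins_total, 3)) < config.p_covariate_missing
    untested_patients = {
        pid for pid in patient_ids if rng.random() < config.p_untested_patient
    }
    # spontaneous-vs-adenosine split among ERC veins (19 vs 23 in the study)
    spontaneous = rng.random(n_veins_total) < 19.0 / 41.0

    patients = []
    i = 0
    for pid in patient_ids:
        veins = []
        for k in range(config.veins_per_patient):
            if pid in untested_patients:
                status = ErcStatus.UNTESTED
            elif labels[i]:
                status = (
                    ErcStatus.RECONNECTION_PRE_ADENOSINE
                    if spontaneous[i]
                    else ErcStatus.DORMANT_WITH_ADENOSINE
                )
            else:
                status = ErcStatus.NONE
            veins.append(
                VeinRecord(
                    patient_id=pid,
                    vein_label=VEIN_LABELS[k],
                    tti_s=None if miss[i, 0] else round(float(tti[i]), 1),
                    n_unsuccessful=None if miss[i, 1] else int(counts[i]),
                    nadir_temp_c=None if miss[i, 2] else round(float(nadir[i]), 1),
                    erc_status=status,
                )
            )
            i += 1
        patients.append(PatientRecord(patient_id=pid, vein_records=veins))

    truth = CohortGroundTruth(
        config=config,
        outcome_intercept=float(intercept),
        vein_patient_ids=vein_pids,
        vein_labels=vein_labels,
        latent_group=latent,
        true_scores=scores,
        erc_labels=labels,
        patient_effects=effects,
    )
    return Cohort(patients=patients, name=f"synthetic-seed{config.seed}"), truth


def analytic_operating_point(
    config: GeneratorConfig,
    cutoff: float,
    n_mc: int = 200_000,
    seed: Optional[int] = None,
) -> dict[str, float]:
    """Generator-implied sensitivity/specificity/AUC at a cutoff.

    Monte-Carlo evaluation of the generative model itself (no missingness,
    huge n, its own stream) — the reference the finite-sample pipeline is
    compared against in recovery tests.
    """
    mc_seed = (config.seed + 101) % (2**31) if seed is None else seed
    big = replace(
        config,
        n_patients=max(1, n_mc // config.veins_per_patient),
        p_covariate_missing=0.0,
        p_untested_patient=0.0,
        outcome_intercept=None,
        seed=mc_seed,
    )
    _, _, _, s, _, _, _, y = _draw_population(big, np.random.default_rng(big.seed))
    pred = s >= cutoff
    sens = float(np.mean(pred[y])) if y.any() else float("nan")
    spec = float(np.mean(~pred[~y]))
    # AUC via the rank form of the Mann-Whitney statistic
    from scipy.stats import rankdata

    r = rankdata(s)
    m = int(y.sum())
    auc = (r[y].sum() - m * (m + 1) / 2.0) / (m * (y.size - m))
    return {
        "sensitivity": sens,
        "specificity": spec,
        "prevalence": float(np.mean(y)),
        "auc": float(auc),
    }


# ---------------------------------------------------------------------------
# freeze traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceGroundTruth:
    """Closed-form feature values of the noiseless generating curve."""

    nadir_c: float
    nadir_time_s: float
    freeze_auc: float
    time_below_zero_s: float
    freeze_magnitude: float
    temp_at_30s: float
    temp_at_60s: float
    warming_time_to_0: float
    warming_time_to_15: Optional[float]
    warming_time_to_20: Optional[float]
    warming_truncated: bool


_T_START = 20.0   # balloon temperature at application start, deg C
_TAU_COOL = 25.0  # cooling time constant, s
_TAU_WARM = 5.0   # fast rewarm time constant, s
_WARM_EXP = 55.0  # amplitude of the exponential rewarm component, deg C
_WARM_LIN = 0.25  # slow linear rewarm rate, deg C/s
_TRUNC_TEMP = 12.0  # deflation cuts the record at this rewarm temperature
_END_TEMP = 25.0    # full records end here


def _cooling(t: np.ndarray | float, nadir: float) -> np.ndarray | float:
    return nadir + (_T_START - nadir) * np.exp(-np.asarray(t, dtype=float) / _TAU_COOL)


def _warming(delta: np.ndarray | float, t_nadir_temp: float) -> np.ndarray | float:
    d = np.asarray(delta, dtype=float)
    return t_nadir_temp + _WARM_EXP * (1.0 - np.exp(-d / _TAU_WARM)) + _WARM_LIN * d


def generate_trace(
    tti_s: float,
    nadir_c: float,
    deflation_truncated: bool = False,
    seed: int = 0,
    noise_sd_c: float = 0.0,
) -> tuple[ApplicationTrace, TraceGroundTruth]:
    """Stylized 1 Hz cryo-application trace plus its closed-form features.

    Freeze phase: exponential approach from 20 deg C toward ``nadir_c``
    over the protocol ablation time (TTI + 150 s, capped at 240 s), which
    holds the curve near the nadir; rewarm: fast exponential plus a slow
    linear drift. Optional Gaussian jitter (sd ``noise_sd_c``, default
    off: console noise artifacts are out of scope and a jittered flat
    freeze bottom makes the sampled nadir time — the warming anchor —
    ill-determined); the ground truth always refers to the noiseless
    curve.
    """
    if nadir_c >= 0:
        raise ValueError("nadir_c must be below 0 deg C")
    rng = np.random.default_rng(seed)
    # ablation runs TTI + 150 s (protocol), on the console's 1 Hz grid so
    # the sampled nadir coincides with the true freeze end
    freeze_end = float(min(round(tti_s) + 150.0, 240.0))
    temp_at_freeze_end = float(_cooling(freeze_end, nadir_c))

    # analytic sub-zero area: cooling branch
    t_cross_cool = _TAU_COOL * math.log((_T_START - nadir_c) / (-nadir_c))

    def cool_integral(a: float, b: float) -> float:
        # integral of the cooling curve
        return nadir_c * (b - a) - _TAU_COOL * (_T_START - nadir_c) * (
            math.exp(-b / _TAU_COOL) - math.exp(-a / _TAU_COOL)
        )

    def warm_integral(d: float) -> float:
        # integral of the warming curve over [0, d] (delta from freeze end)
        return (
            temp_at_freeze_end * d
            + _WARM_EXP * (d + _TAU_WARM * (math.exp(-d / _TAU_WARM) - 1.0))
            + _WARM_LIN * d * d / 2.0
        )

    def warm_crossing(threshold: float) -> float:
        return brentq(
            lambda d: float(_warming(d, temp_at_freeze_end)) - threshold, 0.0, 1000.0
        )

    d_zero = warm_crossing(0.0)
    d_trunc = warm_crossing(_TRUNC_TEMP)
    d_end = warm_crossing(_END_TEMP)
    d_last = d_trunc if deflation_truncated else d_end

    auc = -(cool_integral(t_cross_cool, freeze_end) + warm_integral(d_zero))
    below = (freeze_end - t_cross_cool) + d_zero

    def warm_time_or_truncated(threshold: float) -> tuple[Optional[float], bool]:
        d = warm_crossing(threshold)
        if d <= d_last:
            return d, False
        return (d_last, True) if deflation_truncated else (None, False)

    w15, tr15 = warm_time_or_truncated(15.0)
    w20, tr20 = warm_time_or_truncated(20.0)
    truth = TraceGroundTruth(
        nadir_c=temp_at_freeze_end,
        nadir_time_s=freeze_end,
        freeze_auc=auc,
        time_below_zero_s=below,
        freeze_magnitude=auc / below,
        temp_at_30s=float(_cooling(30.0, nadir_c)),
        temp_at_60s=float(_cooling(60.0, nadir_c)),
        warming_time_to_0=d_zero,
        warming_time_to_15=w15,
        warming_time_to_20=w20,
        warming_truncated=tr15 or tr20,
    )

    times = np.arange(0.0, freeze_end + d_last + 1.0, 1.0)
    temps = np.where(
        times <= freeze_end,
        _cooling(times, nadir_c),
        _warming(np.maximum(times - freeze_end, 0.0), temp_at_freeze_end),
    )
    if noise_sd_c > 0:
        temps = temps + rng.normal(0.0, noise_sd_c, size=temps.size)
    trace = ApplicationTrace(
        times_s=times,
        temps_c=temps,
        tti_s=float(tti_s),
        deflation_truncated=deflation_truncated,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# follow-up
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FollowupScenario:
    """Counts per follow-up category; defaults mirror the study accounting
    (158 patients entering the curve: 35 events + 31 censored early + 92
    administratively; 43 not entering: 23 recurrence-on-AAD without an
    off-drug spell, 7 drug-covered follow-up only, 13 unusable)."""

    n_event_off_aad: int = 35
    n_censored_before_horizon: int = 31
    n_censored_at_horizon: int = 92
    n_recurrence_on_aad_censored: int = 0  # AAD-free spell, then recurred on AAD
    n_recurrence_on_aad_excluded: int = 23
    n_aad_only: int = 7
    n_no_followup: int = 13

    @property
    def total(self) -> int:
        return (
            self.n_event_off_aad
            + self.n_censored_before_horizon
            + self.n_censored_at_horizon
            + self.n_recurrence_on_aad_censored
            + self.n_recurrence_on_aad_excluded
            + self.n_aad_only
            + self.n_no_followup
        )


#: expected disposition of each category in the survival bookkeeping
CATEGORY_DISPOSITION = {
    "event_off_aad": ("entered", "event"),
    "censored_before_horizon": ("entered", "censored"),
    "censored_at_horizon": ("entered", "censored"),
    "recurrence_on_aad_censored": ("entered", "censored"),
    "recurrence_on_aad_excluded": ("excluded", "aad_only"),
    "aad_only": ("excluded", "aad_only"),
    "no_followup": ("excluded", "missing_followup"),
}


def generate_followup(
    scenario: FollowupScenario = FollowupScenario(),
    seed: int = 0,
    patient_ids: Optional[Sequence[str]] = None,
    ablation_date: date = date(2019, 1, 8),
    blanking_days: int = 90,
    horizon_days: int = 365,
) -> tuple[list[FollowupRecord], dict[str, str]]:
    """Emit follow-up records with exact per-category counts.

    Returns the records and a patient-id -> category map (the ground
    truth for bookkeeping tests). When ``patient_ids`` is supplied its
    length must equal ``scenario.total`` and categories are assigned to a
    seed-deterministic shuffle of those ids.
    """
    rng = np.random.default_rng(seed)
    categories = (
        ["event_off_aad"] * scenario.n_event_off_aad
        + ["censored_before_horizon"] * scenario.n_censored_before_horizon
        + ["censored_at_horizon"] * scenario.n_censored_at_horizon
        + ["recurrence_on_aad_censored"] * scenario.n_recurrence_on_aad_censored
        + ["recurrence_on_aad_excluded"] * scenario.n_recurrence_on_aad_excluded
        + ["aad_only"] * scenario.n_aad_only
        + ["no_followup"] * scenario.n_no_followup
    )
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(scenario.total)]
    if len(patient_ids) != scenario.total:
        raise ValueError(
            f"scenario totals {scenario.total} patients but {len(patient_ids)} ids given"
        )
    ids = list(patient_ids)
    order = rng.permutation(len(ids))

    abl = ablation_date
    blank_end = abl + timedelta(days=blanking_days)
    horizon = abl + timedelta(days=horizon_days)
    records: list[FollowupRecord] = []
    category_of: dict[str, str] = {}

    def day(lo: int, hi: int) -> date:
        return abl + timedelta(days=int(rng.integers(lo, hi + 1)))

    for pos, cat in zip(order, categories):
        pid = ids[pos]
        category_of[pid] = cat
        # AADs restarted at ablation, stopped inside blanking unless noted
        aad_stop = abl + timedelta(days=int(rng.integers(30, blanking_days - 5)))
        base_aad = [(abl, aad_stop)]
        if cat == "no_followup":
            rec = FollowupRecord(pid, abl, [], last_followup_date=None)
        elif cat == "aad_only":
            lf = day(180, 430)
            rec = FollowupRecord(
                pid, abl, [(abl, lf)], last_followup_date=lf, last_aad_free_date=None
            )
        elif cat == "recurrence_on_aad_excluded":
            ev = day(blanking_days + 10, horizon_days)
            lf = ev + timedelta(days=int(rng.integers(0, 60)))
            rec = FollowupRecord(
                pid,
                abl,
                [(abl, lf)],
                recurrence_date=ev,
                last_followup_date=lf,
                last_aad_free_date=None,
            )
        elif cat == "recurrence_on_aad_censored":
            resume = day(blanking_days + 40, blanking_days + 120)
            lf = resume + timedelta(days=int(rng.integers(30, 90)))
            rec = FollowupRecord(
                pid,
                abl,
                base_aad + [(resume, lf)],
                recurrence_date=resume + timedelta(days=int(rng.integers(5, 25))),
                last_followup_date=lf,
                last_aad_free_date=resume - timedelta(days=1),
            )
        elif cat == "event_off_aad":
            ev = day(blanking_days + 1, horizon_days - 1)
            rec = FollowupRecord(
                pid,
                abl,
                base_aad,
                recurrence_date=ev,
                last_followup_date=max(ev, horizon),
                last_aad_free_date=max(ev, horizon),
            )
        elif cat == "censored_before_horizon":
            lf = day(blanking_days + 30, horizon_days - 1)
            rec = FollowupRecord(
                pid, abl, base_aad, last_followup_date=lf, last_aad_free_date=lf
            )
        else:  # censored_at_horizon
            lf = day(horizon_days, horizon_days + 60)
            rec = FollowupRecord(
                pid, abl, base_aad, last_followup_date=lf, last_aad_free_date=lf
            )
        records.append(rec)

    records.sort(key=lambda r: r.patient_id)
    return records, category_of


def simulate_survival_entries(
    n_per_group: int,
    hazards_per_day: tuple[float, float],
    censor_day: float = 275.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("non-ERC", "ERC"),
) -> dict[str, list[SurvivalEntry]]:
    """Exponential event times with administrative censoring, per group.

    A minimal two-group survival world for calibration checks (e.g.
    log-rank type-I error under equal hazards).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[SurvivalEntry]] = {}
    for name, hz in zip(group_names, hazards_per_day):
        times = rng.exponential(1.0 / hz, size=n_per_group)
        entries = [
            SurvivalEntry(
                patient_id=f"{name}-{i}",
                time=float(min(t, censor_day)),
                event=bool(t <= censor_day),
                group=name,
            )
            for i, t in enumerate(times)
        ]
        out[name] = entries
    return out
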