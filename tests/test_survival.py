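"""Blanking/censoring rules, Kaplan-Meier, and the log-rank test."""

import collections
from datetime import date, timedelta

import numpy as np
import pytest

from cryoerc.cohort_model import PatientRecord
from cryoerc.survival import (
    Exclusion,
    FollowupRecord,
    SurvivalEntry,
    build_survival_entries,
    group_entries,
    km_estimate,
    log_rank,
    read_followup_table,
    write_followup_table,
)
from cryoerc.synthetic_data import (
    CATEGORY_DISPOSITION,
    FollowupScenario,
    generate_followup,
    simulate_survival_entries,
)

ABL = date(2020, 1, 1)


def _patient(pid, followup):
    return PatientRecord(patient_id=pid, followup=followup)


def _day(n):
    return ABL + timedelta(days=n)


def test_event_off_aad_counts_days_after_blanking():
    fu = FollowupRecord("P1", ABL, [], recurrence_date=_day(200),
                        last_followup_date=_day(400))
    entries, excl = build_survival_entries([_patient("P1", fu)])
    assert excl == []
    assert entries[0].time == 110 and entries[0].event  # 200 - 90


def test_recurrence_on_aad_censors_at_last_aad_free_date():
    fu = FollowupRecord(
        "P1", ABL,
        aad_intervals=[(_day(151), _day(260))],
        recurrence_date=_day(200),
        last_followup_date=_day(260),
        last_aad_free_date=_day(150),
    )
    entries, excl = build_survival_entries([_patient("P1", fu)])
    assert entries[0].time == 60 and not entries[0].event  # 150 - 90


def test_recurrence_inside_blanking_is_ignored():
    fu = FollowupRecord("P1", ABL, [], recurrence_date=_day(50),
                        last_followup_date=_day(400))
    entries, _ = build_survival_entries([_patient("P1", fu)])
    assert not entries[0].event
    assert entries[0].time == 275  # administratively capped at one year


def test_aad_days_pause_the_survival_clock():
    # on AAD days 121..180 (60 days): censoring at day 300 accrues 150 days
    fu = FollowupRecord("P1", ABL, [(_day(121), _day(180))],
                        last_followup_date=_day(300), last_aad_free_date=_day(300))
    entries, _ = build_survival_entries([_patient("P1", fu)])
    assert entries[0].time == 150
    # reset policy: only the 120 days after the AAD spell count
    entries_r, _ = build_survival_entries([_patient("P1", fu)], aad_gap_policy="reset")
    assert entries_r[0].time == 120


def test_aad_only_followup_is_excluded():
    lf = _day(300)
    fu = FollowupRecord("P1", ABL, [(ABL, lf)], last_followup_date=lf)
    entries, excl = build_survival_entries([_patient("P1", fu)])
    assert entries == [] and excl[0].reason == "aad_only"


def test_missing_and_inconsistent_followup_excluded():
    bad = FollowupRecord("P2", ABL, [], recurrence_date=ABL - timedelta(days=5),
                         last_followup_date=_day(100))
    patients = [_patient("P1", None), _patient("P2", bad)]
    entries, excl = build_survival_entries(patients)
    assert len(entries) + len(excl) == 2
    assert {e.reason for e in excl} == {"missing_followup", "inconsistent_dates"}


def test_generated_scenario_bookkeeping_matches_construction():
    """Entry/exclusion tallies equal the generator's category counts."""
    scenario = FollowupScenario(
        n_event_off_aad=10, n_censored_before_horizon=10, n_censored_at_horizon=10,
        n_recurrence_on_aad_censored=10, n_recurrence_on_aad_excluded=10,
        n_aad_only=10, n_no_followup=10,
    )
    records, categories = generate_followup(scenario, seed=13)
    patients = [_patient(r.patient_id, r) for r in records]
    entries, excl = build_survival_entries(patients)
    assert len(entries) + len(excl) == scenario.total

    entered_ids = {e.patient_id for e in entries}
    event_ids = {e.patient_id for e in entries if e.event}
    excl_reason = {e.patient_id: e.reason for e in excl}
    for pid, cat in categories.items():
        disposition, detail = CATEGORY_DISPOSITION[cat]
        if disposition == "entered":
            assert pid in entered_ids, (pid, cat)
            assert (pid in event_ids) == (detail == "event"), (pid, cat)
        else:
            assert excl_reason[pid] == detail, (pid, cat)


def test_study_default_scenario_accounting():
    records, _ = generate_followup(FollowupScenario(), seed=1)
    patients = [_patient(r.patient_id, r) for r in records]
    entries, excl = build_survival_entries(patients)
    assert len(entries) == 158 and len(excl) == 43
    assert sum(e.event for e in entries) == 35
    reasons = collections.Counter(e.reason for e in excl)
    assert reasons == {"aad_only": 30, "missing_followup": 13}


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def _entries(times, events, group="all"):
    return [
        SurvivalEntry(f"p{i}", t, e, group) for i, (t, e) in enumerate(zip(times, events))
    ]


def test_km_hand_product_limit():
    # events at 1 and 2, censor at 1.5, administrative at 3:
    # S(2) = (3/4) * (1/2) = 0.375
    curve = km_estimate(_entries([1, 1.5, 2, 3], [True, False, True, False]))
    assert curve.at(1) == pytest.approx(0.75)
    assert curve.at(2) == pytest.approx(0.375)
    assert curve.at(2.9) == pytest.approx(0.375)


def test_km_no_events_is_flat_one():
    curve = km_estimate(_entries([10, 20, 30], [False] * 3))
    assert curve.at(30) == 1.0


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(8)
    times = rng.exponential(100, size=200)
    curve = km_estimate(_entries(times, [True] * 200))
    for t in (20, 50, 150):
        assert curve.at(t) == pytest.approx(np.mean(times > t))


def test_km_monotone_within_unit_interval():
    rng = np.random.default_rng(15)
    times = rng.exponential(120, size=100)
    events = rng.random(100) < 0.6
    curve = km_estimate(_entries(times, events))
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))


def test_km_unchanged_when_every_subject_doubled():
    times, events = [1, 1.5, 2, 3], [True, False, True, False]
    single = km_estimate(_entries(times, events))
    double = km_estimate(_entries(times * 2, events * 2))
    assert np.allclose(single.survival, double.survival)
    assert np.allclose(single.times, double.times)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_log_rank_identical_groups_is_null():
    es = _entries([5, 10, 15, 20], [True, True, False, True], "A")
    fs = [SurvivalEntry(e.patient_id + "b", e.time, e.event, "B") for e in es]
    res = log_rank({"A": es, "B": fs})
    assert res["chi_square"] == pytest.approx(0.0, abs=1e-12)
    assert res["p_value"] == pytest.approx(1.0)


def test_log_rank_matches_hand_computed_observed_minus_expected():
    # A: events at 1 and 3; B: event at 2, censored at 4.
    # O_A = 2, E_A = 2/4 + 1/3 + 1/2, V = 1/4 + 2/9 + 1/4
    a = _entries([1, 3], [True, True], "A")
    b = _entries([2, 4], [True, False], "B")
    e_a = 2 / 4 + 1 / 3 + 1 / 2
    var = (2 * 2 * 1 * 3) / (16 * 3) + (1 * 2 * 1 * 2) / (9 * 2) + (1 * 1 * 1 * 1) / 4
    expected_chi = (2 - e_a) ** 2 / var
    res = log_rank({"A": a, "B": b})
    assert res["chi_square"] == pytest.approx(expected_chi)


def test_log_rank_empty_group_is_error():
    with pytest.raises(ValueError):
        log_rank({"A": _entries([1], [True], "A"), "B": []})


def test_log_rank_type_one_error_near_nominal_under_equal_hazards():
    """Hazard-ratio-1 simulation: rejection rate at alpha=0.05 stays near
    nominal and the p-value distribution is close to uniform."""
    pvals = []
    for rep in range(400):
        groups = simulate_survival_entries(40, (0.004, 0.004), seed=1000 + rep)
        pvals.append(log_rank(groups)["p_value"])
    pvals = np.asarray(pvals)
    assert 0.02 <= np.mean(pvals < 0.05) <= 0.08
    grid = np.linspace(0, 1, 21)[1:-1]
    ks = np.max(np.abs([np.mean(pvals <= g) - g for g in grid]))
    assert ks < 0.08


# ---------------------------------------------------------------------------
# IO round trip
# ---------------------------------------------------------------------------

def test_followup_table_round_trip(tmp_path):
    records, _ = generate_followup(
        FollowupScenario(2, 2, 2, 2, 2, 2, 2), seed=3
    )
    path = tmp_path / "fu.csv"
    write_followup_table(records, path)
    back = read_followup_table(path)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert a == b
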