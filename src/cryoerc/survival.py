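"""One-year AF-free, AAD-free survival with blanking and drug-aware censoring.

The endpoint is freedom from atrial arrhythmia *off antiarrhythmic
drugs*. The rules, applied per patient:

* a 90-day post-ablation blanking period: recurrences inside it do not
  count, and patients enter the curve only at its end;
* the survival clock accrues **AAD-free days only** — calendar days spent
  on an AAD after blanking do not add survival time (they pause the
  clock; an optional "reset" policy restarts it after each AAD spell);
* a recurrence while off AAD after blanking is an event;
* a recurrence while on AAD is still a recurrence but cannot count as an
  off-drug event, so the patient is censored at the last AAD-free
  follow-up date; with no AAD-free follow-up at all the patient never
  enters the curve;
* administrative censoring caps follow-up at the one-year horizon.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines; this module owns the timeline construction, which is where the
study-specific content lives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort_model import Cohort, PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FollowupRecord",
    "SurvivalEntry",
    "Exclusion",
    "build_survival_entries",
    "km_estimate",
    "KMCurve",
    "log_rank",
    "read_followup_table",
    "write_followup_table",
    "attach_followup",
]

FOLLOWUP_COLUMNS = [
    "patient_id",
    "ablation_date",
    "recurrence_date",
    "recurrence_on_aad",
    "last_followup_date",
    "last_aad_free_date",
    "aad_intervals",
]


def _merge_intervals(intervals: Sequence[tuple[date, date]]) -> list[tuple[date, date]]:
    """Sort and merge overlapping/adjacent AAD intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[date, date]] = []
    for start, end in ivs:
        if end < start:
            raise ValueError(f"AAD interval end {end} before start {start}")
        if merged and start <= merged[-1][1] + timedelta(days=1):
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class FollowupRecord:
    """Per-patient follow-up timeline.

    ``aad_intervals`` are closed date ranges on antiarrhythmic drugs
    (normalised to non-overlapping on construction).
    ``recurrence_on_aad``, when omitted, is derived from whether the
    recurrence date falls inside an AAD interval.
    """

    patient_id: str
    ablation_date: date
    aad_intervals: list[tuple[date, date]] = field(default_factory=list)
    recurrence_date: Optional[date] = None
    recurrence_on_aad: Optional[bool] = None
    last_followup_date: Optional[date] = None
    last_aad_free_date: Optional[date] = None

    def __post_init__(self) -> None:
        self.aad_intervals = _merge_intervals(self.aad_intervals)
        if self.recurrence_on_aad is None and self.recurrence_date is not None:
            self.recurrence_on_aad = self.on_aad(self.recurrence_date)

    def on_aad(self, day: date) -> bool:
        return any(start <= day <= end for start, end in self.aad_intervals)

    def aad_free_days(self, start_exclusive: date, end_inclusive: date) -> int:
        """Number of AAD-free days in the window (start, end]."""
        if end_inclusive <= start_exclusive:
            return 0
        count = 0
        day = start_exclusive + timedelta(days=1)
        while day <= end_inclusive:
            if not self.on_aad(day):
                count += 1
            day += timedelta(days=1)
        return count


@dataclass(frozen=True)
class SurvivalEntry:
    patient_id: str
    time: float  # AAD-free days since end of blanking
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be >= 0")


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


def _default_group(patient: PatientRecord) -> str:
    return "ERC" if patient.has_erc else "non-ERC"


def build_survival_entries(
    patients: Iterable[PatientRecord] | Cohort,
    blanking_days: int = 90,
    horizon_days: int = 365,
    group_fn=None,
    aad_gap_policy: str = "pause",
) -> tuple[list[SurvivalEntry], list[Exclusion]]:
    """Turn patient follow-up into Kaplan-Meier entries plus an exclusion log.

    Entry count + exclusion count always equals the input patient count.
    Exclusion reasons: ``missing_followup``, ``inconsistent_dates``,
    ``aad_only`` (no AAD-free follow-up time after blanking).

    ``aad_gap_policy``: ``"pause"`` (default) keeps all AAD-free days
    accrued across drug spells; ``"reset"`` counts only the AAD-free days
    after the final AAD interval, restarting the clock after each spell.
    The horizon is days post-ablation; on the AAD-free clock it caps time
    at ``horizon_days - blanking_days``.
    """
    if aad_gap_policy not in ("pause", "reset"):
        raise ValueError("aad_gap_policy must be 'pause' or 'reset'")
    patients = list(patients.patients if isinstance(patients, Cohort) else patients)
    group_fn = group_fn or _default_group
    cap = horizon_days - blanking_days
    entries: list[SurvivalEntry] = []
    exclusions: list[Exclusion] = []

    for p in patients:
        fu: Optional[FollowupRecord] = p.followup
        if fu is None or fu.last_followup_date is None:
            exclusions.append(Exclusion(p.patient_id, "missing_followup"))
            continue
        try:
            _validate_dates(fu)
        except ValueError as exc:
            logger.warning("patient %s excluded: %s", p.patient_id, exc)
            exclusions.append(Exclusion(p.patient_id, "inconsistent_dates"))
            continue

        blank_end = fu.ablation_date + timedelta(days=blanking_days)

        def clock(end: date) -> int:
            if aad_gap_policy == "reset":
                start = blank_end
                for s, e in fu.aad_intervals:
                    if e >= start and s <= end:
                        start = max(start, e)
                return fu.aad_free_days(start, end)
            return fu.aad_free_days(blank_end, end)

        recurred_after_blanking = (
            fu.recurrence_date is not None and fu.recurrence_date > blank_end
        )
        if recurred_after_blanking and not fu.recurrence_on_aad:
            t = clock(fu.recurrence_date)
            if t > cap:  # event beyond the one-year horizon
                entries.append(SurvivalEntry(p.patient_id, cap, False, group_fn(p)))
            else:
                entries.append(SurvivalEntry(p.patient_id, t, True, group_fn(p)))
            continue

        # censoring path: recurrence on AAD, in-blanking recurrence, or none
        if recurred_after_blanking and fu.recurrence_on_aad:
            censor_date = fu.last_aad_free_date
        else:
            censor_date = (
                fu.last_followup_date
                if not fu.on_aad(fu.last_followup_date)
                else fu.last_aad_free_date
            )
        t = clock(censor_date) if censor_date is not None else 0
        if t <= 0:
            exclusions.append(Exclusion(p.patient_id, "aad_only"))
            continue
        entries.append(SurvivalEntry(p.patient_id, min(t, cap), False, group_fn(p)))

    assert len(entries) + len(exclusions) == len(patients)
    reasons = pd.Series([e.reason for e in exclusions]).value_counts().to_dict()
    logger.info(
        "survival accounting: %d entered, %d excluded %s",
        len(entries), len(exclusions), reasons,
    )
    return entries, exclusions


def _validate_dates(fu: FollowupRecord) -> None:
    if fu.last_followup_date < fu.ablation_date:
        raise ValueError("last follow-up precedes ablation")
    if fu.recurrence_date is not None and fu.recurrence_date < fu.ablation_date:
        raise ValueError("recurrence precedes ablation")
    if (
        fu.last_aad_free_date is not None
        and fu.last_aad_free_date > fu.last_followup_date
    ):
        raise ValueError("last AAD-free date after last follow-up")


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival step function."""

    times: np.ndarray      # event/censor times, ascending, starting at 0
    survival: np.ndarray   # S(t) just after each time
    n_entries: int
    n_events: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def km_estimate(entries: Sequence[SurvivalEntry]) -> KMCurve:
    """Kaplan-Meier product-limit estimate (censorings after events at ties)."""
    if len(entries) == 0:
        raise ValueError("need at least one survival entry")
    durations = [e.time for e in entries]
    observed = [e.event for e in entries]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        n_entries=len(entries),
        n_events=int(sum(observed)),
    )


def log_rank(entries_by_group: dict[str, Sequence[SurvivalEntry]]) -> dict[str, float]:
    """Two-group log-rank test (1 df, chi-square, no continuity correction)."""
    if len(entries_by_group) != 2:
        raise ValueError("log-rank comparison requires exactly two groups")
    for name, es in entries_by_group.items():
        if len(es) == 0:
            raise ValueError(f"group {name!r} has no entries")
    durations, events, groups = [], [], []
    for name, es in entries_by_group.items():
        for e in es:
            durations.append(e.time)
            events.append(e.event)
            groups.append(name)
    res = multivariate_logrank_test(durations, groups, events)
    return {"chi_square": float(res.test_statistic), "p_value": float(res.p_value)}


def group_entries(entries: Sequence[SurvivalEntry]) -> dict[str, list[SurvivalEntry]]:
    out: dict[str, list[SurvivalEntry]] = {}
    for e in entries:
        out.setdefault(e.group, []).append(e)
    return out


# ---------------------------------------------------------------------------
# delimited IO
# ---------------------------------------------------------------------------

def _fmt_date(d: Optional[date]) -> str:
    return "" if d is None else d.isoformat()


def _parse_date(cell: object) -> Optional[date]:
    if cell is None or cell == "" or (isinstance(cell, float) and math.isnan(cell)):
        return None
    return date.fromisoformat(str(cell))


def _fmt_intervals(ivs: Sequence[tuple[date, date]]) -> str:
    return ";".join(f"{s.isoformat()}:{e.isoformat()}" for s, e in ivs)


def _parse_intervals(cell: object) -> list[tuple[date, date]]:
    if cell is None or cell == "" or (isinstance(cell, float) and math.isnan(cell)):
        return []
    out = []
    for part in str(cell).split(";"):
        s, e = part.split(":")
        out.append((date.fromisoformat(s), date.fromisoformat(e)))
    return out


def write_followup_table(records: Sequence[FollowupRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "ablation_date": _fmt_date(r.ablation_date),
            "recurrence_date": _fmt_date(r.recurrence_date),
            "recurrence_on_aad": "" if r.recurrence_on_aad is None else r.recurrence_on_aad,
            "last_followup_date": _fmt_date(r.last_followup_date),
            "last_aad_free_date": _fmt_date(r.last_aad_free_date),
            "aad_intervals": _fmt_intervals(r.aad_intervals),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=FOLLOWUP_COLUMNS).to_csv(path, index=False)


def read_followup_table(path: str | Path) -> list[FollowupRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        on_aad = row.get("recurrence_on_aad", "")
        records.append(
            FollowupRecord(
                patient_id=str(row["patient_id"]),
                ablation_date=_parse_date(row["ablation_date"]),
                recurrence_date=_parse_date(row.get("recurrence_date", "")),
                recurrence_on_aad=None if on_aad == "" else on_aad in ("True", "true", "1"),
                last_followup_date=_parse_date(row.get("last_followup_date", "")),
                last_aad_free_date=_parse_date(row.get("last_aad_free_date", "")),
                aad_intervals=_parse_intervals(row.get("aad_intervals", "")),
            )
        )
    return records


def attach_followup(cohort: Cohort, records: Sequence[FollowupRecord]) -> int:
    """Attach follow-up records to cohort patients by id; returns matches."""
    by_id = {r.patient_id: r for r in records}
    n = 0
    for p in cohort.patients:
        if p.patient_id in by_id:
            p.followup = by_id[p.patient_id]
            if p.ablation_date is None:
                p.ablation_date = by_id[p.patient_id].ablation_date
            n += 1
    return n
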