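"""Domain records for cryoballoon PVI cohorts and their delimited-table IO.

The unit of analysis is the pulmonary vein: each :class:`VeinRecord` holds
the three predictors of the ERC risk model (time to isolation, number of
unsuccessful applications, nadir balloon temperature) plus the observed
ERC outcome. Records roll up into :class:`PatientRecord` (at most the four
standard veins) and :class:`Cohort`.

Missing data are represented as ``None`` in records and as empty cells on
disk — never as sentinel numerics, which would silently corrupt the
temperature field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the four standard pulmonary veins; accessory / common-ostium anatomy is
#: out of scope and rejected by the reader with a diagnostic.
VEIN_LABELS: tuple[str, ...] = ("LSPV", "LIPV", "RIPV", "RSPV")

VEIN_TABLE_COLUMNS = [
    "patient_id",
    "vein",
    "tti_s",
    "n_unsuccessful",
    "nadir_temp_c",
    "erc_status",
    "n_bonus",
]


class ErcStatus(str, Enum):
    """Per-vein early-reconnection outcome after the 30-minute wait.

    ``reconnection_pre_adenosine`` — spontaneous reconnection observed
    before adenosine; ``dormant_with_adenosine`` — dormant conduction
    unmasked by adenosine; either counts as ERC. ``untested`` veins carry
    no label and are excluded wherever labels are required.
    """

    NONE = "none"
    RECONNECTION_PRE_ADENOSINE = "reconnection_pre_adenosine"
    DORMANT_WITH_ADENOSINE = "dormant_with_adenosine"
    UNTESTED = "untested"

    @property
    def is_erc(self) -> bool:
        return self in (
            ErcStatus.RECONNECTION_PRE_ADENOSINE,
            ErcStatus.DORMANT_WITH_ADENOSINE,
        )


def _check_nonneg_finite(name: str, value: Optional[float]) -> None:
    if value is None:
        return
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass
class VeinRecord:
    """One pulmonary vein of one patient.

    Parameters
    ----------
    tti_s
        Time to isolation in seconds (electrogram annotation), or ``None``.
    n_unsuccessful
        Number of cryo-applications that failed to isolate the vein.
    nadir_temp_c
        Minimum balloon temperature over the successful application, deg C.
    erc_status
        Observed ERC outcome; ``untested`` if no adenosine test was done.
    n_bonus
        Bonus applications after isolation (descriptive only; not a model
        predictor).
    """

    patient_id: str
    vein_label: str
    tti_s: Optional[float] = None
    n_unsuccessful: Optional[int] = None
    nadir_temp_c: Optional[float] = None
    erc_status: ErcStatus = ErcStatus.UNTESTED
    n_bonus: int = 0

    def __post_init__(self) -> None:
        if self.vein_label not in VEIN_LABELS:
            raise ValueError(
                f"unknown vein label {self.vein_label!r}; expected one of {VEIN_LABELS}"
            )
        _check_nonneg_finite("tti_s", self.tti_s)
        if self.n_unsuccessful is not None:
            if self.n_unsuccessful < 0:
                raise ValueError("n_unsuccessful must be >= 0")
            self.n_unsuccessful = int(self.n_unsuccessful)
        if self.nadir_temp_c is not None and not math.isfinite(self.nadir_temp_c):
            raise ValueError("nadir_temp_c must be finite")
        if self.n_bonus < 0:
            raise ValueError("n_bonus must be >= 0")
        self.erc_status = ErcStatus(self.erc_status)

    @property
    def has_complete_predictors(self) -> bool:
        return (
            self.tti_s is not None
            and self.n_unsuccessful is not None
            and self.nadir_temp_c is not None
        )

    @property
    def erc_label(self) -> Optional[bool]:
        """True/False ERC outcome, or ``None`` when the vein was untested."""
        if self.erc_status is ErcStatus.UNTESTED:
            return None
        return self.erc_status.is_erc


@dataclass
class ApplicationTrace:
    """Temperature-time series of a single cryo-application.

    ``times_s`` must be strictly increasing with at least two samples.
    ``tti_s`` is an electrogram annotation — it cannot be derived from the
    temperature curve. ``deflation_truncated`` marks traces whose recording
    ended at automatic balloon deflation before rewarming was complete; the
    warming-time features then report time-to-deflation with a flag.
    """

    times_s: np.ndarray
    temps_c: np.ndarray
    tti_s: Optional[float] = None
    deflation_truncated: bool = False
    aborted: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.shape != self.temps_c.shape:
            raise ValueError("times_s and temps_c must be 1-D arrays of equal length")
        if self.times_s.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(self.times_s)) and np.all(np.isfinite(self.temps_c))):
            raise ValueError("trace samples must be finite")
        _check_nonneg_finite("tti_s", self.tti_s)

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass
class PatientRecord:
    """One patient: up to four vein records plus optional follow-up."""

    patient_id: str
    ablation_date: Optional[date] = None
    vein_records: list[VeinRecord] = field(default_factory=list)
    followup: Optional[object] = None  # survival.FollowupRecord

    def __post_init__(self) -> None:
        labels = [v.vein_label for v in self.vein_records]
        if len(labels) != len(set(labels)):
            raise ValueError(
                f"patient {self.patient_id}: duplicate vein labels {labels}"
            )
        if len(self.vein_records) > 4:
            raise ValueError("at most 4 veins per patient (standard anatomy)")
        for v in self.vein_records:
            if v.patient_id != self.patient_id:
                raise ValueError("vein record patient_id mismatch")

    @property
    def has_erc(self) -> bool:
        """Patient-level ERC: true iff any vein reconnected or was dormant."""
        return any(v.erc_status.is_erc for v in self.vein_records)


@dataclass
class Cohort:
    patients: list[PatientRecord] = field(default_factory=list)
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_ids must be unique within a cohort")

    def veins(self) -> Iterator[VeinRecord]:
        for p in self.patients:
            yield from p.vein_records

    @property
    def n_veins(self) -> int:
        return sum(len(p.vein_records) for p in self.patients)

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# delimited-table IO
# ---------------------------------------------------------------------------

def _parse_optional_float(cell: object) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    return float(cell)  # may raise ValueError -> row rejected by caller


def _parse_optional_int(cell: object) -> Optional[int]:
    v = _parse_optional_float(cell)
    if v is None:
        return None
    if v != int(v):
        raise ValueError(f"expected integer, got {cell!r}")
    return int(v)


def read_vein_table(path: str | Path, sep: str = ",", name: Optional[str] = None) -> Cohort:
    """Read a per-vein table into a :class:`Cohort`.

    Expected columns: ``patient_id, vein, tti_s, n_unsuccessful,
    nadir_temp_c, erc_status, n_bonus`` (``n_bonus`` optional). Empty cells
    become missing values. Rows with an unknown vein label or an unparsable
    numeric are rejected with a logged diagnostic; a duplicated
    (patient, vein) pair is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"patient_id", "vein", "tti_s", "n_unsuccessful", "nadir_temp_c", "erc_status"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")

    by_patient: dict[str, list[VeinRecord]] = {}
    seen: set[tuple[str, str]] = set()
    n_rejected = 0
    for idx, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        vein = str(row["vein"]).strip()
        key = (pid, vein)
        if key in seen:
            raise ValueError(f"{path} row {idx}: duplicated (patient, vein) pair {key}")
        try:
            rec = VeinRecord(
                patient_id=pid,
                vein_label=vein,
                tti_s=_parse_optional_float(row["tti_s"]),
                n_unsuccessful=_parse_optional_int(row["n_unsuccessful"]),
                nadir_temp_c=_parse_optional_float(row["nadir_temp_c"]),
                erc_status=ErcStatus(str(row["erc_status"]).strip() or "untested"),
                n_bonus=_parse_optional_int(row.get("n_bonus", "")) or 0,
            )
        except ValueError as exc:
            logger.warning("%s row %s rejected: %s", path.name, idx, exc)
            n_rejected += 1
            continue
        seen.add(key)
        by_patient.setdefault(pid, []).append(rec)

    patients = [PatientRecord(patient_id=pid, vein_records=recs) for pid, recs in by_patient.items()]
    if n_rejected:
        logger.info("%s: rejected %d structurally invalid rows", path.name, n_rejected)
    return Cohort(patients=patients, name=name or path.stem)


def write_vein_table(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write a cohort back to the per-vein table format (lossless round-trip)."""
    rows = []
    for v in cohort.veins():
        rows.append(
            {
                "patient_id": v.patient_id,
                "vein": v.vein_label,
                "tti_s": "" if v.tti_s is None else v.tti_s,
                "n_unsuccessful": "" if v.n_unsuccessful is None else v.n_unsuccessful,
                "nadir_temp_c": "" if v.nadir_temp_c is None else v.nadir_temp_c,
                "erc_status": v.erc_status.value,
                "n_bonus": v.n_bonus,
            }
        )
    pd.DataFrame(rows, columns=VEIN_TABLE_COLUMNS).to_csv(path, sep=sep, index=False)


def read_trace(path: str | Path, sep: str = ",", **meta: object) -> ApplicationTrace:
    """Read a two-column ``time_s,temp_c`` trace file; metadata via kwargs."""
    df = pd.read_csv(path, sep=sep)
    if not {"time_s", "temp_c"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, temp_c")
    return ApplicationTrace(df["time_s"].to_numpy(), df["temp_c"].to_numpy(), **meta)


def write_trace(trace: ApplicationTrace, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame({"time_s": trace.times_s, "temp_c": trace.temps_c}).to_csv(
        path, sep=sep, index=False
    )


def read_trace_manifest(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Manifest CSV with columns ``trace_file, tti_s, deflation_truncated, aborted``."""
    df = pd.read_csv(path, sep=sep)
    if "trace_file" not in df.columns:
        raise ValueError(f"{path}: manifest needs a trace_file column")
    return df


def iter_manifest_traces(
    manifest: pd.DataFrame, root: str | Path
) -> Iterator[tuple[str, ApplicationTrace]]:
    root = Path(root)
    for _, row in manifest.iterrows():
        tti = row.get("tti_s")
        trace = read_trace(
            root / str(row["trace_file"]),
            tti_s=None if pd.isna(tti) else float(tti),
            deflation_truncated=bool(row.get("deflation_truncated", False)),
            aborted=bool(row.get("aborted", False)),
        )
        yield str(row["trace_file"]), trace


# ---------------------------------------------------------------------------
# completeness filtering
# ---------------------------------------------------------------------------

def filter_complete_veins(
    cohort: Cohort | Iterable[VeinRecord], require_tested: bool = True
) -> list[VeinRecord]:
    """Return veins with all three model predictors present.

    With ``require_tested`` (default), veins whose ERC status is
    ``untested`` are also dropped, so the result is directly usable for
    validation against observed outcomes. Idempotent; retained/dropped
    counts are logged.
    """
    veins: Iterable[VeinRecord]
    veins = cohort.veins() if isinstance(cohort, Cohort) else cohort
    kept, dropped = [], 0
    for v in veins:
        ok = v.has_complete_predictors and (
            not require_tested or v.erc_status is not ErcStatus.UNTESTED
        )
        if ok:
            kept.append(v)
        else:
            dropped += 1
    logger.info("filter_complete_veins: retained %d, dropped %d", len(kept), dropped)
    return kept
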