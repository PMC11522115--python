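"""The ERC risk score, its cutoff classifier, and the bedside decision table.

The score is a fixed linear combination of three per-vein procedural
predictors:

    score = 0.02 * TTI(s) + 0.5 * n_unsuccessful + 0.2 * nadir(deg C)

The coefficients were estimated on an earlier derivation cohort and are
taken as given here. A vein is flagged for ERC testing when its score is
*equal to or above* the cutoff (ties count as positive): -6.7 is the
original operating point, -7.2 the common operating point chosen to work
in both the derivation and validation cohorts.

Because the score is linear and the TTI coefficient positive, the cutoff
inverts to a minimal test-triggering TTI for every (nadir, unsuccessful
count) pair — the decision table a proceduralist can read at the bench.
Threshold inversion uses exact rational arithmetic so table cells are
exact for the published coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "ScoreParams",
    "PREVIOUS_CUTOFF",
    "COMMON_CUTOFF",
    "Decision",
    "erc_score",
    "classify",
    "tti_threshold",
    "CellKind",
    "DecisionCell",
    "DecisionTable",
    "decision_table",
]

#: originally published cutoff
PREVIOUS_CUTOFF = -6.7
#: common cutoff performing well in both derivation and validation cohorts
COMMON_CUTOFF = -7.2

#: absolute guard when comparing a float score to the cutoff, so that a
#: score reconstructed from an inverted threshold still lands on the
#: positive side of the tie rule despite binary rounding.
CLASSIFY_ATOL = 1e-9


@dataclass(frozen=True)
class ScoreParams:
    """Score coefficients and cutoff (defaults: the published model)."""

    coef_tti: float = 0.02          # score units per second
    coef_unsuccessful: float = 0.5  # score units per application
    coef_nadir: float = 0.2         # score units per deg C
    cutoff: float = COMMON_CUTOFF

    def __post_init__(self) -> None:
        for name in ("coef_tti", "coef_unsuccessful", "coef_nadir", "cutoff"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


class Decision(str, Enum):
    TEST_REQUIRED = "test_required"
    NO_TEST = "no_test"


def erc_score(
    tti_s: float,
    n_unsuccessful: float,
    nadir_temp_c: float,
    params: ScoreParams = ScoreParams(),
) -> float:
    """Linear ERC risk score; all three predictors must be present."""
    for name, v in (
        ("tti_s", tti_s),
        ("n_unsuccessful", n_unsuccessful),
        ("nadir_temp_c", nadir_temp_c),
    ):
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be present and finite (got {v!r})")
    return (
        params.coef_tti * tti_s
        + params.coef_unsuccessful * n_unsuccessful
        + params.coef_nadir * nadir_temp_c
    )


def classify(score: float, cutoff: float, atol: float = CLASSIFY_ATOL) -> Decision:
    """Test required iff ``score >= cutoff`` (ties positive)."""
    return Decision.TEST_REQUIRED if score >= cutoff - atol else Decision.NO_TEST


def _frac(x: float) -> Fraction:
    # repr() of a float is its shortest faithful decimal, so 0.02 -> 1/50
    return Fraction(repr(float(x)))


def tti_threshold(
    nadir_temp_c: float,
    n_unsuccessful: int,
    params: ScoreParams = ScoreParams(),
) -> float:
    """Minimal TTI (s) making a vein test-positive at the params' cutoff.

    TTI* = (cutoff - c_u * n - c_nadir * nadir) / c_tti, evaluated in
    exact rational arithmetic. Non-positive values mean "always test";
    values beyond the table cap mean "no test within plausible TTI".
    """
    if params.coef_tti <= 0:
        raise ValueError("coef_tti must be positive to invert the score")
    thr = (
        _frac(params.cutoff)
        - _frac(params.coef_unsuccessful) * n_unsuccessful
        - _frac(params.coef_nadir) * _frac(nadir_temp_c)
    ) / _frac(params.coef_tti)
    return float(thr)


class CellKind(str, Enum):
    ALWAYS_TEST = "always_test"
    NEVER_TEST = "never_test"
    TTI_THRESHOLD = "tti_threshold"


@dataclass(frozen=True)
class DecisionCell:
    kind: CellKind
    tti_threshold_s: Optional[float] = None

    def label(self) -> str:
        if self.kind is CellKind.ALWAYS_TEST:
            return "ERC test"
        if self.kind is CellKind.NEVER_TEST:
            return "NO ERC test"
        thr = self.tti_threshold_s
        txt = f"{thr:g}"
        return f">= {txt}: ERC test"


@dataclass
class DecisionTable:
    """Grid of (nadir deg C, unsuccessful count) -> testing decision."""

    nadir_values: list[int]
    u_values: list[int]
    cells: dict[tuple[int, int], DecisionCell]
    params: ScoreParams
    tti_cap_s: float

    def cell(self, nadir_temp_c: int, n_unsuccessful: int) -> DecisionCell:
        return self.cells[(nadir_temp_c, n_unsuccessful)]

    def to_frame(self) -> pd.DataFrame:
        """Human-readable frame: one row per nadir, one column per count."""
        data = {
            f"u={u}": [self.cells[(nd, u)].label() for nd in self.nadir_values]
            for u in self.u_values
        }
        return pd.DataFrame(data, index=pd.Index(self.nadir_values, name="nadir_c"))

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {
                "nadir_c": nd,
                "n_unsuccessful": u,
                "decision": c.kind.value,
                "tti_threshold_s": c.tti_threshold_s,
            }
            for (nd, u), c in sorted(self.cells.items(), key=lambda kv: (-kv[0][0], kv[0][1]))
        ]
        return pd.DataFrame(rows)


def decision_table(
    params: ScoreParams = ScoreParams(),
    nadir_values: Sequence[int] = tuple(range(-30, -54, -1)),
    u_values: Sequence[int] = tuple(range(0, 4)),
    tti_cap_s: float = 95.0,
) -> DecisionTable:
    """Build the bedside decision table by inverting the score at the cutoff.

    Cell semantics: ``always_test`` when the inverted threshold TTI* <= 0
    (even instant isolation scores above the cutoff); ``never_test`` when
    TTI* exceeds ``tti_cap_s`` (the displayed TTI range ends at 95 s;
    beyond 90 s the balloon is repositioned anyway); otherwise the minimal
    test-triggering TTI in seconds.
    """
    if tti_cap_s <= 0:
        raise ValueError("tti_cap_s must be positive")
    cap = _frac(tti_cap_s)
    cells: dict[tuple[int, int], DecisionCell] = {}
    for nd in nadir_values:
        for u in u_values:
            thr = (
                _frac(params.cutoff)
                - _frac(params.coef_unsuccessful) * u
                - _frac(params.coef_nadir) * nd
            ) / _frac(params.coef_tti)
            if thr <= 0:
                cells[(nd, u)] = DecisionCell(CellKind.ALWAYS_TEST)
            elif thr > cap:
                cells[(nd, u)] = DecisionCell(CellKind.NEVER_TEST)
            else:
                cells[(nd, u)] = DecisionCell(CellKind.TTI_THRESHOLD, float(thr))
    return DecisionTable(
        nadir_values=list(nadir_values),
        u_values=list(u_values),
        cells=cells,
        params=params,
        tti_cap_s=float(tti_cap_s),
    )
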