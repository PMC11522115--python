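"""Biophysical features of a cryo-application temperature-time trace.

All features are defined on the piecewise-linear interpolant of the
sampled curve:

* **freeze AUC** — area between the curve and the 0 deg C axis over the
  sub-zero section, in deg C * s (a positive magnitude); trapezoidal, with
  zero crossings located by linear interpolation so the integral is exact
  for piecewise-linear traces and invariant under grid refinement.
* **freeze magnitude** — freeze AUC divided by the time spent below
  0 deg C: a time-normalised freeze intensity in deg C.
* **temperature at t** — linear interpolation, never extrapolated.
* **warming time to a threshold** — elapsed time from the warming
  reference point (default: the global temperature nadir; an explicit
  thaw-start marker can be supplied instead) to the first upward crossing
  of the threshold. When the console stopped recording at balloon
  deflation before the threshold was reached, the time to the last sample
  is reported with a ``truncated`` flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .cohort_model import ApplicationTrace

logger = logging.getLogger(__name__)

#: warming thresholds reported in the cohort summaries (deg C)
WARMING_THRESHOLDS = (0.0, 15.0, 20.0)


class WarmingTime(NamedTuple):
    seconds: Optional[float]
    truncated: bool


@dataclass
class TraceFeatures:
    """Feature bundle for one application; missing values are ``None``."""

    freeze_auc: float
    freeze_magnitude: Optional[float]
    nadir_temp_c: float
    temp_at_30s: Optional[float]
    temp_at_60s: Optional[float]
    temp_at_tti: Optional[float]
    warming_time_to_0: Optional[float]
    warming_time_to_15: Optional[float]
    warming_time_to_20: Optional[float]
    warming_truncated: bool


def _refine_with_zero_crossings(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert interpolated 0 deg C crossing points into the polyline."""
    ts, ys = [t[0]], [y[0]]
    for i in range(len(t) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 < 0.0 < y1) or (y1 < 0.0 < y0):
            tc = t[i] + (0.0 - y0) * (t[i + 1] - t[i]) / (y1 - y0)
            ts.append(tc)
            ys.append(0.0)
        ts.append(t[i + 1])
        ys.append(y1)
    return np.asarray(ts), np.asarray(ys)


def freeze_auc(trace: ApplicationTrace) -> float:
    """Area (deg C * s, >= 0) between the curve and 0 deg C where temp < 0."""
    t, y = _refine_with_zero_crossings(trace.times_s, trace.temps_c)
    area = -float(np.trapezoid(np.minimum(y, 0.0), t))
    if area == 0.0:
        warnings.warn("trace never dropped below 0 deg C; freeze AUC is 0", stacklevel=2)
    return area


def time_below_zero(trace: ApplicationTrace) -> float:
    """Total duration (s) the interpolated curve spends below 0 deg C."""
    t, y = _refine_with_zero_crossings(trace.times_s, trace.temps_c)
    dt = np.diff(t)
    mid = 0.5 * (y[:-1] + y[1:])  # segment interior sign; endpoints may sit at 0
    return float(np.sum(dt[mid < 0.0]))


def freeze_magnitude(trace: ApplicationTrace) -> Optional[float]:
    """Freeze AUC / time below 0 deg C; ``None`` if the curve never freezes."""
    duration = time_below_zero(trace)
    if duration <= 0.0:
        warnings.warn("zero time below 0 deg C; freeze magnitude undefined", stacklevel=2)
        return None
    return freeze_auc(trace) / duration


def temperature_at(trace: ApplicationTrace, t: float) -> Optional[float]:
    """Interpolated temperature at time ``t``; ``None`` outside the span."""
    t0, t1 = trace.times_s[0], trace.times_s[-1]
    if not (t0 <= t <= t1):
        warnings.warn(
            f"t={t} s outside sampled span [{t0}, {t1}]; not extrapolating", stacklevel=2
        )
        return None
    return float(np.interp(t, trace.times_s, trace.temps_c))


def nadir_index(trace: ApplicationTrace) -> int:
    """Index of the global nadir; earliest sample on ties (deterministic)."""
    return int(np.argmin(trace.temps_c))


def warming_time_to(
    trace: ApplicationTrace,
    threshold_c: float,
    reference_time_s: Optional[float] = None,
) -> WarmingTime:
    """Time from the warming reference point to the first upward crossing
    of ``threshold_c``.

    The reference defaults to the global nadir time; pass
    ``reference_time_s`` to anchor at an explicit thaw-start marker.
    If the threshold is never reached and the trace is
    ``deflation_truncated``, the elapsed time to the final sample is
    returned with ``truncated=True``; a non-truncated trace that never
    reaches the threshold yields a missing value.
    """
    t, y = trace.times_s, trace.temps_c
    i0 = nadir_index(trace)
    if threshold_c < y[i0]:
        raise ValueError(
            f"threshold {threshold_c} deg C lies below the nadir {y[i0]} deg C"
        )
    t_ref = float(t[i0]) if reference_time_s is None else float(reference_time_s)
    if y[i0] >= threshold_c and reference_time_s is None:
        return WarmingTime(0.0, False)
    for i in range(i0, len(t) - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 < threshold_c <= y1:
            tc = t[i] + (threshold_c - y0) * (t[i + 1] - t[i]) / (y1 - y0)
            return WarmingTime(float(tc - t_ref), False)
    if trace.deflation_truncated:
        return WarmingTime(float(t[-1] - t_ref), True)
    warnings.warn(
        f"threshold {threshold_c} deg C never reached on a non-truncated trace",
        stacklevel=2,
    )
    return WarmingTime(None, False)


def extract_features(
    trace: ApplicationTrace, reference_time_s: Optional[float] = None
) -> TraceFeatures:
    """Bundle all biophysical features for one application.

    ``temp_at_30s``/``temp_at_60s`` are measured from the first sample
    (application start); ``temp_at_tti`` only when the trace carries a TTI
    annotation. Warming times use the nadir reference unless an explicit
    marker is given.
    """
    t0 = float(trace.times_s[0])
    nadir = float(trace.temps_c[nadir_index(trace)])

    warming: dict[float, WarmingTime] = {}
    truncated = False
    for thr in WARMING_THRESHOLDS:
        if thr < nadir:  # pragma: no cover - nadir above 0 deg C is pathological
            warming[thr] = WarmingTime(None, False)
            continue
        wt = warming_time_to(trace, thr, reference_time_s=reference_time_s)
        warming[thr] = wt
        truncated = truncated or wt.truncated

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        temp_at_tti = (
            temperature_at(trace, t0 + trace.tti_s) if trace.tti_s is not None else None
        )
        return TraceFeatures(
            freeze_auc=freeze_auc(trace),
            freeze_magnitude=freeze_magnitude(trace),
            nadir_temp_c=nadir,
            temp_at_30s=temperature_at(trace, t0 + 30.0),
            temp_at_60s=temperature_at(trace, t0 + 60.0),
            temp_at_tti=temp_at_tti,
            warming_time_to_0=warming[0.0].seconds,
            warming_time_to_15=warming[15.0].seconds,
            warming_time_to_20=warming[20.0].seconds,
            warming_truncated=truncated,
        )
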