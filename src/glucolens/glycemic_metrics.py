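"""CGM-derived features and target variables.

Per participant-day the pipeline needs two CGM summary features computed
before lunch -- fasting glucose (minimum reading between 6 and 10 AM) and
the recent overnight mean (12 AM to 8 AM) -- and four postprandial targets
for the lunch meal: the absolute 3-h area under the glucose curve (AUC,
mg/dL.h), the incremental AUC above the meal-time baseline (iAUC), the
maximum postprandial glucose (MaxBGL) and the binary hyperglycemia label
(MaxBGL >= 140 mg/dL within the window).

All integrals are taken over the piecewise-linear interpolant of the trace,
with the window endpoints themselves interpolated when they fall between
samples, so the trapezoid over the in-window knots equals the exact integral
of the interpolant. A contiguous gap longer than ``max_gap`` inside a window
marks the metric missing (returned as NaN) rather than silently integrating
across it.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glucolens.log_ingest import CgmTrace

#: Postprandial window length, hours. The study outcome is the 3-h AUC; a
#: 2-h window is supported via the ``horizon`` argument.
DEFAULT_HORIZON_H = 3.0

#: Postprandial hyperglycemia threshold, mg/dL.
HYPER_THRESHOLD = 140.0

#: Longest tolerated CGM gap inside an analysis window, minutes.
MAX_GAP_MIN = 45.0


@dataclass
class GlycemicTargets:
    """Targets for one meal: AUC and iAUC in mg/dL.h, MaxBGL in mg/dL."""

    auc: float
    iauc: float
    max_bgl: float
    hyper_label: int


def _window_arrays(
    trace: CgmTrace, start: pd.Timestamp, end: pd.Timestamp
) -> tuple[np.ndarray, np.ndarray]:
    """Times (hours from ``start``) and glucose on [start, end], endpoints
    interpolated from the bracketing samples where possible."""
    ts = np.array([t.value for t, _ in trace.samples], dtype=np.int64)
    g = np.array([v for _, v in trace.samples], dtype=float)
    if ts.size == 0:
        return np.empty(0), np.empty(0)
    lo, hi = start.value, end.value
    inside = (ts >= lo) & (ts <= hi)
    t_in, g_in = ts[inside], g[inside]
    pieces_t, pieces_g = [t_in], [g_in]
    # interpolated endpoint values if the window edge falls between samples
    for edge in (lo, hi):
        if t_in.size and edge in (t_in[0], t_in[-1]):
            continue
        before = ts < edge
        after = ts > edge
        if before.any() and after.any():
            t0, t1 = ts[before][-1], ts[after][0]
            g0, g1 = g[before][-1], g[after][0]
            ge = g0 + (g1 - g0) * (edge - t0) / (t1 - t0)
            pieces_t.append(np.array([edge], dtype=np.int64))
            pieces_g.append(np.array([ge]))
    t_all = np.concatenate(pieces_t)
    g_all = np.concatenate(pieces_g)
    order = np.argsort(t_all)
    t_all, g_all = t_all[order], g_all[order]
    hours = (t_all - lo) / 3.6e12
    return hours, g_all


def _has_long_gap(hours: np.ndarray, max_gap_min: float) -> bool:
    return hours.size < 2 or np.max(np.diff(hours)) * 60.0 > max_gap_min


def fasting_glucose(trace: CgmTrace, date: dt.date) -> float:
    """Minimum CGM reading between 6 AM and 10 AM (closed window), mg/dL.

    Returns NaN when the window holds no samples; callers drop such rows.
    """
    start = pd.Timestamp(dt.datetime.combine(date, dt.time(6, 0)))
    end = pd.Timestamp(dt.datetime.combine(date, dt.time(10, 0)))
    vals = [g for t, g in trace.samples if start <= t <= end]
    return min(vals) if vals else math.nan


def recent_cgm(trace: CgmTrace, date: dt.date) -> float:
    """Mean CGM reading of the same day over [12 AM, 8 AM), mg/dL."""
    start = pd.Timestamp(dt.datetime.combine(date, dt.time(0, 0)))
    end = pd.Timestamp(dt.datetime.combine(date, dt.time(8, 0)))
    vals = [g for t, g in trace.samples if start <= t < end]
    return float(np.mean(vals)) if vals else math.nan


def postprandial_auc(
    trace: CgmTrace,
    meal_time: pd.Timestamp,
    horizon: float = DEFAULT_HORIZON_H,
    max_gap_min: float = MAX_GAP_MIN,
) -> float:
    """Absolute (not baseline-subtracted) AUC over the postprandial window.

    Trapezoidal integral of glucose versus time in hours, mg/dL.h.
    """
    end = meal_time + pd.Timedelta(hours=horizon)
    hours, g = _window_arrays(trace, meal_time, end)
    if _has_long_gap(hours, max_gap_min):
        return math.nan
    return float(np.trapezoid(g, hours))


def incremental_auc(
    trace: CgmTrace,
    meal_time: pd.Timestamp,
    horizon: float = DEFAULT_HORIZON_H,
    max_gap_min: float = MAX_GAP_MIN,
) -> float:
    """Incremental AUC: area of max(G(t) - G(meal_time), 0) over the window.

    The baseline is glucose at meal time, linearly interpolated from the two
    bracketing samples. Segments that cross the baseline are split at the
    crossing so the clipped trapezoid is exact for the linear interpolant.
    """
    end = meal_time + pd.Timedelta(hours=horizon)
    hours, g = _window_arrays(trace, meal_time, end)
    if _has_long_gap(hours, max_gap_min):
        return math.nan
    if hours[0] > 1e-12:  # no bracketing sample before the meal: no baseline
        return math.nan
    baseline = g[0]
    excess = g - baseline
    area = 0.0
    for i in range(len(hours) - 1):
        h0, h1 = hours[i], hours[i + 1]
        e0, e1 = excess[i], excess[i + 1]
        if e0 >= 0 and e1 >= 0:
            area += 0.5 * (e0 + e1) * (h1 - h0)
        elif e0 <= 0 and e1 <= 0:
            continue
        else:  # sign change: only the positive triangle counts
            frac = e0 / (e0 - e1)
            hc = h0 + frac * (h1 - h0)
            if e0 > 0:
                area += 0.5 * e0 * (hc - h0)
            else:
                area += 0.5 * e1 * (h1 - hc)
    return float(area)


def max_bgl(
    trace: CgmTrace,
    meal_time: pd.Timestamp,
    horizon: float = DEFAULT_HORIZON_H,
    max_gap_min: float = MAX_GAP_MIN,
) -> float:
    """Maximum glucose within the postprandial window, mg/dL."""
    end = meal_time + pd.Timedelta(hours=horizon)
    hours, g = _window_arrays(trace, meal_time, end)
    if _has_long_gap(hours, max_gap_min):
        return math.nan
    return float(np.max(g))


def hyper_label(
    max_bgl_value: float, threshold: float = HYPER_THRESHOLD
) -> int | float:
    """1 iff MaxBGL >= 140 mg/dL (the ``>=`` is part of the definition)."""
    if math.isnan(max_bgl_value):
        return math.nan
    return int(max_bgl_value >= threshold)


def meal_targets(
    trace: CgmTrace,
    meal_time: pd.Timestamp,
    horizon: float = DEFAULT_HORIZON_H,
    threshold: float = HYPER_THRESHOLD,
) -> GlycemicTargets:
    """All four targets for one meal; any NaN propagates to the label."""
    auc = postprandial_auc(trace, meal_time, horizon)
    iauc = incremental_auc(trace, meal_time, horizon)
    mx = max_bgl(trace, meal_time, horizon)
    return GlycemicTargets(auc, iauc, mx, hyper_label(mx, threshold))
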