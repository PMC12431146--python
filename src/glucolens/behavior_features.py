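"""Behavioral and dietary feature engineering.

Builds the five named feature sets used by the predictors from the four
ingested sources. The common block (15 features) carries fasting glucose,
the overnight CGM mean, meal and work timing, BMI and the nutrition-label
facts every set shares. On top of it:

* ``Sensor`` adds six activPAL durations: sitting/standing/stepping seconds
  for the day until lunch, and the same three restricted to work hours.
* ``Self`` adds one self-reported activity score derived from the work logs
  of *previous* days in the same study phase (no same-day leakage).
* ``Macro`` adds net carbs, fat, protein and fiber (grams, as consumed).
* ``GL`` adds the glycemic load of the lunch.

Glycemic load is the regression estimate

    GL = 19.27 + 0.39 * net_carbs - 0.21 * fat - 0.01 * protein^2
         - 0.01 * fiber^2

with macronutrients in grams, scaled by (1 - leftover_fraction) before the
formula is applied. Clock times are encoded as fractional hours since
midnight and day-of-week as an integer 0-6 (Monday = 0), matching how the
tree-based backbones consume them.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glucolens.glycemic_metrics import (
    DEFAULT_HORIZON_H,
    fasting_glucose,
    meal_targets,
    recent_cgm,
)
from glucolens.log_ingest import (
    ActivityEventLog,
    CgmTrace,
    MealRecord,
    WorkRecord,
)

logger = logging.getLogger(__name__)

#: activPAL emits seven event classes but the feature layer uses three.
#: Sedentary postures (incl. transport and lying) count as sitting; cycling
#: is locomotion and counts as stepping. Override via ``class_map=``.
DEFAULT_CLASS_MAP = {
    "sedentary": "sitting",
    "seated_transport": "sitting",
    "lying_primary": "sitting",
    "lying_secondary": "sitting",
    "standing": "standing",
    "stepping": "stepping",
    "cycling": "stepping",
}

COMMON_FEATURES = [
    "fasting_glucose",
    "recent_cgm",
    "lunch_time",
    "work_from_home",
    "bmi",
    "calories",
    "calories_from_fat",
    "saturated_fat",
    "trans_fat",
    "cholesterol",
    "sodium",
    "total_carbs",
    "sugar",
    "work_start_time",
    "day_of_week",
]

SENSOR_FEATURES = [
    "sitting_total",
    "standing_total",
    "stepping_total",
    "sitting_at_work",
    "standing_at_work",
    "stepping_at_work",
]

SELF_FEATURES = ["self_activity_score"]
MACRO_FEATURES = ["net_carbs", "fat", "protein", "fiber"]
GL_FEATURES = ["glycemic_load"]

FEATURE_SETS: dict[str, list[str]] = {
    "Sensor+GL": COMMON_FEATURES + SENSOR_FEATURES + GL_FEATURES,
    "Sensor+Macro": COMMON_FEATURES + SENSOR_FEATURES + MACRO_FEATURES,
    "Self+GL": COMMON_FEATURES + SELF_FEATURES + GL_FEATURES,
    "Self+Macro": COMMON_FEATURES + SELF_FEATURES + MACRO_FEATURES,
    "All": COMMON_FEATURES + SENSOR_FEATURES + SELF_FEATURES + MACRO_FEATURES
    + GL_FEATURES,
}

TARGET_COLUMNS = ["auc", "iauc", "max_bgl", "hyper_label"]
ID_COLUMNS = ["participant_id", "date"]


@dataclass
class ActivityDurations:
    """Per-class seconds, day-start-to-lunch and work-start-to-lunch."""

    sitting_total: float
    standing_total: float
    stepping_total: float
    sitting_at_work: float
    standing_at_work: float
    stepping_at_work: float


def glycemic_load(net_carbs: float, fat: float, protein: float, fiber: float) -> float:
    """Glycemic load of a meal from its macronutrients in grams."""
    for name, v in (("net_carbs", net_carbs), ("fat", fat),
                    ("protein", protein), ("fiber", fiber)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return (
        19.27
        + 0.39 * net_carbs
        - 0.21 * fat
        - 0.01 * protein**2
        - 0.01 * fiber**2
    )


def _overlap_seconds(
    events: list[tuple[pd.Timestamp, float, str]],
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
    class_map: dict[str, str],
) -> dict[str, float]:
    totals = {"sitting": 0.0, "standing": 0.0, "stepping": 0.0}
    lo, hi = window_start.value / 1e9, window_end.value / 1e9
    for start, duration, activity in events:
        s = start.value / 1e9
        e = s + duration
        sec = min(e, hi) - max(s, lo)
        if sec > 0:
            totals[class_map[activity]] += sec
    return totals


def activpal_durations(
    events: ActivityEventLog,
    date: dt.date,
    lunch_time: dt.time,
    work_start: dt.time,
    class_map: dict[str, str] | None = None,
) -> ActivityDurations:
    """Sum per-class event seconds over [midnight, lunch) and [work start,
    lunch); events straddling a boundary contribute only their overlap."""
    class_map = class_map or DEFAULT_CLASS_MAP
    day0 = pd.Timestamp(dt.datetime.combine(date, dt.time(0, 0)))
    lunch = pd.Timestamp(dt.datetime.combine(date, lunch_time))
    work = pd.Timestamp(dt.datetime.combine(date, work_start))
    total = _overlap_seconds(events.events, day0, lunch, class_map)
    at_work = _overlap_seconds(events.events, work, lunch, class_map)
    return ActivityDurations(
        sitting_total=total["sitting"],
        standing_total=total["standing"],
        stepping_total=total["stepping"],
        sitting_at_work=at_work["sitting"],
        standing_at_work=at_work["standing"],
        stepping_at_work=at_work["stepping"],
    )


def self_activity_score(
    work_history: list[WorkRecord], current_date: dt.date, phase: str
) -> float:
    """Self-reported activity score from prior same-phase work logs.

    mean(pct_walking) + 12 * mean(pct_standing) over strictly earlier days
    of the same phase; NaN when no prior day exists.
    """
    prior = [
        w for w in work_history
        if w.phase == phase and w.date < current_date
    ]
    if not prior:
        return float("nan")
    walking = np.mean([w.pct_walking for w in prior])
    standing = np.mean([w.pct_standing for w in prior])
    return float(walking + 12.0 * standing)


def _hours(t: dt.time) -> float:
    return t.hour + t.minute / 60.0 + t.second / 3600.0


def consumed_macros(meal: MealRecord) -> dict[str, float]:
    """Nutrition facts scaled by the fraction actually eaten."""
    scale = 1.0 - meal.leftover_fraction
    return {f: getattr(meal, f) * scale for f in MealRecord.NUTRIENT_FIELDS}


def assemble_features(
    cgm: list[CgmTrace],
    activity: list[ActivityEventLog],
    meals: list[MealRecord],
    work: list[WorkRecord],
    bmi: dict[str, float],
    feature_set: str = "All",
    horizon: float = DEFAULT_HORIZON_H,
    class_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per participant-workday lunch under the named feature set.

    Returns a DataFrame with ``participant_id``/``date`` identifiers, the
    feature columns of ``FEATURE_SETS[feature_set]`` and the four targets.
    Rows missing a mandatory feature or target are dropped with a logged
    count. Every feature is computable from data timestamped at or before
    the lunch; targets use the postprandial window only.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(
            f"unknown feature set {feature_set!r}; valid: {sorted(FEATURE_SETS)}"
        )
    columns = FEATURE_SETS[feature_set]
    cgm_by_pid = {t.participant_id: t for t in cgm}
    act_by_pid = {a.participant_id: a for a in activity}
    work_by_key = {(w.participant_id, w.date): w for w in work}
    work_by_pid: dict[str, list[WorkRecord]] = {}
    for w in work:
        work_by_pid.setdefault(w.participant_id, []).append(w)

    rows = []
    n_dropped = 0
    for meal in meals:
        pid, date = meal.participant_id, meal.date
        wrec = work_by_key.get((pid, date))
        trace = cgm_by_pid.get(pid)
        events = act_by_pid.get(pid)
        if wrec is None or trace is None or events is None:
            n_dropped += 1
            continue
        lunch_ts = pd.Timestamp(dt.datetime.combine(date, meal.meal_time))
        macros = consumed_macros(meal)
        gl = glycemic_load(
            macros["net_carbs"], macros["fat"], macros["protein"], macros["fiber"]
        )
        durations = activpal_durations(
            events, date, meal.meal_time, wrec.work_start, class_map
        )
        targets = meal_targets(trace, lunch_ts, horizon)
        row: dict[str, object] = {
            "participant_id": pid,
            "date": date,
            "fasting_glucose": fasting_glucose(trace, date),
            "recent_cgm": recent_cgm(trace, date),
            "lunch_time": _hours(meal.meal_time),
            "work_from_home": wrec.work_from_home,
            "bmi": bmi[pid],
            "calories": macros["calories"],
            "calories_from_fat": macros["calories_from_fat"],
            "saturated_fat": macros["saturated_fat"],
            "trans_fat": macros["trans_fat"],
            "cholesterol": macros["cholesterol"],
            "sodium": macros["sodium"],
            "total_carbs": macros["total_carbs"],
            "sugar": macros["sugar"],
            "work_start_time": _hours(wrec.work_start),
            "day_of_week": date.weekday(),
            "sitting_total": durations.sitting_total,
            "standing_total": durations.standing_total,
            "stepping_total": durations.stepping_total,
            "sitting_at_work": durations.sitting_at_work,
            "standing_at_work": durations.standing_at_work,
            "stepping_at_work": durations.stepping_at_work,
            "self_activity_score": self_activity_score(
                work_by_pid.get(pid, []), date, wrec.phase
            ),
            "net_carbs": macros["net_carbs"],
            "fat": macros["fat"],
            "protein": macros["protein"],
            "fiber": macros["fiber"],
            "glycemic_load": gl,
            "auc": targets.auc,
            "iauc": targets.iauc,
            "max_bgl": targets.max_bgl,
            "hyper_label": targets.hyper_label,
        }
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=ID_COLUMNS + columns + TARGET_COLUMNS)
    df = df[ID_COLUMNS + columns + TARGET_COLUMNS]
    complete = df[columns + TARGET_COLUMNS].notna().all(axis=1)
    n_dropped += int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete participant-day rows", n_dropped)
    return df.loc[complete].reset_index(drop=True)
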