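"""Typed ingestion of the four raw CSV sources.

Readers validate each row against the record invariants, skip (and count)
rows that violate them, and hard-fail on structural problems such as a
missing column. Timestamps are timezone-naive local clock time throughout:
every analysis window (fasting 6-10 AM, overnight 12-8 AM, postprandial
3 h) is defined on the participant's local clock.

CSV dialects
------------
cgm.csv               participant_id, timestamp (ISO-8601), glucose
activpal_events.csv   participant_id, start (ISO-8601), duration_s, activity
food_log.csv          participant_id, date, meal_time (HH:MM), calories,
                      calories_from_fat, saturated_fat, trans_fat,
                      cholesterol, sodium, total_carbs, sugar, net_carbs,
                      fat, protein, fiber, leftover_fraction
work_log.csv          participant_id, date, work_start, work_end (HH:MM),
                      work_from_home, pct_sitting, pct_standing,
                      pct_walking, phase
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ACTIVITY_CLASSES = (
    "sedentary",
    "standing",
    "stepping",
    "cycling",
    "lying_primary",
    "lying_secondary",
    "seated_transport",
)

PHASES = ("Baseline", "Stand", "Move")

GLUCOSE_MIN, GLUCOSE_MAX = 20.0, 500.0


class IngestError(ValueError):
    """Structural problem with an input file (missing column, overlap, ...)."""


@dataclass
class CgmTrace:
    """One participant's interstitial glucose series, mg/dL at ~15-min cadence.

    ``samples`` is kept sorted by timestamp; gaps are preserved as gaps and
    interpolation decisions are left to the metric layer.
    """

    participant_id: str
    samples: list[tuple[pd.Timestamp, float]] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["timestamp", "glucose"])


@dataclass
class ActivityEventLog:
    """Event stream from the thigh-worn sensor: (start, duration s, class)."""

    participant_id: str
    events: list[tuple[pd.Timestamp, float, str]] = field(default_factory=list)


@dataclass
class MealRecord:
    """One lunch's nutrition facts as listed, plus the leftover fraction.

    Consumed amounts are ``listed * (1 - leftover_fraction)``; the scaling is
    applied by the feature layer, not at ingest.
    """

    participant_id: str
    date: dt.date
    meal_time: dt.time
    calories: float
    calories_from_fat: float
    saturated_fat: float
    trans_fat: float
    cholesterol: float
    sodium: float
    total_carbs: float
    sugar: float
    net_carbs: float
    fat: float
    protein: float
    fiber: float
    leftover_fraction: float = 0.0

    NUTRIENT_FIELDS = (
        "calories",
        "calories_from_fat",
        "saturated_fat",
        "trans_fat",
        "cholesterol",
        "sodium",
        "total_carbs",
        "sugar",
        "net_carbs",
        "fat",
        "protein",
        "fiber",
    )


@dataclass
class WorkRecord:
    """One day's work timing, location and self-reported activity split."""

    participant_id: str
    date: dt.date
    work_start: dt.time
    work_end: dt.time
    work_from_home: int
    pct_sitting: float
    pct_standing: float
    pct_walking: float
    phase: str


@dataclass
class IngestSummary:
    n_read: int = 0
    n_skipped: int = 0
    diagnostics: list[str] = field(default_factory=list)

    def skip(self, line: int, reason: str) -> None:
        self.n_skipped += 1
        msg = f"line {line}: {reason}"
        self.diagnostics.append(msg)
        logger.warning("skipped row, %s", msg)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s) {missing}")


def _parse_time(value: str) -> dt.time:
    return dt.datetime.strptime(str(value).strip(), "%H:%M").time()


# ---------------------------------------------------------------------------
# readers


def read_cgm(path: str | Path, summary: IngestSummary | None = None) -> list[CgmTrace]:
    """Read cgm.csv into one trace per participant.

    Rows with glucose outside [20, 500] mg/dL or unparseable timestamps are
    skipped with a line-numbered diagnostic; duplicate (participant,
    timestamp) rows keep the first occurrence.
    """
    summary = summary if summary is not None else IngestSummary()
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "timestamp", "glucose"], str(path))
    rows: dict[str, dict[pd.Timestamp, float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ts = pd.Timestamp(row.timestamp)
            glucose = float(row.glucose)
        except (ValueError, TypeError):
            summary.skip(i, "unparseable timestamp or glucose")
            continue
        if not GLUCOSE_MIN <= glucose <= GLUCOSE_MAX:
            summary.skip(i, f"glucose {glucose} outside [{GLUCOSE_MIN}, {GLUCOSE_MAX}]")
            continue
        pid = str(row.participant_id)
        per = rows.setdefault(pid, {})
        if ts in per:  # dedupe keeping first
            summary.skip(i, f"duplicate timestamp {ts} for {pid}")
            continue
        per[ts] = glucose
        summary.n_read += 1
    return [
        CgmTrace(pid, sorted(per.items())) for pid, per in sorted(rows.items())
    ]


def read_activity(
    path: str | Path, summary: IngestSummary | None = None
) -> list[ActivityEventLog]:
    """Read activpal_events.csv; overlapping events are a hard error."""
    summary = summary if summary is not None else IngestSummary()
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "start", "duration_s", "activity"], str(path))
    logs: dict[str, list[tuple[pd.Timestamp, float, str, int]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = pd.Timestamp(row.start)
            duration = float(row.duration_s)
        except (ValueError, TypeError):
            summary.skip(i, "unparseable start or duration")
            continue
        activity = str(row.activity)
        if activity not in ACTIVITY_CLASSES:
            summary.skip(i, f"unknown activity class {activity!r}")
            continue
        if duration <= 0:
            summary.skip(i, f"nonpositive duration {duration}")
            continue
        logs.setdefault(str(row.participant_id), []).append((start, duration, activity, i))
        summary.n_read += 1
    out = []
    for pid, events in sorted(logs.items()):
        events.sort(key=lambda e: e[0])
        for (s1, d1, _, l1), (s2, _, _, l2) in zip(events, events[1:]):
            if s1 + pd.Timedelta(seconds=d1) > s2:
                raise IngestError(
                    f"{path}: overlapping activity events for {pid} "
                    f"at lines {l1} and {l2}"
                )
        out.append(ActivityEventLog(pid, [(s, d, a) for s, d, a, _ in events]))
    return out


def read_meals(path: str | Path, summary: IngestSummary | None = None) -> list[MealRecord]:
    summary = summary if summary is not None else IngestSummary()
    df = pd.read_csv(path)
    required = ["participant_id", "date", "meal_time", *MealRecord.NUTRIENT_FIELDS,
                "leftover_fraction"]
    _require_columns(df, required, str(path))
    records: list[MealRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = MealRecord(
                participant_id=str(row.participant_id),
                date=pd.Timestamp(row.date).date(),
                meal_time=_parse_time(row.meal_time),
                **{f: float(getattr(row, f)) for f in MealRecord.NUTRIENT_FIELDS},
                leftover_fraction=float(row.leftover_fraction),
            )
        except (ValueError, TypeError):
            summary.skip(i, "unparseable meal row")
            continue
        if any(getattr(rec, f) < 0 for f in MealRecord.NUTRIENT_FIELDS):
            summary.skip(i, "negative nutrient amount")
            continue
        if rec.net_carbs > rec.total_carbs + 1e-9:
            summary.skip(i, "net_carbs exceeds total_carbs")
            continue
        if not 0.0 <= rec.leftover_fraction <= 1.0:
            summary.skip(i, "leftover_fraction outside [0, 1]")
            continue
        records.append(rec)
        summary.n_read += 1
    return records


def read_work(path: str | Path, summary: IngestSummary | None = None) -> list[WorkRecord]:
    summary = summary if summary is not None else IngestSummary()
    df = pd.read_csv(path)
    required = ["participant_id", "date", "work_start", "work_end", "work_from_home",
                "pct_sitting", "pct_standing", "pct_walking", "phase"]
    _require_columns(df, required, str(path))
    records: list[WorkRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = WorkRecord(
                participant_id=str(row.participant_id),
                date=pd.Timestamp(row.date).date(),
                work_start=_parse_time(row.work_start),
                work_end=_parse_time(row.work_end),
                work_from_home=int(row.work_from_home),
                pct_sitting=float(row.pct_sitting),
                pct_standing=float(row.pct_standing),
                pct_walking=float(row.pct_walking),
                phase=str(row.phase),
            )
        except (ValueError, TypeError):
            summary.skip(i, "unparseable work row")
            continue
        if rec.phase not in PHASES:
            summary.skip(i, f"unknown phase {rec.phase!r}")
            continue
        if rec.work_start >= rec.work_end:
            summary.skip(i, "work_start not before work_end")
            continue
        if rec.pct_sitting + rec.pct_standing + rec.pct_walking > 100.0 + 1e-9:
            summary.skip(i, "activity percentages sum above 100")
            continue
        if min(rec.pct_sitting, rec.pct_standing, rec.pct_walking) < 0:
            summary.skip(i, "negative activity percentage")
            continue
        records.append(rec)
        summary.n_read += 1
    return records


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_cgm(traces: Iterable[CgmTrace], path: str | Path) -> None:
    rows = [
        {"participant_id": t.participant_id, "timestamp": ts.isoformat(), "glucose": g}
        for t in traces
        for ts, g in t.samples
    ]
    pd.DataFrame(rows, columns=["participant_id", "timestamp", "glucose"]).to_csv(
        path, index=False
    )


def write_activity(logs: Iterable[ActivityEventLog], path: str | Path) -> None:
    rows = [
        {
            "participant_id": log.participant_id,
            "start": start.isoformat(),
            "duration_s": duration,
            "activity": activity,
        }
        for log in logs
        for start, duration, activity in log.events
    ]
    pd.DataFrame(rows, columns=["participant_id", "start", "duration_s", "activity"]).to_csv(
        path, index=False
    )


def write_meals(records: Iterable[MealRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id, "date": r.date.isoformat(),
               "meal_time": r.meal_time.strftime("%H:%M")}
        row.update({f: getattr(r, f) for f in MealRecord.NUTRIENT_FIELDS})
        row["leftover_fraction"] = r.leftover_fraction
        rows.append(row)
    cols = ["participant_id", "date", "meal_time", *MealRecord.NUTRIENT_FIELDS,
            "leftover_fraction"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_work(records: Iterable[WorkRecord], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "date": r.date.isoformat(),
            "work_start": r.work_start.strftime("%H:%M"),
            "work_end": r.work_end.strftime("%H:%M"),
            "work_from_home": r.work_from_home,
            "pct_sitting": r.pct_sitting,
            "pct_standing": r.pct_standing,
            "pct_walking": r.pct_walking,
            "phase": r.phase,
        }
        for r in records
    ]
    cols = ["participant_id", "date", "work_start", "work_end", "work_from_home",
            "pct_sitting", "pct_standing", "pct_walking", "phase"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
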