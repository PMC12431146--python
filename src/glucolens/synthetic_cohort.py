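"""Synthetic multimodal cohort with known ground-truth effect structure.

The study emulated here followed full-time working adults through three
phases -- Baseline, a "stand more" intervention and a "move more"
intervention, the latter two in randomized order -- with a 15-minute CGM,
a thigh-worn activity sensor, a standardized delivered lunch on workdays,
and daily food and work logs.

Because the original data are private, this module generates a cohort with
the same shape and a *known* causal structure so that every downstream
stage (feature assembly, predictors, counterfactual explanations) can be
tested for signal recovery:

* each lunch produces a glucose excursion with a gamma-shaped
  rise-then-decay kernel peaking ~45 min after the meal;
* the excursion amplitude rises with the meal's glycemic load and with
  pre-lunch sitting hours, and falls with pre-lunch stepping minutes --
  the directions clinical work reports for fiber/activity vs
  sitting/calories;
* self-reported work-log percentages are the true sensor-derived
  percentages plus truncated-Gaussian reporting error, so self-report and
  sensor feature sets differ realistically.

Default parameters put hyperglycemia (MaxBGL >= 140 mg/dL) prevalence near
40% of lunches so that class balancing is exercised.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glucolens.behavior_features import DEFAULT_CLASS_MAP, glycemic_load
from glucolens.log_ingest import (
    ActivityEventLog,
    CgmTrace,
    MealRecord,
    WorkRecord,
    write_activity,
    write_cgm,
    write_meals,
    write_work,
)

#: Gamma-kernel time-to-peak, minutes.
RESPONSE_TAU_MIN = 45.0

#: Physiologic floor for simulated glucose, mg/dL.
GLUCOSE_FLOOR = 40.0


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class GroundTruthParams:
    """Generating parameters, retained for parameter-recovery tests.

    gl_effect          mg/dL peak rise per glycemic-load unit
    stepping_effect    mg/dL peak reduction per pre-lunch stepping minute
    sitting_effect     mg/dL peak rise per pre-lunch sitting hour
    baseline_glucose_* per-participant fasting baseline, mg/dL
    noise_sd           iid CGM sensor noise, mg/dL
    """

    gl_effect: float = 1.7
    stepping_effect: float = 0.5
    sitting_effect: float = 1.2
    baseline_glucose_mean: float = 88.0
    baseline_glucose_sd: float = 7.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 10
    n_phases: int = 3
    workdays_per_phase: int = 5
    cgm_interval: int = 15  # minutes
    seed: int = 0
    effect_params: GroundTruthParams = field(default_factory=GroundTruthParams)
    start_date: dt.date = dt.date(2022, 3, 7)  # a Monday

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_phases < 1 or self.workdays_per_phase < 1:
            raise ConfigurationError("phase and workday counts must be >= 1")
        if self.cgm_interval < 1 or 60 % self.cgm_interval != 0:
            raise ConfigurationError("cgm_interval must divide 60")


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    bmi: float
    habitual_lunch_time: dt.time
    habitual_work_start: dt.time
    wfh_probability: float
    baseline_glucose: float
    phase_order: tuple[str, ...]


@dataclass
class RawDataBundle:
    """Everything the generator produced, plus the truth that produced it."""

    config: CohortConfig
    params: GroundTruthParams
    profiles: list[ParticipantProfile]
    cgm: list[CgmTrace]
    activity: list[ActivityEventLog]
    meals: list[MealRecord]
    work: list[WorkRecord]

    def bmi_by_participant(self) -> dict[str, float]:
        return {p.participant_id: p.bmi for p in self.profiles}

    def write_csvs(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_cgm(self.cgm, directory / "cgm.csv")
        write_activity(self.activity, directory / "activpal_events.csv")
        write_meals(self.meals, directory / "food_log.csv")
        write_work(self.work, directory / "work_log.csv")
        truth = {
            "params": dataclasses.asdict(self.params),
            "profiles": [
                {
                    "participant_id": p.participant_id,
                    "bmi": p.bmi,
                    "habitual_lunch_time": p.habitual_lunch_time.strftime("%H:%M"),
                    "habitual_work_start": p.habitual_work_start.strftime("%H:%M"),
                    "wfh_probability": p.wfh_probability,
                    "baseline_glucose": p.baseline_glucose,
                    "phase_order": list(p.phase_order),
                }
                for p in self.profiles
            ],
        }
        (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# meal-response kinetics


def response_kernel(u: np.ndarray | float) -> np.ndarray | float:
    """Unimodal gamma-shaped response r(u) = u * exp(1 - u) for u >= 0.

    r(0) = 0, peak r(1) = 1 at one kernel time-constant after the meal,
    then exponential decay -- the rise-then-fall morphology of a
    postprandial CGM excursion.
    """
    u = np.asarray(u, dtype=float)
    out = np.where(u > 0, u * np.exp(1.0 - u), 0.0)
    return out if out.ndim else float(out)


def meal_amplitude(
    gl: float, stepping_min: float, sitting_h: float, params: GroundTruthParams
) -> float:
    """Peak excursion height, mg/dL, clipped at zero."""
    a = (
        params.gl_effect * gl
        - params.stepping_effect * stepping_min
        + params.sitting_effect * sitting_h
    )
    return max(a, 0.0)


def simulate_cgm_day(
    date: dt.date,
    baseline: float,
    meal_events: list[tuple[pd.Timestamp, float]],
    params: GroundTruthParams,
    rng: np.random.Generator,
    cgm_interval: int = 15,
    tau_min: float = RESPONSE_TAU_MIN,
) -> list[tuple[pd.Timestamp, float]]:
    """One day of CGM samples: baseline + summed meal responses + noise.

    ``meal_events`` holds (meal timestamp, amplitude mg/dL) pairs. Responses
    superpose additively; samples are clipped to the physiologic floor.
    """
    day0 = pd.Timestamp(dt.datetime.combine(date, dt.time(0, 0)))
    n = 24 * 60 // cgm_interval
    minutes = np.arange(n) * cgm_interval
    glucose = np.full(n, baseline, dtype=float)
    for meal_ts, amplitude in meal_events:
        offset_min = (meal_ts - day0).total_seconds() / 60.0
        glucose += amplitude * response_kernel((minutes - offset_min) / tau_min)
    if params.noise_sd > 0:
        glucose += rng.normal(0.0, params.noise_sd, size=n)
    glucose = np.maximum(glucose, GLUCOSE_FLOOR)
    return [
        (day0 + pd.Timedelta(minutes=int(m)), float(g))
        for m, g in zip(minutes, glucose)
    ]


# ---------------------------------------------------------------------------
# day-level building blocks


def _draw_profiles(config: CohortConfig, rng: np.random.Generator
                   ) -> list[ParticipantProfile]:
    profiles = []
    phase_names = ["Baseline", "Stand", "Move"][: config.n_phases]
    for i in range(config.n_participants):
        interventions = phase_names[1:]
        order = list(rng.permutation(interventions)) if interventions else []
        lunch_min = int(rng.integers(11 * 60 + 30, 13 * 60 + 30))
        work_min = int(rng.integers(7 * 60 + 30, 9 * 60 + 30))
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                bmi=float(np.clip(rng.normal(32.8, 4.5), 20.0, 50.0)),
                habitual_lunch_time=dt.time(lunch_min // 60, lunch_min % 60),
                habitual_work_start=dt.time(work_min // 60, work_min % 60),
                wfh_probability=float(rng.uniform(0.1, 0.4)),
                baseline_glucose=float(
                    rng.normal(
                        config.effect_params.baseline_glucose_mean,
                        config.effect_params.baseline_glucose_sd,
                    )
                ),
                phase_order=tuple(phase_names[:1] + order),
            )
        )
    return profiles


# class-mix probabilities (sitting, standing, stepping) for waking bouts
_PHASE_MIX = {
    "Baseline": (0.62, 0.24, 0.14),
    "Stand": (0.48, 0.38, 0.14),
    "Move": (0.48, 0.24, 0.28),
    "Weekend": (0.55, 0.27, 0.18),
}
_CLASS_FOR_MIX = ("sedentary", "standing", "stepping")


def _simulate_activity_day(
    date: dt.date, phase: str, rng: np.random.Generator
) -> list[tuple[pd.Timestamp, float, str]]:
    """Tile one day [00:00, 24:00) with non-overlapping activity events."""
    day0 = pd.Timestamp(dt.datetime.combine(date, dt.time(0, 0)))
    # integer-second bookkeeping guarantees the tiling makes progress
    wake_s = int(round(rng.normal(6.5 * 3600, 1200)))
    sleep_s = int(round(rng.normal(22.5 * 3600, 1200)))
    events: list[tuple[pd.Timestamp, float, str]] = [
        (day0, float(wake_s), "lying_primary")
    ]
    probs = np.array(_PHASE_MIX[phase])
    cursor = wake_s
    while cursor < sleep_s:
        activity = _CLASS_FOR_MIX[int(rng.choice(3, p=probs))]
        scale = {"sedentary": 35.0, "standing": 15.0, "stepping": 8.0}[activity]
        duration = int(round(float(rng.exponential(scale)) * 60.0))
        duration = max(60, min(duration, sleep_s - cursor))
        events.append((day0 + pd.Timedelta(seconds=cursor), float(duration), activity))
        cursor += duration
    events.append(
        (day0 + pd.Timedelta(seconds=cursor), float(86400 - cursor), "lying_primary")
    )
    return events


def _draw_meal(
    pid: str, date: dt.date, lunch_time: dt.time, rng: np.random.Generator
) -> MealRecord:
    total_carbs = float(np.clip(rng.normal(60.0, 15.0), 15.0, 140.0))
    fiber = float(np.clip(rng.normal(5.0, 2.0), 0.5, 15.0))
    fiber = min(fiber, total_carbs)
    net_carbs = total_carbs - fiber
    fat = float(np.clip(rng.normal(25.0, 8.0), 5.0, 70.0))
    protein = float(np.clip(rng.normal(30.0, 8.0), 8.0, 70.0))
    sugar = float(np.clip(rng.normal(0.25, 0.1), 0.02, 0.6)) * total_carbs
    saturated_fat = float(np.clip(rng.normal(0.35, 0.1), 0.05, 0.7)) * fat
    trans_fat = float(np.clip(rng.normal(0.3, 0.3), 0.0, 2.0))
    calories = 4.0 * (total_carbs + protein) + 9.0 * fat
    leftover = 0.0 if rng.uniform() < 0.7 else float(rng.uniform(0.05, 0.4))
    return MealRecord(
        participant_id=pid,
        date=date,
        meal_time=lunch_time,
        calories=round(calories, 1),
        calories_from_fat=round(9.0 * fat, 1),
        saturated_fat=round(saturated_fat, 2),
        trans_fat=round(trans_fat, 2),
        cholesterol=round(float(np.clip(rng.normal(80.0, 30.0), 0.0, 300.0)), 1),
        sodium=round(float(np.clip(rng.normal(900.0, 300.0), 100.0, 3000.0)), 1),
        total_carbs=round(total_carbs, 2),
        sugar=round(sugar, 2),
        net_carbs=round(net_carbs, 2),
        fat=round(fat, 2),
        protein=round(protein, 2),
        fiber=round(fiber, 2),
        leftover_fraction=round(leftover, 3),
    )


def _true_work_percentages(
    events: list[tuple[pd.Timestamp, float, str]],
    work_start: pd.Timestamp,
    work_end: pd.Timestamp,
) -> tuple[float, float, float]:
    totals = {"sitting": 0.0, "standing": 0.0, "stepping": 0.0}
    lo, hi = work_start.value / 1e9, work_end.value / 1e9
    for start, duration, activity in events:
        s = start.value / 1e9
        sec = min(s + duration, hi) - max(s, lo)
        if sec > 0:
            totals[DEFAULT_CLASS_MAP[activity]] += sec
    denom = max(sum(totals.values()), 1e-9)
    return tuple(100.0 * totals[k] / denom for k in ("sitting", "standing", "stepping"))


def _self_report(true_pcts: tuple[float, float, float],
                 rng: np.random.Generator) -> tuple[float, float, float]:
    # truncated-Gaussian reporting error, sd 5 percentage points
    noisy = [max(p + float(rng.normal(0.0, 5.0)), 0.0) for p in true_pcts]
    total = sum(noisy)
    if total > 100.0:
        noisy = [100.0 * p / total for p in noisy]
    # integer-tenths bookkeeping keeps the reported sum at or below 100
    tenths = [int(round(p * 10.0)) for p in noisy]
    excess = sum(tenths) - 1000
    if excess > 0:
        tenths[tenths.index(max(tenths))] -= excess
    return tuple(t / 10.0 for t in tenths)


def _minutes_in_class(
    events: list[tuple[pd.Timestamp, float, str]],
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
    feature_class: str,
) -> float:
    lo, hi = window_start.value / 1e9, window_end.value / 1e9
    total = 0.0
    for start, duration, activity in events:
        if DEFAULT_CLASS_MAP[activity] != feature_class:
            continue
        s = start.value / 1e9
        sec = min(s + duration, hi) - max(s, lo)
        if sec > 0:
            total += sec
    return total / 60.0


# ---------------------------------------------------------------------------
# top-level generator


def generate_cohort(config: CohortConfig) -> RawDataBundle:
    """Generate the full multimodal bundle for one seeded cohort.

    Each phase spans whole calendar weeks (5 workdays per week); weekend
    days get CGM and activity data but no lunch or work log, so they never
    become modeling rows. Identical config (including seed) reproduces the
    bundle exactly.
    """
    rng = np.random.default_rng(config.seed)
    params = config.effect_params
    profiles = _draw_profiles(config, rng)

    cgm, activity, meals, work = [], [], [], []
    for profile in profiles:
        pid = profile.participant_id
        p_events: list[tuple[pd.Timestamp, float, str]] = []
        p_samples: list[tuple[pd.Timestamp, float]] = []
        day = config.start_date
        for phase in profile.phase_order:
            workdays_done = 0
            while workdays_done < config.workdays_per_phase:
                is_workday = day.weekday() < 5
                day_phase = phase if is_workday else "Weekend"
                events = _simulate_activity_day(day, day_phase, rng)
                p_events.extend(events)
                meal_events: list[tuple[pd.Timestamp, float]] = []

                # background breakfast and dinner excursions (no logs kept)
                for hour, sd in ((7.6, 0.5), (19.0, 0.75)):
                    t = pd.Timestamp(dt.datetime.combine(day, dt.time(0, 0)))
                    t += pd.Timedelta(hours=float(rng.normal(hour, sd)))
                    bg_gl = float(np.clip(rng.normal(18.0, 5.0), 0.0, 40.0))
                    meal_events.append((t, params.gl_effect * bg_gl))

                if is_workday:
                    lunch_min = int(
                        profile.habitual_lunch_time.hour * 60
                        + profile.habitual_lunch_time.minute
                        + rng.normal(0.0, 20.0)
                    )
                    lunch_min = int(np.clip(lunch_min, 10 * 60, 15 * 60))
                    # snap to the CGM grid so the excursion onset is observed
                    lunch_min -= lunch_min % config.cgm_interval
                    lunch_time = dt.time(lunch_min // 60, lunch_min % 60)
                    lunch_ts = pd.Timestamp(dt.datetime.combine(day, lunch_time))

                    start_min = int(
                        profile.habitual_work_start.hour * 60
                        + profile.habitual_work_start.minute
                        + rng.normal(0.0, 15.0)
                    )
                    start_min = int(np.clip(start_min, 6 * 60, 11 * 60))
                    work_start = dt.time(start_min // 60, start_min % 60)
                    end_min = start_min + int(rng.normal(8.5 * 60, 30.0))
                    end_min = int(np.clip(end_min, start_min + 6 * 60, 23 * 60))
                    work_end = dt.time(end_min // 60, end_min % 60)
                    ws_ts = pd.Timestamp(dt.datetime.combine(day, work_start))
                    we_ts = pd.Timestamp(dt.datetime.combine(day, work_end))

                    meal = _draw_meal(pid, day, lunch_time, rng)
                    scale = 1.0 - meal.leftover_fraction
                    gl = glycemic_load(
                        meal.net_carbs * scale, meal.fat * scale,
                        meal.protein * scale, meal.fiber * scale,
                    )
                    day0 = pd.Timestamp(dt.datetime.combine(day, dt.time(0, 0)))
                    stepping_min = _minutes_in_class(events, day0, lunch_ts, "stepping")
                    sitting_h = _minutes_in_class(events, day0, lunch_ts, "sitting") / 60.0
                    amplitude = meal_amplitude(gl, stepping_min, sitting_h, params)
                    meal_events.append((lunch_ts, amplitude))

                    true_pcts = _true_work_percentages(events, ws_ts, we_ts)
                    pct_sit, pct_stand, pct_walk = _self_report(true_pcts, rng)
                    meals.append(meal)
                    work.append(
                        WorkRecord(
                            participant_id=pid,
                            date=day,
                            work_start=work_start,
                            work_end=work_end,
                            work_from_home=int(rng.uniform() < profile.wfh_probability),
                            pct_sitting=pct_sit,
                            pct_standing=pct_stand,
                            pct_walking=pct_walk,
                            phase=phase,
                        )
                    )
                    workdays_done += 1

                p_samples.extend(
                    simulate_cgm_day(
                        day, profile.baseline_glucose, meal_events, params, rng,
                        config.cgm_interval,
                    )
                )
                day = day + dt.timedelta(days=1)
            # weekend/break days until the next Monday still produce CGM and
            # activity data, but no lunch or work log (never modeling rows)
            while day.weekday() != 0:
                events = _simulate_activity_day(day, "Weekend", rng)
                p_events.extend(events)
                meal_events = []
                for hour, sd in ((7.6, 0.5), (13.0, 0.75), (19.0, 0.75)):
                    t = pd.Timestamp(dt.datetime.combine(day, dt.time(0, 0)))
                    t += pd.Timedelta(hours=float(rng.normal(hour, sd)))
                    bg_gl = float(np.clip(rng.normal(18.0, 5.0), 0.0, 40.0))
                    meal_events.append((t, params.gl_effect * bg_gl))
                p_samples.extend(
                    simulate_cgm_day(
                        day, profile.baseline_glucose, meal_events, params, rng,
                        config.cgm_interval,
                    )
                )
                day = day + dt.timedelta(days=1)
        cgm.append(CgmTrace(pid, p_samples))
        activity.append(ActivityEventLog(pid, p_events))

    return RawDataBundle(
        config=config, params=params, profiles=profiles,
        cgm=cgm, activity=activity, meals=meals, work=work,
    )
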