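"""Seed-reproducible synthetic wearable data with injectable problem episodes.

The generator emulates the structure of consumer-wearable exports: a
per-minute step stream, a per-minute heart-rate stream and session-
structured sleep records with stage minutes and awakenings. Defaults
describe a *compliant* subject — one who at the default rule thresholds
produces problem-free days: ~12000 steps/day, ~7 h of night sleep with
short sleep-onset latency and few awakenings, waking heart rate ~74 bpm
with a resting floor above the bradycardia limit, occasional short
afternoon naps. It is parametric, not a statistical fit to any cohort.

:func:`inject_problem_episode` rewrites one day so that it provably
satisfies a chosen rule's condition (verified by running the detector on
the modified day before returning); all stream and session invariants are
preserved and other days are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as date_t
from datetime import datetime, time, timedelta
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from wearkg.io import SampleStream, SleepSession
from wearkg.observations import (
    HEART_PROPERTIES,
    MOVEMENT_PROPERTIES,
    Observation,
    PROPERTY_UNITS,
    SLEEP_PROPERTIES,
    classify_observation,
    observation_id,
)


class SyntheticProfile(BaseModel):
    """Parameters of one simulated subject."""

    subject_id: str = "tms6"
    start_date: date_t = date_t(2021, 3, 1)
    baseline_daily_steps_mean: float = 12000.0
    baseline_daily_steps_sd: float = 1500.0
    bedtime_hour: float = 23.0          # mean bedtime, hours since midnight
    bedtime_jitter_sd_min: float = 15.0
    asleep_minutes_mean: float = 420.0
    asleep_minutes_sd: float = 25.0
    fall_asleep_minutes_mean: float = 12.0
    fall_asleep_minutes_sd: float = 4.0
    awakenings_rate: float = 2.0        # Poisson mean per night
    hr_wake_mean: float = 74.0
    hr_wake_sd: float = 3.0
    hr_sleep_mean: float = 64.0
    hr_sleep_sd: float = 1.5
    hr_floor: float = 61.0              # resting floor of this simulated cohort
    hr_step_coupling: float = 0.2       # bpm per step/minute
    nap_propensity: float = 0.15
    nap_minutes_min: float = 20.0
    nap_minutes_max: float = 60.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticProfile":
        if min(self.baseline_daily_steps_mean, self.asleep_minutes_mean,
               self.fall_asleep_minutes_mean, self.hr_wake_mean,
               self.hr_sleep_mean) <= 0:
            raise ValueError("profile means must be positive")
        if not 0 <= self.nap_propensity <= 1:
            raise ValueError("nap_propensity must be in [0, 1]")
        return self


@dataclass
class SyntheticDataset:
    """Generated streams and sessions for one subject."""

    profile: SyntheticProfile
    n_days: int
    seed: int
    steps: SampleStream
    heart_rate: SampleStream
    sessions: list[SleepSession]

    def __iter__(self):
        return iter((self.steps, self.heart_rate, self.sessions))

    @property
    def dates(self) -> list[date_t]:
        return [self.profile.start_date + timedelta(days=d) for d in range(self.n_days)]

    def slice(self, d0: date_t, d1: date_t) -> "SyntheticDataset":
        """Restrict to samples on [d0, d1) and sessions ending there."""
        t0 = datetime.combine(d0, time.min)
        t1 = datetime.combine(d1, time.min)
        return replace(
            self,
            steps=SampleStream(subject_id=self.steps.subject_id, kind="steps",
                               samples=[s for s in self.steps.samples if t0 <= s[0] < t1]),
            heart_rate=SampleStream(subject_id=self.heart_rate.subject_id, kind="heart_rate",
                                    samples=[s for s in self.heart_rate.samples if t0 <= s[0] < t1]),
            sessions=[s for s in self.sessions if t0 <= s.end < t1],
        )


def _diurnal_weights(minutes_of_day: np.ndarray) -> np.ndarray:
    """Mild mid-afternoon peak in activity propensity."""
    hours = minutes_of_day / 60.0
    return 0.15 + np.exp(-((hours - 14.0) ** 2) / (2 * 4.5 ** 2))


def generate_subject_days(
    profile: SyntheticProfile, n_days: int, seed: Optional[int] = None
) -> SyntheticDataset:
    """Generate ``n_days`` of per-minute steps, heart rate and sleep sessions.

    Steps are non-negative integers with a diurnal pattern and are zero
    during sleep; heart rate is elevated with activity and lower during
    sleep; each night's sleep session has consistent stage minutes. A
    fixed seed reproduces the output exactly.
    """
    if n_days < 0:
        raise ValueError("n_days must be non-negative")
    seed = profile.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    start = datetime.combine(profile.start_date, time.min)
    total_minutes = 1440 * n_days
    sleep_mask = np.zeros(total_minutes, dtype=bool)
    sessions: list[SleepSession] = []

    def mark(session_start: datetime, session_end: datetime) -> None:
        a = max(0, int((session_start - start).total_seconds() // 60))
        b = min(total_minutes, int((session_end - start).total_seconds() // 60))
        if b > a:
            sleep_mask[a:b] = True

    for d in range(n_days):
        day = profile.start_date + timedelta(days=d)
        # Night sleep ending on the morning of `day`: bedtime the evening before.
        bed_jitter = rng.normal(0.0, profile.bedtime_jitter_sd_min)
        bed = (datetime.combine(day - timedelta(days=1), time.min)
               + timedelta(minutes=round(profile.bedtime_hour * 60 + bed_jitter)))
        fall = max(1, round(rng.normal(profile.fall_asleep_minutes_mean,
                                       profile.fall_asleep_minutes_sd)))
        asleep = max(60, round(rng.normal(profile.asleep_minutes_mean,
                                          profile.asleep_minutes_sd)))
        awakenings = int(rng.poisson(profile.awakenings_rate))
        awake = 3 * awakenings
        end = bed + timedelta(minutes=fall + asleep + awake)
        deep = round(0.18 * asleep)
        rem = round(0.22 * asleep)
        sessions.append(SleepSession(
            subject_id=profile.subject_id, start=bed, end=end,
            minutes_to_fall_asleep=fall, minutes_deep=deep,
            minutes_light=asleep - deep - rem, minutes_rem=rem,
            minutes_awake=awake, awakenings_count=awakenings,
            is_main_sleep=True,
        ))
        mark(bed, end)
        if rng.random() < profile.nap_propensity:
            nap_len = round(rng.uniform(profile.nap_minutes_min, profile.nap_minutes_max))
            nap_start = (datetime.combine(day, time.min)
                         + timedelta(minutes=round(14 * 60 + rng.uniform(-60, 120))))
            nap_end = nap_start + timedelta(minutes=nap_len + 2)
            sessions.append(SleepSession(
                subject_id=profile.subject_id, start=nap_start, end=nap_end,
                minutes_to_fall_asleep=2, minutes_light=nap_len,
                awakenings_count=0, is_main_sleep=False,
            ))
            mark(nap_start, nap_end)

    steps_per_min = np.zeros(total_minutes, dtype=np.int64)
    for d in range(n_days):
        lo, hi = 1440 * d, 1440 * (d + 1)
        wake_idx = np.flatnonzero(~sleep_mask[lo:hi]) + lo
        total = max(0, round(rng.normal(profile.baseline_daily_steps_mean,
                                        profile.baseline_daily_steps_sd)))
        if wake_idx.size and total:
            weights = _diurnal_weights((wake_idx - lo).astype(float))
            weights /= weights.sum()
            steps_per_min[wake_idx] = rng.multinomial(total, weights)

    hr = np.where(
        sleep_mask,
        rng.normal(profile.hr_sleep_mean, profile.hr_sleep_sd, total_minutes),
        rng.normal(profile.hr_wake_mean, profile.hr_wake_sd, total_minutes)
        + profile.hr_step_coupling * steps_per_min,
    )
    hr = np.clip(np.round(hr), profile.hr_floor, 190).astype(np.int64)

    timestamps = [start + timedelta(minutes=m) for m in range(total_minutes)]
    steps_stream = SampleStream(
        subject_id=profile.subject_id, kind="steps",
        samples=[(ts, float(v)) for ts, v in zip(timestamps, steps_per_min)])
    hr_stream = SampleStream(
        subject_id=profile.subject_id, kind="heart_rate",
        samples=[(ts, float(v)) for ts, v in zip(timestamps, hr)])
    sessions.sort(key=lambda s: s.start)
    return SyntheticDataset(profile=profile, n_days=n_days, seed=seed,
                            steps=steps_stream, heart_rate=hr_stream,
                            sessions=sessions)


# -- episode injection ------------------------------------------------------

class InjectionError(ValueError):
    pass


def _edit_minutes(stream: SampleStream, start: datetime, end: datetime,
                  value_fn) -> SampleStream:
    """Replace values of samples with timestamps in [start, end)."""
    samples = [(ts, float(value_fn(ts, v)) if start <= ts < end else v)
               for ts, v in stream.samples]
    return SampleStream(subject_id=stream.subject_id, kind=stream.kind, samples=samples)


def _main_session_index(data: SyntheticDataset, day: date_t) -> int:
    for i, s in enumerate(data.sessions):
        if s.end.date() == day and s.is_main_sleep:
            return i
    raise InjectionError(f"no main sleep session ends on {day}")


def _rebuild(session: SleepSession, **changes) -> SleepSession:
    fields = session.model_dump()
    fields.update(changes)
    fields["efficiency"] = changes.get("efficiency")  # recompute unless forced
    return SleepSession(**fields)


def inject_problem_episode(
    data: SyntheticDataset,
    problem_type: str,
    day: date_t | str,
    params: Optional[dict] = None,
) -> SyntheticDataset:
    """Return a copy of ``data`` whose ``day`` satisfies ``problem_type``.

    The modified day is post-checked by running the detector on a window
    around it; the function raises if the target rule does not fire.
    Days other than ``day`` are not modified.
    """
    from wearkg.rules import detect_problems  # local import to avoid a cycle

    if isinstance(day, str):
        day = date_t.fromisoformat(day)
    params = dict(params or {})
    if day not in set(data.dates):
        raise InjectionError(f"date {day} outside the generated range")

    day0 = datetime.combine(day, time.min)
    sessions = list(data.sessions)
    steps, hr = data.steps, data.heart_rate

    def set_asleep(idx: int, stream_updates: bool, target_asleep: float,
                   new_end: datetime | None = None) -> None:
        nonlocal sessions, steps, hr
        s = sessions[idx]
        scale = target_asleep / max(s.asleep_minutes, 1.0)
        deep = round(s.minutes_deep * scale)
        rem = round(s.minutes_rem * scale)
        light = round(target_asleep) - deep - rem
        end = new_end if new_end is not None else s.start + timedelta(
            minutes=s.minutes_to_fall_asleep + target_asleep + s.minutes_awake)
        sessions[idx] = _rebuild(s, minutes_deep=deep, minutes_rem=rem,
                                 minutes_light=light, end=end)
        if stream_updates:
            old_end, new_e = s.end, sessions[idx].end
            if new_e > old_end:  # grew: silence the newly-asleep minutes
                steps = _edit_minutes(steps, old_end, new_e, lambda ts, v: 0)
                hr = _edit_minutes(hr, old_end, new_e,
                                   lambda ts, v: data.profile.hr_sleep_mean)
            elif new_e < old_end:  # shrank: freed minutes are restless waking
                steps = _edit_minutes(steps, new_e, old_end, lambda ts, v: 0)
                hr = _edit_minutes(hr, new_e, old_end, lambda ts, v: 85)

    def add_nap(nap_start: datetime, asleep_min: float) -> None:
        nonlocal sessions, steps, hr
        nap_end = nap_start + timedelta(minutes=asleep_min + 2)
        sessions.append(SleepSession(
            subject_id=data.profile.subject_id, start=nap_start, end=nap_end,
            minutes_to_fall_asleep=2, minutes_light=asleep_min,
            awakenings_count=0, is_main_sleep=False))
        steps = _edit_minutes(steps, nap_start, nap_end, lambda ts, v: 0)
        hr = _edit_minutes(hr, nap_start, nap_end,
                           lambda ts, v: data.profile.hr_sleep_mean)

    def waking_window(start_min: int, length: int, hr_value: float,
                      step_value: float, cap_hr: float) -> None:
        """Force an HR/steps pattern on [start, start+length) and cap the
        run with breaking HR values just outside it. The window is pushed
        past the morning sleep end, and naps it would overlap are removed
        (their minutes are overwritten anyway)."""
        nonlocal sessions, steps, hr
        morning_end = max((s.end for s in sessions
                           if s.end.date() == day and s.is_main_sleep),
                          default=day0)
        a = max(day0 + timedelta(minutes=start_min),
                morning_end + timedelta(minutes=2))
        b = a + timedelta(minutes=length)
        sessions = [s for s in sessions
                    if s.is_main_sleep
                    or s.end <= a - timedelta(minutes=1)
                    or s.start >= b + timedelta(minutes=1)]
        steps = _edit_minutes(steps, a, b, lambda ts, v: step_value)
        hr = _edit_minutes(hr, a, b, lambda ts, v: hr_value)
        hr = _edit_minutes(hr, a - timedelta(minutes=1), a, lambda ts, v: cap_hr)
        hr = _edit_minutes(hr, b, b + timedelta(minutes=1), lambda ts, v: cap_hr)

    if problem_type == "Insomnia":
        idx = _main_session_index(data, day)
        sessions[idx] = _rebuild(sessions[idx], minutes_to_fall_asleep=params.get(
            "fall_asleep_minutes", 45))
    elif problem_type == "Restlessness":
        idx = _main_session_index(data, day)
        sessions[idx] = _rebuild(sessions[idx],
                                 awakenings_count=int(params.get("awakenings", 14)))
    elif problem_type == "TooMuchSleep":
        idx = _main_session_index(data, day)
        set_asleep(idx, True, params.get("asleep_minutes", 540))
    elif problem_type == "LackOfSleep":
        idx = _main_session_index(data, day)
        # drop the day's naps so the daily total really is the main sleep
        for j in sorted((j for j, s in enumerate(sessions)
                         if s.end.date() == day and not s.is_main_sleep), reverse=True):
            del sessions[j]
        set_asleep(idx, True, params.get("asleep_minutes", 240))
    elif problem_type == "IncreasedNapping":
        n = int(params.get("nap_count", 3))
        length = params.get("nap_minutes", 40)
        for k in range(n):
            add_nap(day0 + timedelta(minutes=10 * 60 + 210 * k), length)
    elif problem_type == "NapCloseToBedtime":
        nxt = day + timedelta(days=1)
        try:
            main_idx = _main_session_index(data, nxt)
        except InjectionError as exc:
            raise InjectionError(
                f"cannot inject NapCloseToBedtime on {day}: no following main sleep"
            ) from exc
        bed = data.sessions[main_idx].start
        gap = params.get("gap_minutes", 60)
        length = params.get("nap_minutes", 40)
        add_nap(bed - timedelta(minutes=gap + length + 2), length)
    elif problem_type == "LowSleepQuality":
        idx = _main_session_index(data, day)
        s = sessions[idx]
        target = params.get("efficiency", 80.0)
        new_in_bed = s.asleep_minutes / (target / 100.0)
        extra = new_in_bed - s.in_bed_minutes
        if extra > 0:
            new_end = s.end + timedelta(minutes=round(extra))
            sessions[idx] = _rebuild(
                s, end=new_end,
                minutes_awake=s.minutes_awake + round(extra))
            steps = _edit_minutes(steps, s.end, new_end, lambda ts, v: 0)
            hr = _edit_minutes(hr, s.end, new_end,
                               lambda ts, v: data.profile.hr_sleep_mean + 4)
    elif problem_type == "StressOrPain":
        waking_window(int(params.get("start_minute", 9 * 60)),
                      int(params.get("length", 330)),
                      hr_value=params.get("hr", 96), step_value=0, cap_hr=80)
    elif problem_type == "LowHeartRate":
        waking_window(int(params.get("start_minute", 10 * 60)),
                      int(params.get("length", 15)),
                      hr_value=params.get("hr", 55), step_value=0, cap_hr=75)
    elif problem_type == "Inactivity":
        waking_window(int(params.get("start_minute", 9 * 60)),
                      int(params.get("length", 330)),
                      hr_value=params.get("hr", 72), step_value=0, cap_hr=95)
    elif problem_type == "LackOfMovement":
        waking_window(int(params.get("start_minute", int(7.5 * 60))),
                      int(params.get("length", 825)),
                      hr_value=params.get("hr", 75), step_value=0, cap_hr=110)
    elif problem_type == "LackOfExercise":
        target = params.get("steps", 4000)
        day_end = day0 + timedelta(days=1)
        total = sum(v for ts, v in steps.samples if day0 <= ts < day_end)
        factor = target / total if total > 0 else 0.0
        steps = _edit_minutes(steps, day0, day_end,
                              lambda ts, v: float(int(v * factor)))
    else:
        raise InjectionError(f"unknown problem type: {problem_type!r}")

    sessions.sort(key=lambda s: s.start)
    modified = replace(data, steps=steps, heart_rate=hr, sessions=sessions)

    check = modified.slice(day - timedelta(days=1), day + timedelta(days=2))
    found = detect_problems(check.steps, check.heart_rate, check.sessions)
    if not any(p.problem_type == problem_type
               and p.temporal_extent[0].date() == day for p in found):
        raise InjectionError(
            f"injection of {problem_type} on {day} did not trigger the rule")
    return modified


# -- benchmark object generation --------------------------------------------

_PROPERTY_FEATURE = (
    [(p, "movement") for p in sorted(MOVEMENT_PROPERTIES)]
    + [(p, "sleep") for p in sorted(SLEEP_PROPERTIES)]
    + [(p, "heart") for p in sorted(HEART_PROPERTIES)]
)


def generate_benchmark_objects(n: int, seed: int = 0,
                               subject_id: str = "bench") -> list[Observation]:
    """``n`` classified observations with a realistic property mix
    (mostly per-minute steps and heart rate, some sleep metrics)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    weights = np.array([8.0 if p in ("steps", "heart_rate") else 1.0
                        for p, _ in _PROPERTY_FEATURE])
    weights /= weights.sum()
    start = datetime(2021, 3, 1)
    out = []
    for i in range(n):
        prop, feature = _PROPERTY_FEATURE[int(rng.choice(len(_PROPERTY_FEATURE), p=weights))]
        ts = start + timedelta(minutes=i)
        obs = Observation(
            id=observation_id(subject_id, prop, ts),
            subject_id=subject_id, feature_of_interest=feature,
            observed_property=prop,
            result=float(np.round(rng.uniform(0, 120), 1)),
            unit=PROPERTY_UNITS[prop],
            phenomenon_time=(ts, ts + timedelta(minutes=1)),
        )
        classify_observation(obs)
        out.append(obs)
    return out
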