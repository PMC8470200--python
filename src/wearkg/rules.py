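"""Symbolic rule base for detecting problem situations.

The rule base mirrors an a-priori set of twelve clinician-defined rules
with strict numeric limits. Daily rules aggregate a subject's sleep
sessions and step counts per calendar day:

    time to fall asleep in a day      > 1800 s    -> Insomnia
    sleep interruptions in a day      > 10        -> Restlessness
    total sleep in a day              > 480 min   -> TooMuchSleep
    total sleep in a day              < 300 min   -> LackOfSleep
    asleep in naps in a day           > 100 min   -> IncreasedNapping
    nap ends < 2 h before main sleep start        -> NapCloseToBedtime
    session sleep efficiency          < 85        -> LowSleepQuality
    steps in a day                    < 8000      -> LackOfExercise

Window rules scan the per-minute heart-rate stream for maximal runs of
minutes satisfying a heart-rate condition; a run fires when its cumulative
step count satisfies the step condition and its length exceeds the
duration threshold:

    steps < 50   & HR > 90  for > 300 min  -> StressOrPain
    steps < 1000 & HR < 80  for > 300 min  -> Inactivity
    steps < 500  & HR < 100 for > 800 min  -> LackOfMovement
    any maximal run of HR < 60             -> LowHeartRate

All comparisons are strict. The step condition in composite rules is
cumulative over the window while the heart-rate condition is per minute
(per-minute step counts rarely approach 500, which would otherwise make
those limits vacuous). By default, heart-rate minutes that fall inside a
sleep session are excluded from window rules: sustained low heart rate
with no steps is the normal physiology of sleep, and the waking-hour
reading is the clinically meaningful one (``include_sleep_minutes``
restores the raw behaviour). Thresholds can be overridden per subject.
"""

from __future__ import annotations

import operator
from bisect import bisect_left
from dataclasses import dataclass, field
from datetime import date as date_t
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from wearkg.io import SampleStream, SleepSession
from wearkg.kg import KnowledgeGraph, build_graph
from wearkg.observations import (
    Observation,
    PROPERTY_UNITS,
    observation_id,
    observations_from_sessions,
    observations_from_stream,
)
from wearkg.situations import ProblemSituation, instantiate_problem, problem_to_graph

Comparator = Literal["<", ">"]
_CMP = {"<": operator.lt, ">": operator.gt}

RuleScope = Literal["daily", "session", "window", "per_reading_run"]


class Condition(BaseModel):
    variable: str
    comparator: Comparator
    threshold: float
    unit: str = ""

    def holds(self, value: float) -> bool:
        return _CMP[self.comparator](value, self.threshold)


class RuleSpec(BaseModel):
    """One detection rule: scope, strict conditions, optional duration."""

    problem_type: str
    scope: RuleScope
    conditions: list[Condition]
    window_min_duration: Optional[float] = None  # minutes, window scope only

    @model_validator(mode="after")
    def _check(self) -> "RuleSpec":
        for c in self.conditions:
            if c.threshold <= 0:
                raise ValueError(
                    f"{self.problem_type}: threshold for {c.variable} must be positive")
        if self.scope == "window" and self.window_min_duration is None:
            raise ValueError(f"{self.problem_type}: window rule needs window_min_duration")
        return self

    def condition(self, variable: str) -> Condition:
        for c in self.conditions:
            if c.variable == variable:
                return c
        raise KeyError(f"{self.problem_type}: no condition on {variable!r}")

    def with_overrides(self, overrides: dict) -> "RuleSpec":
        """Return a copy with per-variable thresholds / duration replaced."""
        spec = self.model_copy(deep=True)
        for key, value in overrides.items():
            if key == "window_min_duration":
                spec.window_min_duration = float(value)
                continue
            found = False
            for c in spec.conditions:
                if c.variable == key:
                    c.threshold = float(value)
                    found = True
            if not found:
                raise KeyError(f"{self.problem_type}: no condition on {key!r} to override")
        return spec


def _rule(ptype: str, scope: RuleScope, conds: list[tuple], duration: float | None = None) -> RuleSpec:
    return RuleSpec(
        problem_type=ptype, scope=scope,
        conditions=[Condition(variable=v, comparator=c, threshold=t, unit=u)
                    for v, c, t, u in conds],
        window_min_duration=duration,
    )


def default_rules() -> dict[str, RuleSpec]:
    return {r.problem_type: r for r in [
        _rule("Insomnia", "daily", [("fall_asleep_seconds", ">", 1800, "s")]),
        _rule("Restlessness", "daily", [("interruptions", ">", 10, "count")]),
        _rule("TooMuchSleep", "daily", [("sleep_minutes", ">", 480, "min")]),
        _rule("LackOfSleep", "daily", [("sleep_minutes", "<", 300, "min")]),
        _rule("IncreasedNapping", "daily", [("nap_minutes", ">", 100, "min")]),
        _rule("NapCloseToBedtime", "daily", [("nap_gap_minutes", "<", 120, "min")]),
        _rule("LowSleepQuality", "session", [("efficiency", "<", 85, "percent")]),
        _rule("LackOfExercise", "daily", [("steps", "<", 8000, "steps")]),
        _rule("StressOrPain", "window",
              [("steps", "<", 50, "steps"), ("heart_rate", ">", 90, "bpm")], 300),
        _rule("Inactivity", "window",
              [("steps", "<", 1000, "steps"), ("heart_rate", "<", 80, "bpm")], 300),
        _rule("LackOfMovement", "window",
              [("steps", "<", 500, "steps"), ("heart_rate", "<", 100, "bpm")], 800),
        _rule("LowHeartRate", "per_reading_run", [("heart_rate", "<", 60, "bpm")]),
    ]}


class Rulebase(BaseModel):
    """Default rules plus per-subject threshold overrides and options."""

    rules: dict[str, RuleSpec] = Field(default_factory=default_rules)
    overrides: dict[str, dict[str, dict]] = Field(default_factory=dict)
    include_sleep_minutes: bool = False
    # Alternative napping criterion (naps per day); no default threshold.
    nap_count_threshold: Optional[int] = None

    def resolve(self, subject_id: str | None = None) -> dict[str, RuleSpec]:
        resolved = dict(self.rules)
        for ptype, ov in self.overrides.get(subject_id or "", {}).items():
            if ptype not in resolved:
                raise KeyError(f"override for unknown rule {ptype!r}")
            resolved[ptype] = resolved[ptype].with_overrides(ov)
        return resolved

    @classmethod
    def from_file(cls, path: str | Path) -> "Rulebase":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        base = cls()
        if "rules" in raw:
            for ptype, ov in raw["rules"].items():
                if ptype not in base.rules:
                    raise KeyError(f"unknown rule {ptype!r} in config")
                base.rules[ptype] = base.rules[ptype].with_overrides(ov)
        base.overrides = raw.get("overrides", {})
        base.include_sleep_minutes = raw.get("include_sleep_minutes", False)
        base.nap_count_threshold = raw.get("nap_count_threshold")
        return base


_KNOWN_RULE_IDS = frozenset((
    "Insomnia", "Restlessness", "TooMuchSleep", "LackOfSleep",
    "IncreasedNapping", "NapCloseToBedtime", "LowSleepQuality",
    "LackOfExercise", "StressOrPain", "Inactivity", "LackOfMovement",
    "LowHeartRate",
))


def default_rulebase() -> Rulebase:
    return Rulebase()


# -- day partitioning and aggregation --------------------------------------

def _minute(ts: datetime) -> datetime:
    return ts.replace(second=0, microsecond=0)


@dataclass
class DayContext:
    subject_id: str
    date: date_t
    steps: list[tuple[datetime, float]] = field(default_factory=list)
    heart_rate: list[tuple[datetime, float]] = field(default_factory=list)
    sessions: list[SleepSession] = field(default_factory=list)


@dataclass
class SessionInfo:
    session: SleepSession
    is_nap: bool

    @property
    def efficiency(self) -> float:
        return float(self.session.efficiency)

    @property
    def id(self) -> str:
        return observation_id(self.session.subject_id, "asleep_duration",
                              self.session.start)


@dataclass
class DailyAggregate:
    """Per-day totals consumed by the daily rules."""

    subject_id: str
    date: date_t
    totals: dict[str, float]
    per_session: list[SessionInfo]
    has_sleep_data: bool
    step_samples: list[tuple[datetime, float]]
    next_main_sleep_start: Optional[datetime] = None

    @property
    def has_step_data(self) -> bool:
        return bool(self.step_samples)


def partition_by_day(
    streams: Iterable[SampleStream],
    sessions: Sequence[SleepSession],
) -> dict[date_t, DayContext]:
    """Assign every sample to the date of its timestamp and every sleep
    session to the date of its end (the morning a night's sleep finishes)."""
    contexts: dict[date_t, DayContext] = {}
    subject = ""

    def ctx(day: date_t) -> DayContext:
        if day not in contexts:
            contexts[day] = DayContext(subject_id=subject, date=day)
        return contexts[day]

    for stream in streams:
        subject = stream.subject_id or subject
        for ts, value in stream.samples:
            c = ctx(ts.date())
            if stream.kind == "steps":
                c.steps.append((ts, value))
            else:
                c.heart_rate.append((ts, value))
    for s in sessions:
        subject = s.subject_id or subject
        ctx(s.end.date()).sessions.append(s)
    for c in contexts.values():
        c.subject_id = c.subject_id or subject
        c.sessions.sort(key=lambda s: s.start)
    return dict(sorted(contexts.items()))


def designate_naps(sessions: Sequence[SleepSession]) -> list[SessionInfo]:
    """Mark one session of a day as main sleep, the rest as naps.

    The ``is_main_sleep`` flag wins when any session carries it; otherwise
    the longest session (ties broken by earliest start) is main sleep.
    """
    infos = [SessionInfo(session=s, is_nap=True) for s in sessions]
    if not infos:
        return infos
    flagged = [i for i in infos if i.session.is_main_sleep is True]
    if flagged:
        for i in flagged:
            i.is_nap = False
        return infos
    main = max(infos, key=lambda i: (i.session.asleep_minutes, -i.session.start.timestamp()))
    main.is_nap = False
    return infos


def compute_daily_aggregates(context: DayContext, rulebase: Rulebase | None = None) -> DailyAggregate:
    """Aggregate one day: sleep totals, interruptions, naps and steps.

    A day with no sessions yields an aggregate flagged as having no sleep
    data; sleep rules are skipped on such days (missing data is
    non-adherence, not zero sleep).
    """
    infos = designate_naps(context.sessions)
    sleep_minutes = sum(i.session.asleep_minutes for i in infos)
    fall_asleep_seconds = 60.0 * sum(i.session.minutes_to_fall_asleep for i in infos)
    interruptions = sum(i.session.awakenings_count for i in infos)
    naps = [i for i in infos if i.is_nap]
    totals = {
        "sleep_minutes": sleep_minutes,
        "fall_asleep_seconds": fall_asleep_seconds,
        "interruptions": float(interruptions),
        "nap_minutes": sum(i.session.asleep_minutes for i in naps),
        "nap_count": float(len(naps)),
        "steps": float(sum(v for _, v in context.steps)),
    }
    return DailyAggregate(
        subject_id=context.subject_id,
        date=context.date,
        totals=totals,
        per_session=infos,
        has_sleep_data=bool(infos),
        step_samples=list(context.steps),
    )


# -- daily rule evaluation --------------------------------------------------

def _day_extent(day: date_t) -> tuple[datetime, datetime]:
    start = datetime.combine(day, time.min)
    return (start, start + timedelta(days=1))


def _session_obs(sessions: Iterable[SleepSession], prop: str) -> list[Observation]:
    out = []
    for s in sessions:
        out.extend(o for o in observations_from_sessions([s], classify=False)
                   if o.observed_property == prop)
    return out


def _step_obs(subject_id: str, samples: Sequence[tuple[datetime, float]]) -> list[Observation]:
    return [Observation(
        id=observation_id(subject_id, "steps", ts),
        subject_id=subject_id, feature_of_interest="movement",
        observed_property="steps", result=float(v), unit=PROPERTY_UNITS["steps"],
        phenomenon_time=(ts, ts + timedelta(minutes=1)),
    ) for ts, v in samples]


def _hr_obs(subject_id: str, samples: Sequence[tuple[datetime, float]]) -> list[Observation]:
    return [Observation(
        id=observation_id(subject_id, "heart_rate", ts),
        subject_id=subject_id, feature_of_interest="heart",
        observed_property="heart_rate", result=float(v), unit=PROPERTY_UNITS["heart_rate"],
        phenomenon_time=(ts, ts + timedelta(minutes=1)),
    ) for ts, v in samples]


#: daily rule -> (aggregate variable, sleep property interpreted on firing)
_DAILY_SIMPLE = {
    "Insomnia": ("fall_asleep_seconds", "minutes_to_fall_asleep"),
    "Restlessness": ("interruptions", "awake_count"),
    "TooMuchSleep": ("sleep_minutes", "asleep_duration"),
    "LackOfSleep": ("sleep_minutes", "asleep_duration"),
    "IncreasedNapping": ("nap_minutes", "asleep_duration"),
}


def evaluate_daily_rules(
    agg: DailyAggregate,
    rules: dict[str, RuleSpec] | Rulebase,
    nap_count_threshold: Optional[int] = None,
) -> list[ProblemSituation]:
    """Evaluate all daily/session-scope rules on one day's aggregate.

    Emits at most one problem per rule per day; comparisons are strict.
    Sleep rules are skipped on days without sleep data, the step rule on
    days with no step samples. NapCloseToBedtime is evaluated here only
    when ``agg.next_main_sleep_start`` has been filled by the pipeline.
    """
    if isinstance(rules, Rulebase):
        nap_count_threshold = rules.nap_count_threshold
        rules = rules.resolve(agg.subject_id)
    for name in rules:
        if name not in _KNOWN_RULE_IDS:
            raise KeyError(f"unknown rule id {name!r}")
    problems: list[ProblemSituation] = []
    extent = _day_extent(agg.date)
    sessions = [i.session for i in agg.per_session]
    naps = [i.session for i in agg.per_session if i.is_nap]

    if agg.has_sleep_data:
        for ptype, (variable, prop) in _DAILY_SIMPLE.items():
            rule = rules.get(ptype)
            if rule is None:
                continue
            if not rule.condition(variable).holds(agg.totals[variable]):
                continue
            pool = naps if ptype == "IncreasedNapping" else sessions
            obs = _session_obs(pool, prop)
            if obs:
                problems.append(instantiate_problem(ptype, obs, extent))
        if (nap_count_threshold is not None and "IncreasedNapping" in rules
                and agg.totals["nap_count"] > nap_count_threshold
                and not any(p.problem_type == "IncreasedNapping" for p in problems)):
            obs = _session_obs(naps, "asleep_duration")
            if obs:
                problems.append(instantiate_problem("IncreasedNapping", obs, extent))
        if "LowSleepQuality" in rules:
            cond = rules["LowSleepQuality"].condition("efficiency")
            failing = [i.session for i in agg.per_session if cond.holds(i.efficiency)]
            if failing:
                problems.append(instantiate_problem(
                    "LowSleepQuality", _session_obs(failing, "efficiency"), extent))
        if "NapCloseToBedtime" in rules and agg.next_main_sleep_start is not None:
            gate = rules["NapCloseToBedtime"].condition("nap_gap_minutes")
            close = [n for n in naps
                     if 0 <= (agg.next_main_sleep_start - n.end).total_seconds() / 60.0
                     and gate.holds((agg.next_main_sleep_start - n.end).total_seconds() / 60.0)]
            if close:
                problems.append(instantiate_problem(
                    "NapCloseToBedtime", _session_obs(close, "asleep_duration"), extent))

    if agg.has_step_data and "LackOfExercise" in rules:
        if rules["LackOfExercise"].condition("steps").holds(agg.totals["steps"]):
            problems.append(instantiate_problem(
                "LackOfExercise", _step_obs(agg.subject_id, agg.step_samples), extent))

    problems.sort(key=lambda p: (p.temporal_extent[0], p.problem_type))
    return problems


# -- window rules ------------------------------------------------------------

@dataclass
class Window:
    """A maximal run of minutes satisfying a per-minute heart-rate condition."""

    start: datetime  # first minute, floored
    end: datetime    # exclusive
    total_steps: float
    hr_condition: str

    @property
    def length(self) -> int:
        return int((self.end - self.start).total_seconds() // 60)


_EPOCH = datetime(1970, 1, 1)


def _minute_index(ts: datetime) -> int:
    return int((_minute(ts) - _EPOCH).total_seconds()) // 60


def _from_minute_index(m: int) -> datetime:
    return _EPOCH + timedelta(minutes=m)


def _hr_runs(hr: SampleStream, cond: Condition) -> list[tuple[datetime, datetime]]:
    """Maximal runs of consecutive minutes whose HR sample satisfies cond.

    Minutes lacking an HR sample break runs, as do non-satisfying minutes.
    Returns (start minute, end minute exclusive) pairs in order.
    """
    if not hr.samples:
        return []
    mins = np.fromiter((_minute_index(ts) for ts, _ in hr.samples), dtype=np.int64,
                       count=len(hr.samples))
    vals = np.fromiter((v for _, v in hr.samples), dtype=np.float64,
                       count=len(hr.samples))
    ok = vals < cond.threshold if cond.comparator == "<" else vals > cond.threshold
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return []
    adjacent = (np.diff(idx) == 1) & (np.diff(mins[idx]) == 1)
    breaks = np.flatnonzero(~adjacent)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(_from_minute_index(int(mins[idx[a]])),
             _from_minute_index(int(mins[idx[b]]) + 1))
            for a, b in zip(starts, ends)]


def find_hr_step_windows(
    steps: SampleStream, hr: SampleStream, rule: RuleSpec
) -> list[Window]:
    """Qualifying windows for a composite steps-and-heart-rate rule.

    A window is a maximal contiguous run of minutes each carrying an HR
    sample that satisfies the rule's heart-rate comparison; it qualifies
    when the cumulative steps over the run satisfy the step comparison and
    the run is strictly longer than ``window_min_duration`` minutes.
    """
    hr_cond = rule.condition("heart_rate")
    step_cond = rule.condition("steps")
    assert rule.window_min_duration is not None
    desc = f"heart_rate {hr_cond.comparator} {hr_cond.threshold:g}"
    step_mins = np.fromiter((_minute_index(ts) for ts, _ in steps.samples),
                            dtype=np.int64, count=len(steps.samples))
    step_vals = np.fromiter((v for _, v in steps.samples), dtype=np.float64,
                            count=len(steps.samples))
    prefix = np.concatenate(([0.0], np.cumsum(step_vals)))
    out = []
    for start, end in _hr_runs(hr, hr_cond):
        length = (end - start).total_seconds() / 60.0
        if length <= rule.window_min_duration:
            continue
        lo = np.searchsorted(step_mins, _minute_index(start), side="left")
        hi = np.searchsorted(step_mins, _minute_index(end), side="left")
        total = float(prefix[hi] - prefix[lo])
        if step_cond.holds(total):
            out.append(Window(start=start, end=end, total_steps=total, hr_condition=desc))
    return out


def find_low_hr_runs(hr: SampleStream, rule: RuleSpec | None = None) -> list[Window]:
    """Maximal runs of minutes with heart rate below the bradycardia limit."""
    if rule is None:
        rule = default_rules()["LowHeartRate"]
    cond = rule.condition("heart_rate")
    desc = f"heart_rate {cond.comparator} {cond.threshold:g}"
    return [Window(start=s, end=e, total_steps=0.0, hr_condition=desc)
            for s, e in _hr_runs(hr, cond)]


# -- full pipeline -----------------------------------------------------------

def _mask_sleep(hr: SampleStream, sessions: Sequence[SleepSession]) -> SampleStream:
    """Drop HR samples falling inside any sleep session interval."""
    if not sessions:
        return hr
    intervals = sorted((s.start, s.end) for s in sessions)
    starts = [a for a, _ in intervals]
    kept = []
    for ts, v in hr.samples:
        i = bisect_left(starts, ts)
        inside = (i < len(intervals) and intervals[i][0] == ts) or \
                 (i > 0 and intervals[i - 1][0] <= ts < intervals[i - 1][1])
        if not inside:
            kept.append((ts, v))
    return SampleStream(subject_id=hr.subject_id, kind="heart_rate", samples=kept)


def _fill_next_main_sleep(
    aggregates: dict[date_t, DailyAggregate], sessions: Sequence[SleepSession]
) -> None:
    """For each day, record the start of the next main sleep after the
    day's last nap (main sleep usually starts that evening but is
    attributed to the next morning's date)."""
    infos: list[SessionInfo] = []
    for agg in aggregates.values():
        infos.extend(agg.per_session)
    mains = sorted((i.session.start for i in infos if not i.is_nap))
    for agg in aggregates.values():
        naps = [i.session for i in agg.per_session if i.is_nap]
        if not naps:
            continue
        last_nap_end = max(n.end for n in naps)
        nxt = next((m for m in mains if m >= last_nap_end), None)
        agg.next_main_sleep_start = nxt


def detect_problems(
    steps: SampleStream,
    hr: SampleStream,
    sessions: Sequence[SleepSession],
    rulebase: Rulebase | None = None,
) -> list[ProblemSituation]:
    """Run the full rule base over one subject's data.

    Deterministic: identical inputs and configuration yield an identical,
    (start, type)-sorted problem list.
    """
    rulebase = rulebase or default_rulebase()
    subject = steps.subject_id or hr.subject_id or (sessions[0].subject_id if sessions else "")
    rules = rulebase.resolve(subject)
    problems: list[ProblemSituation] = []

    contexts = partition_by_day([steps, hr], sessions)
    aggregates = {day: compute_daily_aggregates(c, rulebase) for day, c in contexts.items()}
    _fill_next_main_sleep(aggregates, sessions)
    for agg in aggregates.values():
        problems.extend(evaluate_daily_rules(agg, rules, rulebase.nap_count_threshold))

    hr_eval = hr if rulebase.include_sleep_minutes else _mask_sleep(hr, sessions)
    for ptype in ("StressOrPain", "Inactivity", "LackOfMovement"):
        rule = rules.get(ptype)
        if rule is None:
            continue
        for window in find_hr_step_windows(steps, hr_eval, rule):
            obs = (_hr_obs(subject, [(ts, v) for ts, v in hr_eval.samples
                                     if window.start <= ts < window.end])
                   + _step_obs(subject, [(ts, v) for ts, v in steps.samples
                                         if window.start <= ts < window.end]))
            problems.append(instantiate_problem(ptype, obs, (window.start, window.end)))
    if "LowHeartRate" in rules:
        for window in find_low_hr_runs(hr_eval, rules["LowHeartRate"]):
            obs = _hr_obs(subject, [(ts, v) for ts, v in hr_eval.samples
                                    if window.start <= ts < window.end])
            problems.append(instantiate_problem("LowHeartRate", obs, (window.start, window.end)))

    problems.sort(key=lambda p: (p.temporal_extent[0], p.problem_type))
    return problems


def run_rulebase(
    steps: SampleStream,
    hr: SampleStream,
    sessions: Sequence[SleepSession],
    rulebase: Rulebase | None = None,
) -> tuple[list[ProblemSituation], KnowledgeGraph]:
    """Detect problems and return them with the enriched knowledge graph
    (all observations plus every problem in full DnS shape)."""
    observations = (observations_from_stream(steps)
                    + observations_from_stream(hr)
                    + observations_from_sessions(sessions))
    kg = build_graph(observations)
    problems = detect_problems(steps, hr, sessions, rulebase)
    for p in problems:
        problem_to_graph(p, kg)
    return problems, kg


# -- SHACL-SPARQL export -----------------------------------------------------

_SPARQL_PREFIXES = """\
PREFIX sosa: <http://www.w3.org/ns/sosa/>
PREFIX dul:  <http://www.ontologydesignpatterns.org/ont/dul/DUL.owl#>
PREFIX em:   <https://w3id.org/wearkg/em#>
PREFIX ms:   <https://w3id.org/wearkg/ms/>
"""

#: Observation-level WHERE pattern per rule: (property local name, filter
#: template on ?value, concept/entity pair for the constructed view).
_SHACL_PATTERNS = {
    "Insomnia": ("minutes_to_fall_asleep", "(?value * 60) {cmp} {thr:g}", "sleep"),
    "Restlessness": ("awake_count", "?value {cmp} {thr:g}", "sleep"),
    "TooMuchSleep": ("asleep_duration", "?value {cmp} {thr:g}", "sleep"),
    "LackOfSleep": ("asleep_duration", "?value {cmp} {thr:g}", "sleep"),
    "IncreasedNapping": ("asleep_duration", "?value {cmp} {thr:g}", "sleep"),
    "NapCloseToBedtime": ("asleep_duration", None, "sleep"),
    "LowSleepQuality": ("efficiency", "?value {cmp} {thr:g}", "sleep"),
    "LackOfExercise": ("steps", "?value {cmp} {thr:g}", "movement"),
    "StressOrPain": ("heart_rate", "?value {cmp} {thr:g}", "heart"),
    "Inactivity": ("heart_rate", "?value {cmp} {thr:g}", "heart"),
    "LackOfMovement": ("heart_rate", "?value {cmp} {thr:g}", "heart"),
    "LowHeartRate": ("heart_rate", "?value {cmp} {thr:g}", "heart"),
}

_SCOPE_COMMENTS = {
    "daily": "Aggregation over a calendar day is performed by the native engine; "
             "the pattern below matches the contributing observations.",
    "session": "Evaluated per sleep session by the native engine.",
    "window": "Temporal-window semantics (maximal per-minute runs with a "
              "cumulative step condition and a strict duration threshold) "
              "exceed a single SHACL-SPARQL graph pattern and are evaluated "
              "by the native engine; the construct below illustrates the "
              "per-minute heart-rate condition only.",
    "per_reading_run": "Maximal-run grouping of consecutive readings is "
                       "performed by the native engine.",
}


def _construct_body(rule: RuleSpec) -> str:
    prop, filt_tmpl, concept = _SHACL_PATTERNS[rule.problem_type]
    if filt_tmpl is not None:
        var = ("heart_rate" if prop == "heart_rate"
               else "steps" if prop == "steps" else None)
        cond = rule.condition(var) if var else rule.conditions[0]
        filt = "  FILTER (" + filt_tmpl.format(cmp=cond.comparator, thr=cond.threshold) + ")\n"
    else:
        filt = ""
    return f"""{_SPARQL_PREFIXES}
CONSTRUCT {{
  ?problem a em:Problem, em:{rule.problem_type}, dul:Situation ;
      em:hasView ?view ; dul:satisfies ?view ;
      em:interprets ?obs ; dul:isSettingFor ?obs .
  ?view a em:View, dul:Description ; dul:defines ?concept .
  ?concept a dul:Concept ; dul:classifies ?property .
}}
WHERE {{
  ?obs a sosa:Observation ;
      sosa:observedProperty ?property ;
      sosa:hasSimpleResult ?value .
  FILTER (?property = ms:property/{prop})
{filt}  BIND (IRI(CONCAT(STR(?obs), "/problem/{rule.problem_type}")) AS ?problem)
  BIND (IRI(CONCAT(STR(?problem), "/view")) AS ?view)
  BIND (IRI(CONCAT(STR(?view), "/concept/{concept}")) AS ?concept)
}}"""


def export_shacl_rules(rulebase: Rulebase | None = None) -> str:
    """Export the rule base as a SHACL-SPARQL rules document (Turtle).

    One ``sh:SPARQLRule`` per rule, whose CONSTRUCT body produces the DnS
    problem shape and whose WHERE clause matches observations with the
    rule's numeric filter. Rules whose semantics exceed a single graph
    pattern (windows, daily aggregation, runs) carry an ``rdfs:comment``
    stating what the native engine evaluates.
    """
    from rdflib import RDF, RDFS, Graph, Literal, Namespace

    rulebase = rulebase or Rulebase()
    SH = Namespace("http://www.w3.org/ns/shacl#")
    EMNS = Namespace("https://w3id.org/wearkg/em#")
    g = Graph()
    g.bind("sh", SH)
    g.bind("em", EMNS)
    g.bind("rdfs", RDFS)
    for ptype in sorted(rulebase.rules):
        rule = rulebase.rules[ptype]
        shape = EMNS[f"{ptype}RuleShape"]
        node = EMNS[f"{ptype}Rule"]
        g.add((shape, RDF.type, SH.NodeShape))
        g.add((shape, SH.targetClass, Namespace("http://www.w3.org/ns/sosa/").Observation))
        g.add((shape, SH.rule, node))
        g.add((node, RDF.type, SH.SPARQLRule))
        g.add((node, SH.construct, Literal(_construct_body(rule))))
        comment = _SCOPE_COMMENTS.get(rule.scope)
        if comment:
            g.add((node, RDFS.comment, Literal(comment)))
    return g.serialize(format="turtle")
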