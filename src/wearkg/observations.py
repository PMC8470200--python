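"""SOSA-style observations and their forward classification.

Each measurement becomes an observation: a container linking a feature of
interest (movement, sleep or heart), an observed property from a controlled
vocabulary, a numeric result with unit, and a half-open phenomenon-time
interval. Observations are classified into a fixed hierarchy of observation
types whose membership conditions are equivalence axioms of the form

    MovementObservation == Observation
        and observedProperty in MovementProperty
        and featureOfInterest == movement
    WalkingFeature == MovementObservation
        and observedProperty in {distance, elevation, floors, steps}

Because every axiom combines only a feature nominal and a finite property
set, classification is realised as forward evaluation of the finite
predicates, closed under parents — semantically exact for this hierarchy,
with no general OWL reasoner involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Callable, Iterable, Union

from wearkg.io import SampleStream, SleepSession

FEATURES = ("movement", "sleep", "heart")

MOVEMENT_PROPERTIES = frozenset({
    "steps", "distance", "elevation", "floors",
    "fair_activity", "high_activity", "light_activity", "sedentary",
})
# Core sleep vocabulary plus minutes_to_fall_asleep / efficiency, which the
# sleep rules consume (documented extension of the core set).
SLEEP_PROPERTIES = frozenset({
    "asleep_count", "asleep_duration", "awake_count", "awake_duration",
    "minutes_to_fall_asleep", "efficiency",
})
HEART_PROPERTIES = frozenset({"heart_rate", "cardio", "fat_burn", "peak"})

VOCABULARY = MOVEMENT_PROPERTIES | SLEEP_PROPERTIES | HEART_PROPERTIES

#: Units of the observed properties, for observation results.
PROPERTY_UNITS = {
    "steps": "steps", "distance": "m", "elevation": "m", "floors": "floors",
    "fair_activity": "min", "high_activity": "min", "light_activity": "min",
    "sedentary": "min",
    "asleep_count": "count", "asleep_duration": "min",
    "awake_count": "count", "awake_duration": "min",
    "minutes_to_fall_asleep": "min", "efficiency": "percent",
    "heart_rate": "bpm", "cardio": "min", "fat_burn": "min", "peak": "min",
}


@dataclass
class Observation:
    """One SOSA-style observation with its inferred type classes."""

    id: str
    subject_id: str
    feature_of_interest: str
    observed_property: str
    result: float
    unit: str
    phenomenon_time: tuple[datetime, datetime]  # half-open [start, end)
    inferred_classes: frozenset[str] = field(default_factory=lambda: frozenset({"Observation"}))

    def __post_init__(self) -> None:
        if self.observed_property not in VOCABULARY:
            raise ValueError(f"unknown observed property: {self.observed_property!r}")
        if self.feature_of_interest not in FEATURES:
            raise ValueError(f"unknown feature of interest: {self.feature_of_interest!r}")
        start, end = self.phenomenon_time
        if end <= start:
            raise ValueError("phenomenon time end must be after start")


Predicate = Callable[[str, str], bool]


@dataclass(frozen=True)
class ObservationClassHierarchy:
    """Observation type classes: name -> (parent, membership predicate).

    A predicate takes (feature_of_interest, observed_property) and states
    the class's *local* membership condition; actual membership also
    requires the parent's condition (inherited equivalence axioms), which
    :func:`classify_observation` enforces by evaluating root-downwards.
    """

    classes: dict[str, tuple[str | None, Predicate]]

    def parent(self, name: str) -> str | None:
        return self.classes[name][0]

    def ancestors(self, name: str) -> list[str]:
        out = []
        cur = self.parent(name)
        while cur is not None:
            out.append(cur)
            cur = self.parent(cur)
        return out


def _prop_in(props: frozenset[str] | set[str]) -> Predicate:
    props = frozenset(props)
    return lambda foi, prop: prop in props


def _feature_and_props(feature: str, props: frozenset[str]) -> Predicate:
    return lambda foi, prop: foi == feature and prop in props


DEFAULT_HIERARCHY = ObservationClassHierarchy(classes={
    "Observation": (None, lambda foi, prop: True),
    "MovementObservation": ("Observation", _feature_and_props("movement", MOVEMENT_PROPERTIES)),
    "MovementIntensity": ("MovementObservation", _prop_in(
        {"fair_activity", "high_activity", "light_activity", "sedentary"})),
    "WalkingFeature": ("MovementObservation", _prop_in(
        {"distance", "elevation", "floors", "steps"})),
    "SleepObservation": ("Observation", _feature_and_props("sleep", SLEEP_PROPERTIES)),
    "AsleepCount": ("SleepObservation", _prop_in({"asleep_count"})),
    "AsleepDuration": ("SleepObservation", _prop_in({"asleep_duration"})),
    "AwakeCount": ("SleepObservation", _prop_in({"awake_count"})),
    "AwakeDuration": ("SleepObservation", _prop_in({"awake_duration"})),
    "HeartObservation": ("Observation", _feature_and_props("heart", HEART_PROPERTIES)),
    "Cardio": ("HeartObservation", _prop_in({"cardio"})),
    "FatBurn": ("HeartObservation", _prop_in({"fat_burn"})),
    "HeartRate": ("HeartObservation", _prop_in({"heart_rate"})),
    "Peak": ("HeartObservation", _prop_in({"peak"})),
})


def classify_observation(
    obs: Observation,
    hierarchy: ObservationClassHierarchy = DEFAULT_HIERARCHY,
) -> frozenset[str]:
    """Return every class whose (inherited) membership condition holds.

    Membership of a class requires its own predicate plus those of all its
    ancestors; the result is therefore closed under parents by
    construction. Observations matching no specific axiom classify as
    {"Observation"} only. The result is also stored on the observation.
    """
    member: set[str] = set()
    for name, (parent, pred) in hierarchy.classes.items():
        conditions = [pred] + [hierarchy.classes[a][1] for a in hierarchy.ancestors(name)]
        if all(c(obs.feature_of_interest, obs.observed_property) for c in conditions):
            member.add(name)
    obs.inferred_classes = frozenset(member)
    return obs.inferred_classes


# -- construction from raw inputs ------------------------------------------

_STREAM_FEATURE = {"steps": ("movement", "steps"), "heart_rate": ("heart", "heart_rate")}

#: Properties derived from one sleep session, with their value extractors.
SLEEP_SESSION_PROPERTIES: dict[str, Callable[[SleepSession], float]] = {
    "asleep_duration": lambda s: s.asleep_minutes,
    "awake_count": lambda s: float(s.awakenings_count),
    "awake_duration": lambda s: s.minutes_awake,
    "minutes_to_fall_asleep": lambda s: s.minutes_to_fall_asleep,
    "efficiency": lambda s: float(s.efficiency),
}


def observation_id(subject_id: str, observed_property: str, start: datetime) -> str:
    """Deterministic observation identifier (IRI-safe local name)."""
    return f"obs/{subject_id}/{observed_property}/{start.strftime('%Y%m%dT%H%M%S')}"


def observations_from_stream(stream: SampleStream, classify: bool = True) -> list[Observation]:
    """One observation per sample; instantaneous samples get [t, t + 1 min)."""
    feature, prop = _STREAM_FEATURE[stream.kind]
    unit = PROPERTY_UNITS[prop]
    out = []
    for ts, value in stream.samples:
        obs = Observation(
            id=observation_id(stream.subject_id, prop, ts),
            subject_id=stream.subject_id,
            feature_of_interest=feature,
            observed_property=prop,
            result=float(value),
            unit=unit,
            phenomenon_time=(ts, ts + timedelta(minutes=1)),
        )
        if classify:
            classify_observation(obs)
        out.append(obs)
    return out


def observations_from_sessions(
    sessions: Iterable[SleepSession], classify: bool = True
) -> list[Observation]:
    """Per session, one observation per derived sleep property."""
    out = []
    for s in sessions:
        for prop, extract in SLEEP_SESSION_PROPERTIES.items():
            obs = Observation(
                id=observation_id(s.subject_id, prop, s.start),
                subject_id=s.subject_id,
                feature_of_interest="sleep",
                observed_property=prop,
                result=float(extract(s)),
                unit=PROPERTY_UNITS[prop],
                phenomenon_time=(s.start, s.end),
            )
            if classify:
                classify_observation(obs)
            out.append(obs)
    return out


def to_observations(
    data: Union[SampleStream, Iterable[SleepSession]],
    subject_id: str | None = None,
) -> list[Observation]:
    """Convert a validated input (stream or sleep sessions) to observations.

    Identifiers are deterministic functions of (subject, property, start),
    so the same input always yields the same observations.
    """
    if isinstance(data, SampleStream):
        if subject_id is not None and data.subject_id != subject_id:
            raise ValueError("stream subject does not match requested subject")
        return observations_from_stream(data)
    if isinstance(data, Iterable):
        sessions = list(data)
        if all(isinstance(s, SleepSession) for s in sessions):
            if subject_id is not None and any(s.subject_id != subject_id for s in sessions):
                raise ValueError("session subject does not match requested subject")
            return observations_from_sessions(sessions)
    raise TypeError(f"cannot convert {type(data).__name__} to observations")
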