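"""Readers and writers for wearable data files.

Input formats mirror what consumer wearables expose through their cloud
APIs: per-minute sample streams (steps, heart rate) as CSV with columns
``subject_id,timestamp,value``, and sleep sessions as a JSON array with
per-session stage minutes, awakenings and optional efficiency.

Timestamps are ISO-8601 without timezone; a single implicit local timezone
is assumed throughout. Missing minutes are represented by absence, never by
zero: a gap in a stream means the device did not record, which downstream
rules treat differently from a recorded zero.
"""

from __future__ import annotations

import csv
import json
import math
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

StreamKind = Literal["steps", "heart_rate"]


class DataFormatError(ValueError):
    """A file violated the wire format or an invariant of its record type."""


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


class SampleStream(BaseModel):
    """An ordered per-minute stream of one measurement kind for one subject."""

    subject_id: str
    kind: StreamKind
    samples: list[tuple[datetime, float]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_invariants(self) -> "SampleStream":
        prev: Optional[datetime] = None
        for i, (ts, value) in enumerate(self.samples):
            if value < 0:
                raise DataFormatError(f"sample {i}: negative value {value}")
            if self.kind == "steps" and value != int(value):
                raise DataFormatError(f"sample {i}: steps value {value} is not an integer")
            if prev is not None:
                if ts == prev:
                    raise DataFormatError(f"sample {i}: duplicate timestamp {ts.isoformat()}")
                if ts < prev:
                    raise DataFormatError(f"sample {i}: timestamps not increasing")
            prev = ts
        return self

    def __len__(self) -> int:
        return len(self.samples)

    def total(self) -> float:
        return sum(v for _, v in self.samples)


class SleepSession(BaseModel):
    """One continuous sleep session with stage minutes and awakenings.

    ``efficiency`` is the percentage of in-bed time spent asleep; when a
    device does not report it, it is filled as round(100 x asleep / in-bed)
    with ties away from zero (rules compare it against integer thresholds).
    """

    subject_id: str
    start: datetime
    end: datetime
    minutes_to_fall_asleep: float = 0
    minutes_deep: float = 0
    minutes_light: float = 0
    minutes_rem: float = 0
    minutes_awake: float = 0
    awakenings_count: int = 0
    efficiency: Optional[float] = None
    is_main_sleep: Optional[bool] = None

    @property
    def asleep_minutes(self) -> float:
        return self.minutes_deep + self.minutes_light + self.minutes_rem

    @property
    def in_bed_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    @property
    def duration_ms(self) -> int:
        return int((self.end - self.start).total_seconds() * 1000)

    @model_validator(mode="after")
    def _check_and_fill(self) -> "SleepSession":
        if self.end <= self.start:
            raise DataFormatError(
                f"session for {self.subject_id}: end {self.end} not after start {self.start}"
            )
        for name in ("minutes_to_fall_asleep", "minutes_deep", "minutes_light",
                     "minutes_rem", "minutes_awake"):
            if getattr(self, name) < 0:
                raise DataFormatError(f"session for {self.subject_id}: negative {name}")
        if self.awakenings_count < 0:
            raise DataFormatError(f"session for {self.subject_id}: negative awakenings_count")
        stage_sum = self.asleep_minutes + self.minutes_awake
        if stage_sum > self.in_bed_minutes + 1:
            raise DataFormatError(
                f"session for {self.subject_id}: stage minutes {stage_sum} exceed "
                f"in-bed minutes {self.in_bed_minutes} + 1"
            )
        if self.efficiency is None:
            in_bed = self.in_bed_minutes
            self.efficiency = float(_round_half_away(100.0 * self.asleep_minutes / in_bed)) if in_bed > 0 else 0.0
        if not 0 <= self.efficiency <= 100:
            raise DataFormatError(
                f"session for {self.subject_id}: efficiency {self.efficiency} outside [0, 100]"
            )
        return self


class ExerciseSession(BaseModel):
    """Minutes spent in heart-rate zones during one exercise session."""

    subject_id: str
    start: datetime
    end: datetime
    minutes_fat_burn: float = 0
    minutes_cardio: float = 0
    minutes_peak: float = 0

    @model_validator(mode="after")
    def _check(self) -> "ExerciseSession":
        if self.end <= self.start:
            raise DataFormatError("exercise session end not after start")
        for name in ("minutes_fat_burn", "minutes_cardio", "minutes_peak"):
            if getattr(self, name) < 0:
                raise DataFormatError(f"exercise session: negative {name}")
        return self


def read_sample_stream(path: str | Path, kind: StreamKind) -> SampleStream:
    """Read a per-minute sample CSV (``subject_id,timestamp,value``).

    Rows are sorted by timestamp before validation; duplicate timestamps,
    negative values and malformed rows are rejected with the row number.
    An empty file (or header only) yields an empty stream with subject ``""``.
    """
    path = Path(path)
    rows: list[tuple[datetime, float]] = []
    subject: Optional[str] = None
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and header and header[0].strip().lower() != "subject_id":
            raise DataFormatError(f"{path}: missing header row 'subject_id,timestamp,value'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise DataFormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            sid, ts_raw, val_raw = (c.strip() for c in row)
            try:
                ts = datetime.fromisoformat(ts_raw)
                value = float(val_raw)
            except ValueError as exc:
                raise DataFormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if subject is None:
                subject = sid
            elif sid != subject:
                raise DataFormatError(f"{path}:{lineno}: multiple subjects in one stream file")
            rows.append((ts, value))
    rows.sort(key=lambda r: r[0])
    try:
        return SampleStream(subject_id=subject or "", kind=kind, samples=rows)
    except (DataFormatError, ValidationError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def read_sleep_sessions(path: str | Path) -> list[SleepSession]:
    """Read a JSON array of sleep-session records, sorted by start time."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise DataFormatError(f"{path}: expected a JSON array of sessions")
    sessions = []
    for i, record in enumerate(raw):
        try:
            sessions.append(SleepSession(**record))
        except (DataFormatError, ValidationError, TypeError) as exc:
            raise DataFormatError(f"{path}: session {i}: {exc}") from exc
    sessions.sort(key=lambda s: s.start)
    return sessions


def write_sample_stream(stream: SampleStream, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "timestamp", "value"])
        for ts, value in stream.samples:
            out = int(value) if stream.kind == "steps" else value
            writer.writerow([stream.subject_id, ts.isoformat(), out])


def write_sleep_sessions(sessions: Iterable[SleepSession], path: str | Path) -> None:
    records = []
    for s in sessions:
        record = s.model_dump()
        record["start"] = s.start.isoformat()
        record["end"] = s.end.isoformat()
        if record.get("is_main_sleep") is None:
            record.pop("is_main_sleep", None)
        records.append(record)
    Path(path).write_text(json.dumps(records, indent=2), encoding="utf-8")


# -- problem output --------------------------------------------------------

_PROBLEM_FIELDS = ["id", "problem_type", "category", "subject_id",
                   "start", "end", "interpreted_observation_ids"]


def write_problems(problems: list, path: str | Path, format: str = "json") -> None:
    """Write detected problems as JSON or CSV (one record per problem)."""
    path = Path(path)
    records = [_problem_record(p) for p in problems]
    if format == "json":
        path.write_text(json.dumps(records, indent=2), encoding="utf-8")
    elif format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_PROBLEM_FIELDS)
            writer.writeheader()
            for record in records:
                record = dict(record)
                record["interpreted_observation_ids"] = ";".join(
                    record["interpreted_observation_ids"])
                writer.writerow(record)
    else:
        raise DataFormatError(f"unknown problem output format: {format!r}")


def _problem_record(p) -> dict:
    return {
        "id": p.id,
        "problem_type": p.problem_type,
        "category": p.category,
        "subject_id": p.subject_id,
        "start": p.temporal_extent[0].isoformat(),
        "end": p.temporal_extent[1].isoformat(),
        "interpreted_observation_ids": list(p.interpreted_observation_ids),
    }


def read_problems(path: str | Path, format: str = "json") -> list[dict]:
    """Read back a problems file into plain records (round-trip of write)."""
    path = Path(path)
    if format == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
    elif format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            records = []
            for row in csv.DictReader(fh):
                row["interpreted_observation_ids"] = (
                    row["interpreted_observation_ids"].split(";")
                    if row["interpreted_observation_ids"] else [])
                records.append(row)
    else:
        raise DataFormatError(f"unknown problem output format: {format!r}")
    return records
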