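"""Dashboard-style aggregation of streams and detected problems.

Reproduces the data transformations behind a clinician dashboard:
resampling a per-minute stream to a chosen resolution (minute, hour, day,
week, month, year) with sum or average aggregation, min/avg/max summaries
under each chart, a per-day sleep series with stage breakdown, and a
problem timeline. Weeks start on Monday; months and years are
calendar-aligned. Empty buckets are omitted, so sum-resampling conserves
the in-range total at every resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_t
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd

from wearkg.io import SampleStream, SleepSession
from wearkg.rules import designate_naps
from wearkg.situations import ProblemSituation

_FREQ = {
    "minute": "min",
    "hour": "h",
    "day": "D",
    "week": "W-MON",   # closed/label "left" => weeks [Mon, Mon), labelled
    "month": "MS",     # by their starting Monday
    "year": "YS",
}

RESOLUTIONS = tuple(_FREQ)
AGGREGATIONS = ("sum", "average")


@dataclass
class ResampledSeries:
    resolution: str
    agg: str
    points: list[tuple[datetime, float]] = field(default_factory=list)

    def values(self) -> list[float]:
        return [v for _, v in self.points]


def resample(
    stream: SampleStream,
    resolution: str,
    agg: str = "sum",
    date_range: Optional[tuple[datetime, datetime]] = None,
) -> ResampledSeries:
    """Aggregate a stream into resolution-aligned buckets.

    ``date_range`` is half-open [start, end); buckets with no samples are
    omitted rather than reported as zero.
    """
    if resolution not in _FREQ:
        raise ValueError(f"unknown resolution: {resolution!r}")
    if agg not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation: {agg!r}")
    samples = stream.samples
    if date_range is not None:
        start, end = date_range
        samples = [s for s in samples if start <= s[0] < end]
    if not samples:
        return ResampledSeries(resolution=resolution, agg=agg)
    series = pd.Series([v for _, v in samples],
                       index=pd.DatetimeIndex([ts for ts, _ in samples]))
    grouped = series.resample(_FREQ[resolution], label="left", closed="left")
    out = grouped.sum() if agg == "sum" else grouped.mean()
    counts = grouped.count()
    points = [(ts.to_pydatetime(), float(v))
              for (ts, v), n in zip(out.items(), counts) if n > 0]
    return ResampledSeries(resolution=resolution, agg=agg, points=points)


def summary_stats(series: ResampledSeries | Sequence[float]) -> dict[str, float]:
    """Average, minimum and maximum of the bucket values."""
    values = series.values() if isinstance(series, ResampledSeries) else list(series)
    if not values:
        raise ValueError("summary of an empty series")
    return {
        "average": sum(values) / len(values),
        "minimum": min(values),
        "maximum": max(values),
    }


def sleep_day_series(sessions: Iterable[SleepSession]) -> list[dict]:
    """Per-day total sleep minutes with a per-stage breakdown payload."""
    by_day: dict[date_t, list[SleepSession]] = {}
    for s in sessions:
        by_day.setdefault(s.end.date(), []).append(s)
    out = []
    for day in sorted(by_day):
        group = by_day[day]
        naps = [i for i in designate_naps(group) if i.is_nap]
        out.append({
            "date": day.isoformat(),
            "sleep_minutes": sum(s.asleep_minutes for s in group),
            "minutes_deep": sum(s.minutes_deep for s in group),
            "minutes_light": sum(s.minutes_light for s in group),
            "minutes_rem": sum(s.minutes_rem for s in group),
            "minutes_awake": sum(s.minutes_awake for s in group),
            "nap_minutes": sum(i.session.asleep_minutes for i in naps),
            "awakenings": sum(s.awakenings_count for s in group),
        })
    return out


def problem_timeline(
    problems: Iterable[ProblemSituation],
    date_range: Optional[tuple[datetime, datetime]] = None,
) -> list[dict]:
    """Problems in range as ordered timeline records (start, then type)."""
    records = []
    for p in problems:
        start, end = p.temporal_extent
        if date_range is not None and not (date_range[0] <= start < date_range[1]):
            continue
        records.append({
            "start": start.isoformat(),
            "end": end.isoformat(),
            "problem_type": p.problem_type,
            "category": p.category,
            "subject_id": p.subject_id,
            "id": p.id,
        })
    records.sort(key=lambda r: (r["start"], r["problem_type"]))
    return records


def build_report(
    subject_id: str,
    steps: SampleStream,
    heart_rate: SampleStream,
    sessions: Sequence[SleepSession],
    problems: Sequence[ProblemSituation],
    resolution: str = "day",
    agg: str = "sum",
    date_range: Optional[tuple[datetime, datetime]] = None,
) -> dict:
    """One JSON-serialisable report per (subject, range, resolution, agg)."""
    steps_series = resample(steps, resolution, agg, date_range)
    hr_series = resample(heart_rate, resolution, "average", date_range)
    report = {
        "subject_id": subject_id,
        "resolution": resolution,
        "aggregation": agg,
        "steps": {
            "points": [(ts.isoformat(), v) for ts, v in steps_series.points],
            "summary": summary_stats(steps_series) if steps_series.points else None,
        },
        "heart_rate": {
            "points": [(ts.isoformat(), v) for ts, v in hr_series.points],
            "summary": summary_stats(hr_series) if hr_series.points else None,
        },
        "sleep": sleep_day_series(sessions),
        "problems": problem_timeline(problems, date_range),
    }
    return report
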