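"""Scalability harness: ingestion timing and rule-evaluation scaling.

Task 1 measures the time to materialise an increasing number of classified
observations into the knowledge graph. Task 2 measures, for a growing
day-aligned prefix of a synthetic dataset and for individual rules, the
evaluation time and the number of problem objects generated.

Wall-clock times are reported, never asserted: they depend on the host.
The structural properties are what matters — generated-object counts are
deterministic under a fixed seed and non-decreasing across nested
(day-prefix) datasets, because every prefix is cut at a whole-day boundary
so no partially-observed day can make a daily rule flicker.
"""

from __future__ import annotations

import csv
import time as time_mod
from dataclasses import dataclass
from datetime import timedelta
from pathlib import Path
from typing import Optional, Sequence

from wearkg.kg import build_graph
from wearkg.observations import (
    observations_from_sessions,
    observations_from_stream,
)
from wearkg.rules import Rulebase, default_rules, detect_problems
from wearkg.synthetic import (
    SyntheticDataset,
    SyntheticProfile,
    generate_benchmark_objects,
    generate_subject_days,
    inject_problem_episode,
)

DEFAULT_RULE_TRIO = ("LackOfMovement", "LowSleepQuality", "LackOfSleep")


@dataclass
class BenchmarkRecord:
    task: int
    n_objects_in_kb: int
    elapsed_ms: float
    n_objects_generated: Optional[int] = None
    rule_id: Optional[str] = None


def _check_sizes(sizes: Sequence[int]) -> None:
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")


def run_task1(sizes: Sequence[int], seed: int = 0) -> list[BenchmarkRecord]:
    """Ingestion scaling: time build_graph over n generated observations.

    Observation sets are nested (the same seed generates the same prefix),
    so sizes are directly comparable.
    """
    _check_sizes(sizes)
    records = []
    for n in sizes:
        observations = generate_benchmark_objects(n, seed)
        t0 = time_mod.perf_counter()
        build_graph(observations)
        elapsed = (time_mod.perf_counter() - t0) * 1000.0
        records.append(BenchmarkRecord(task=1, n_objects_in_kb=n, elapsed_ms=elapsed))
    return records


def _episode_dataset(n_days: int, seed: int,
                     rule_ids: Sequence[str]) -> SyntheticDataset:
    """Compliant dataset with the trio's episodes injected on a fixed
    schedule (every 3rd/4th/5th day), so rules have something to fire on."""
    data = generate_subject_days(SyntheticProfile(seed=seed), n_days)
    schedule = {"LackOfSleep": 3, "LowSleepQuality": 4, "LackOfMovement": 5,
                "Insomnia": 7, "Restlessness": 11, "TooMuchSleep": 13}
    for d in range(1, n_days - 1):
        for rule_id, period in schedule.items():
            if rule_id in rule_ids and d % period == 0:
                data = inject_problem_episode(
                    data, rule_id, data.profile.start_date + timedelta(days=d))
                break
    return data


def run_task2(
    sizes: Sequence[int],
    rule_ids: Sequence[str] = DEFAULT_RULE_TRIO,
    seed: int = 0,
) -> list[BenchmarkRecord]:
    """Rule scaling: problems generated and time per (KB size, rule).

    Each size selects the largest whole-day prefix whose observation count
    does not exceed it; ``n_objects_in_kb`` reports the actual count used.
    """
    _check_sizes(sizes)
    known = set(default_rules())
    for r in rule_ids:
        if r not in known:
            raise KeyError(f"unknown rule id {r!r}")
    # ~2885 observations per day (2 x 1440 samples + 5 per session)
    n_days = max(2, int(max(sizes) / 2800) + 2)
    data = _episode_dataset(n_days, seed, rule_ids)

    day_obs: list[int] = []  # cumulative observation count per day prefix
    cumulative = 0
    for day in data.dates:
        nxt = day + timedelta(days=1)
        part = data.slice(day, nxt)
        cumulative += (len(part.steps) + len(part.heart_rate)
                       + 5 * len(part.sessions))
        day_obs.append(cumulative)

    base = Rulebase()
    records = []
    for size in sizes:
        k = sum(1 for c in day_obs if c <= size)
        prefix = data.slice(data.profile.start_date,
                            data.profile.start_date + timedelta(days=k))
        n_in_kb = day_obs[k - 1] if k else 0
        for rule_id in rule_ids:
            rb = Rulebase(rules={rule_id: base.rules[rule_id]})
            t0 = time_mod.perf_counter()
            problems = detect_problems(prefix.steps, prefix.heart_rate,
                                       prefix.sessions, rb)
            elapsed = (time_mod.perf_counter() - t0) * 1000.0
            records.append(BenchmarkRecord(
                task=2, n_objects_in_kb=n_in_kb, elapsed_ms=elapsed,
                n_objects_generated=len(problems), rule_id=rule_id))
    return records


def write_benchmark_csv(records: Sequence[BenchmarkRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task", "rule_id", "n_objects_in_kb", "elapsed_ms",
                         "n_objects_generated"])
        for r in records:
            writer.writerow([r.task, r.rule_id or "", r.n_objects_in_kb,
                             f"{r.elapsed_ms:.1f}",
                             "" if r.n_objects_generated is None else r.n_objects_generated])
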