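"""Rule-base behaviour: day partitioning, strict thresholds, window
detection against a brute-force oracle, determinism, SHACL export."""

import operator
from datetime import date, datetime, time, timedelta

import numpy as np
import pytest
import rdflib

from wearkg.io import SampleStream
from wearkg.rules import (
    Rulebase,
    compute_daily_aggregates,
    default_rules,
    detect_problems,
    evaluate_daily_rules,
    export_shacl_rules,
    find_hr_step_windows,
    find_low_hr_runs,
    partition_by_day,
    run_rulebase,
)

from conftest import D0, make_nap, make_session, make_stream

MIDNIGHT = datetime.combine(D0, time.min)


def day_inputs(asleep=400, fall=10, awakenings=2, efficiency=None,
               steps_total=9000, naps=(), extra_sessions=()):
    """One boundary-compliant day, with selected quantities overridden."""
    half = steps_total // 2
    steps = SampleStream(subject_id="tms6", kind="steps", samples=[
        (MIDNIGHT + timedelta(hours=10), float(half)),
        (MIDNIGHT + timedelta(hours=15), float(steps_total - half))])
    hr = SampleStream(subject_id="tms6", kind="heart_rate", samples=[])
    sessions = [make_session(day=D0, asleep=asleep, fall=fall,
                             awakenings=awakenings, efficiency=efficiency,
                             is_main=True)]
    sessions += list(naps) + list(extra_sessions)
    return steps, hr, sessions


def detected_types(steps, hr, sessions, rulebase=None):
    return {p.problem_type for p in detect_problems(steps, hr, sessions, rulebase)}


class TestPartition:
    def test_sample_assigned_to_its_date(self):
        stream = make_stream("steps", [5], start=datetime(2021, 3, 1, 23, 59))
        contexts = partition_by_day([stream], [])
        assert list(contexts) == [date(2021, 3, 1)]

    def test_session_assigned_to_end_date(self):
        session = make_session(day=date(2021, 3, 2))  # 23:00 Mar 1 -> morning Mar 2
        contexts = partition_by_day([], [session])
        assert list(contexts) == [date(2021, 3, 2)]

    def test_step_totals_conserved_across_days(self):
        rng = np.random.default_rng(5)
        values = rng.integers(0, 30, size=3000)
        stream = make_stream("steps", values, start=datetime(2021, 3, 1, 22, 0))
        contexts = partition_by_day([stream], [])
        per_day = sum(sum(v for _, v in c.steps) for c in contexts.values())
        assert per_day == stream.total()


class TestDailyAggregates:
    def test_fall_asleep_converted_to_seconds(self):
        contexts = partition_by_day([], [make_session(fall=31)])
        (agg,) = [compute_daily_aggregates(c) for c in contexts.values()]
        assert agg.totals["fall_asleep_seconds"] == 1860

    def test_interruptions_summed_over_sessions(self):
        sessions = [make_session(awakenings=6), make_nap(asleep=30)]
        sessions[1].awakenings_count = 5
        contexts = partition_by_day([], sessions)
        (agg,) = [compute_daily_aggregates(c) for c in contexts.values()]
        assert agg.totals["interruptions"] == 11

    def test_longest_session_is_main_sleep(self):
        # no flags: the 420-min session is main, the 45-min one a nap
        long = make_session(asleep=420)
        long.is_main_sleep = None
        short = make_nap(asleep=45)
        short.is_main_sleep = None
        contexts = partition_by_day([], [long, short])
        (agg,) = [compute_daily_aggregates(c) for c in contexts.values()]
        assert agg.totals["nap_minutes"] == 45
        assert agg.totals["nap_count"] == 1

    def test_day_without_sessions_flagged(self):
        stream = make_stream("steps", [5])
        contexts = partition_by_day([stream], [])
        (agg,) = [compute_daily_aggregates(c) for c in contexts.values()]
        assert not agg.has_sleep_data


class TestDailyRuleBoundaries:
    """Strict comparisons: at the printed limit nothing fires; one unit
    past it the rule fires."""

    def test_all_limits_exactly_at_threshold_fire_nothing(self):
        # fall asleep 1800 s, interruptions 10, sleep 480, efficiency 85, steps 8000
        steps, hr, sessions = day_inputs(asleep=480, fall=30, awakenings=10,
                                         efficiency=85, steps_total=8000)
        assert detected_types(steps, hr, sessions) == set()

    @pytest.mark.parametrize("kwargs,expected", [
        (dict(fall=31), {"Insomnia"}),
        (dict(awakenings=11), {"Restlessness"}),
        (dict(asleep=481), {"TooMuchSleep"}),
        (dict(asleep=299), {"LackOfSleep"}),
        (dict(asleep=300), set()),
        (dict(efficiency=84), {"LowSleepQuality"}),
        (dict(steps_total=7999), {"LackOfExercise"}),
    ])
    def test_one_past_threshold_fires(self, kwargs, expected):
        steps, hr, sessions = day_inputs(**kwargs)
        assert detected_types(steps, hr, sessions) == expected

    @pytest.mark.parametrize("nap_minutes,expected", [
        (100, set()), (101, {"IncreasedNapping"}),
    ])
    def test_nap_minutes_threshold(self, nap_minutes, expected):
        naps = [make_nap(start_hour=10, asleep=60),
                make_nap(start_hour=13, asleep=nap_minutes - 60)]
        steps, hr, sessions = day_inputs(asleep=370, naps=naps)
        assert detected_types(steps, hr, sessions) == expected

    @pytest.mark.parametrize("gap,fires", [(120, False), (119, True), (60, True)])
    def test_nap_close_to_bedtime_gap(self, gap, fires):
        bed = MIDNIGHT + timedelta(hours=23)  # next main sleep starts Mar 1 23:00
        nap_end = bed - timedelta(minutes=gap)
        nap = make_nap(start_hour=(nap_end - MIDNIGHT).total_seconds() / 3600 - 0.5,
                       asleep=28)
        next_main = make_session(day=D0 + timedelta(days=1), is_main=True)
        steps, hr, sessions = day_inputs(naps=[nap], extra_sessions=[next_main])
        types = {p.problem_type for p in detect_problems(steps, hr, sessions)
                 if p.temporal_extent[0].date() == D0}
        assert ("NapCloseToBedtime" in types) is fires

    def test_sleep_rules_skipped_without_sleep_data(self):
        steps = SampleStream(subject_id="a", kind="steps",
                             samples=[(MIDNIGHT + timedelta(hours=10), 9000.0)])
        hr = SampleStream(subject_id="a", kind="heart_rate", samples=[])
        assert detected_types(steps, hr, []) == set()

    def test_step_rule_skipped_without_step_samples(self):
        steps = SampleStream(subject_id="tms6", kind="steps", samples=[])
        hr = SampleStream(subject_id="tms6", kind="heart_rate", samples=[])
        # zero step samples: no LackOfExercise even though total is 0
        assert detected_types(steps, hr, [make_session()]) == set()


class TestWindowRules:
    def _streams(self, hr_vals, step_vals=None, start=MIDNIGHT + timedelta(hours=8)):
        hr = make_stream("heart_rate", hr_vals, start=start)
        steps = make_stream("steps", step_vals or [], start=start)
        return steps, hr

    def test_801_minute_low_run_qualifies(self):
        rule = default_rules()["LackOfMovement"]
        steps, hr = self._streams([90] * 801)
        (window,) = find_hr_step_windows(steps, hr, rule)
        assert window.length == 801
        assert window.total_steps == 0

    def test_800_minute_run_does_not_qualify(self):
        rule = default_rules()["LackOfMovement"]
        steps, hr = self._streams([90] * 800)
        assert find_hr_step_windows(steps, hr, rule) == []

    def test_breaking_minute_splits_runs(self):
        rule = default_rules()["Inactivity"]
        steps, hr = self._streams([70] * 400 + [120] + [70] * 400)
        # two maximal runs of 400, neither exceeds the 300+1... both do qualify
        windows = find_hr_step_windows(steps, hr, rule)
        assert [w.length for w in windows] == [400, 400]

    def test_missing_minute_breaks_run(self):
        rule = default_rules()["Inactivity"]
        steps, hr = self._streams([70] * 200 + [None] + [70] * 200)
        assert find_hr_step_windows(steps, hr, rule) == []

    def test_cumulative_steps_disqualify(self):
        rule = default_rules()["Inactivity"]
        steps, hr = self._streams([70] * 301, step_vals=[4] * 301)  # 1204 steps
        assert find_hr_step_windows(steps, hr, rule) == []
        steps, hr = self._streams([70] * 301, step_vals=[3] * 301)  # 903 steps
        assert len(find_hr_step_windows(steps, hr, rule)) == 1

    def test_low_hr_runs(self):
        _, hr = self._streams([59, 59, 61, 58])
        assert [w.length for w in find_low_hr_runs(hr)] == [2, 1]

    def test_equality_minute_never_included(self):
        _, hr = self._streams([60, 60, 60])
        assert find_low_hr_runs(hr) == []

    def test_matches_brute_force_oracle_on_random_streams(self):
        rule = default_rules()["Inactivity"]
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(50, 2000))
            hr_vals = [None if rng.random() < 0.03 else int(rng.integers(80 - 4, 80 + 4))
                       for _ in range(n)]
            step_vals = [int(rng.integers(0, 8)) for _ in range(n)]
            steps, hr = self._streams(hr_vals, step_vals)
            got = [(w.start, w.end, w.total_steps)
                   for w in find_hr_step_windows(steps, hr, rule)]
            assert got == oracle_windows(hr_vals, step_vals,
                                         MIDNIGHT + timedelta(hours=8))


def oracle_windows(hr_vals, step_vals, base, hr_thr=80.0, step_thr=1000.0,
                   min_dur=300.0):
    """Brute force: label every minute, scan maximal satisfying runs."""
    n = len(hr_vals)
    sat = [hr_vals[i] is not None and hr_vals[i] < hr_thr for i in range(n)]
    out = []
    i = 0
    while i < n:
        if not sat[i]:
            i += 1
            continue
        j = i
        while j < n and sat[j]:
            j += 1
        total = float(sum(step_vals[i:j]))
        if (j - i) > min_dur and total < step_thr:
            out.append((base + timedelta(minutes=i), base + timedelta(minutes=j), total))
        i = j
    return out


class TestPipeline:
    def test_compliant_day_detects_nothing(self, compliant_data):
        steps, hr, sessions = compliant_data
        assert detect_problems(steps, hr, sessions) == []

    def test_rerun_gives_byte_identical_graph(self, compliant_data):
        steps, hr, sessions = day_inputs(asleep=250)
        out1 = run_rulebase(steps, hr, sessions)
        out2 = run_rulebase(steps, hr, sessions)
        assert out1[0] == out2[0]
        assert out1[1].canonical_nt() == out2[1].canonical_nt()
        assert out1[1].serialize("turtle") == out2[1].serialize("turtle")

    def test_emitted_problems_sorted_by_start_then_type(self):
        steps, hr, sessions = day_inputs(asleep=250, steps_total=100)
        problems = detect_problems(steps, hr, sessions)
        keys = [(p.temporal_extent[0], p.problem_type) for p in problems]
        assert keys == sorted(keys)
        assert [p.problem_type for p in problems] == ["LackOfExercise", "LackOfSleep"]

    def test_window_rules_ignore_sleep_minutes_by_default(self):
        # 480 sleeping minutes of HR 64 would otherwise be an Inactivity run
        session = make_session(asleep=464, fall=10, awakenings=2)
        hr = make_stream("heart_rate", [64] * 480, start=session.start)
        steps = SampleStream(subject_id="tms6", kind="steps", samples=[
            (MIDNIGHT + timedelta(hours=10), 9000.0)])
        assert detected_types(steps, hr, [session]) == set()
        rb = Rulebase(include_sleep_minutes=True)
        assert "Inactivity" in detected_types(steps, hr, [session], rb)

    def test_monotone_in_steps(self):
        low = day_inputs(steps_total=5000)
        high = day_inputs(steps_total=9000)
        assert "LackOfExercise" in detected_types(*low)
        assert "LackOfExercise" not in detected_types(*high)

    def test_monotone_in_sleep_deficit(self):
        for asleep in (250, 200, 120):
            steps, hr, sessions = day_inputs(asleep=asleep)
            assert "LackOfSleep" in detected_types(steps, hr, sessions)

    def test_at_most_one_problem_per_daily_rule_and_day(self):
        naps = [make_nap(start_hour=9, asleep=80), make_nap(start_hour=13, asleep=80)]
        steps, hr, sessions = day_inputs(asleep=250, efficiency=60, naps=naps)
        problems = detect_problems(steps, hr, sessions)
        keys = [(p.problem_type, p.temporal_extent[0]) for p in problems]
        assert len(keys) == len(set(keys))


class TestRulebaseConfig:
    def test_per_subject_override(self):
        rb = Rulebase(overrides={"tms6": {"LackOfExercise": {"steps": 5000}}})
        steps, hr, sessions = day_inputs(steps_total=6000)
        assert "LackOfExercise" not in detected_types(steps, hr, sessions, rb)
        assert "LackOfExercise" in detected_types(steps, hr, sessions)

    def test_load_from_yaml(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text(
            "rules:\n  LackOfSleep:\n    sleep_minutes: 360\n"
            "overrides:\n  tms7:\n    Insomnia:\n      fall_asleep_seconds: 900\n")
        rb = Rulebase.from_file(cfg)
        assert rb.rules["LackOfSleep"].condition("sleep_minutes").threshold == 360
        assert rb.resolve("tms7")["Insomnia"].condition("fall_asleep_seconds").threshold == 900
        assert rb.resolve("tms6")["Insomnia"].condition("fall_asleep_seconds").threshold == 1800

    def test_unknown_rule_id_rejected(self):
        steps, hr, sessions = day_inputs()
        contexts = partition_by_day([steps, hr], sessions)
        (agg,) = [compute_daily_aggregates(c) for c in contexts.values()]
        with pytest.raises(KeyError):
            evaluate_daily_rules(agg, {"NotARule": default_rules()["LackOfSleep"]})

    def test_nap_count_variant_has_no_default(self):
        rb = Rulebase()
        assert rb.nap_count_threshold is None
        rb = Rulebase(nap_count_threshold=3)
        naps = [make_nap(start_hour=h, asleep=20) for h in (9, 11, 13, 15)]
        steps, hr, sessions = day_inputs(naps=naps)
        assert "IncreasedNapping" in detected_types(steps, hr, sessions, rb)
        assert "IncreasedNapping" not in detected_types(steps, hr, sessions)


class TestShaclExport:
    def test_document_parses_as_turtle(self):
        g = rdflib.Graph()
        g.parse(data=export_shacl_rules(), format="turtle")
        assert len(g) > 0

    def test_inactivity_construct_target_present(self):
        doc = export_shacl_rules()
        assert "em:Inactivity" in doc
        assert "sh:construct" in doc

    def test_one_rule_per_spec(self):
        g = rdflib.Graph()
        g.parse(data=export_shacl_rules(), format="turtle")
        sh = rdflib.Namespace("http://www.w3.org/ns/shacl#")
        rules = list(g.subjects(rdflib.RDF.type, sh.SPARQLRule))
        assert len(rules) == 12

    def test_window_rules_carry_explanatory_comment(self):
        g = rdflib.Graph()
        g.parse(data=export_shacl_rules(), format="turtle")
        em = rdflib.Namespace("https://w3id.org/wearkg/em#")
        comments = list(g.objects(em.InactivityRule, rdflib.RDFS.comment))
        assert comments and "window" in str(comments[0]).lower()

    def test_empty_rulebase_yields_prefix_only_document(self):
        doc = export_shacl_rules(Rulebase(rules={}))
        g = rdflib.Graph()
        g.parse(data=doc, format="turtle")
        assert len(g) == 0
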