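"""Observation construction, axiom classification and graph building."""

import itertools
from datetime import datetime, timedelta

import pytest
from rdflib import RDF

from wearkg.io import SampleStream
from wearkg.kg import (
    EM,
    MS,
    SOSA,
    TRIPLES_PER_OBSERVATION_BESIDES_TYPES,
    KnowledgeGraph,
    build_graph,
    serialize_graph,
)
from wearkg.observations import (
    FEATURES,
    VOCABULARY,
    Observation,
    classify_observation,
    observation_id,
    observations_from_sessions,
    observations_from_stream,
    to_observations,
)

from conftest import make_session, make_stream


def _obs(feature, prop):
    t = datetime(2021, 3, 1, 9)
    return Observation(
        id=observation_id("x", prop, t), subject_id="x",
        feature_of_interest=feature, observed_property=prop,
        result=1.0, unit="u", phenomenon_time=(t, t + timedelta(minutes=1)))


# Independent oracle: each equivalence axiom written out verbatim as a
# predicate over (feature, property), including the inherited conditions.
def oracle_classes(feature, prop):
    movement = {"steps", "distance", "elevation", "floors",
                "fair_activity", "high_activity", "light_activity", "sedentary"}
    sleep = {"asleep_count", "asleep_duration", "awake_count", "awake_duration",
             "minutes_to_fall_asleep", "efficiency"}
    heart = {"heart_rate", "cardio", "fat_burn", "peak"}
    out = {"Observation"}
    if feature == "movement" and prop in movement:
        out.add("MovementObservation")
        if prop in {"fair_activity", "high_activity", "light_activity", "sedentary"}:
            out.add("MovementIntensity")
        if prop in {"distance", "elevation", "floors", "steps"}:
            out.add("WalkingFeature")
    if feature == "sleep" and prop in sleep:
        out.add("SleepObservation")
        for leaf, p in [("AsleepCount", "asleep_count"),
                        ("AsleepDuration", "asleep_duration"),
                        ("AwakeCount", "awake_count"),
                        ("AwakeDuration", "awake_duration")]:
            if prop == p:
                out.add(leaf)
    if feature == "heart" and prop in heart:
        out.add("HeartObservation")
        for leaf, p in [("Cardio", "cardio"), ("FatBurn", "fat_burn"),
                        ("HeartRate", "heart_rate"), ("Peak", "peak")]:
            if prop == p:
                out.add(leaf)
    return frozenset(out)


class TestClassification:
    def test_steps_observation_is_walking_feature(self):
        assert classify_observation(_obs("movement", "steps")) == {
            "Observation", "MovementObservation", "WalkingFeature"}

    def test_heart_rate_observation(self):
        assert classify_observation(_obs("heart", "heart_rate")) == {
            "Observation", "HeartObservation", "HeartRate"}

    def test_unmatched_leaf_property_stays_at_branch(self):
        # efficiency matches no leaf axiom: branch class only
        assert classify_observation(_obs("sleep", "efficiency")) == {
            "Observation", "SleepObservation"}

    def test_mismatched_feature_classifies_as_observation_only(self):
        assert classify_observation(_obs("sleep", "steps")) == {"Observation"}

    @pytest.mark.parametrize("feature,prop",
                             list(itertools.product(FEATURES, sorted(VOCABULARY))))
    def test_matches_exhaustive_oracle(self, feature, prop):
        assert classify_observation(_obs(feature, prop)) == oracle_classes(feature, prop)

    @pytest.mark.parametrize("feature,prop",
                             list(itertools.product(FEATURES, sorted(VOCABULARY))))
    def test_closed_under_parents(self, feature, prop):
        classes = classify_observation(_obs(feature, prop))
        parent_of = {"MovementIntensity": "MovementObservation",
                     "WalkingFeature": "MovementObservation",
                     "AsleepCount": "SleepObservation",
                     "AsleepDuration": "SleepObservation",
                     "AwakeCount": "SleepObservation",
                     "AwakeDuration": "SleepObservation",
                     "Cardio": "HeartObservation", "FatBurn": "HeartObservation",
                     "HeartRate": "HeartObservation", "Peak": "HeartObservation"}
        for cls in classes:
            if cls in parent_of:
                assert parent_of[cls] in classes
        assert "Observation" in classes

    def test_idempotent(self):
        obs = _obs("movement", "steps")
        first = classify_observation(obs)
        assert classify_observation(obs) == first


class TestToObservations:
    def test_steps_sample_maps_directly(self):
        stream = make_stream("steps", [300], start=datetime(2021, 3, 1, 9))
        (obs,) = to_observations(stream)
        assert obs.feature_of_interest == "movement"
        assert obs.observed_property == "steps"
        assert obs.result == 300
        assert obs.phenomenon_time == (datetime(2021, 3, 1, 9),
                                       datetime(2021, 3, 1, 9, 1))

    def test_sleep_session_yields_derived_properties(self):
        session = make_session(awakenings=3)
        obs = to_observations([session])
        by_prop = {o.observed_property: o for o in obs}
        assert set(by_prop) == {"asleep_duration", "awake_count", "awake_duration",
                                "minutes_to_fall_asleep", "efficiency"}
        assert by_prop["awake_count"].result == 3

    def test_ids_deterministic(self):
        stream = make_stream("steps", [1, 2, 3])
        assert [o.id for o in to_observations(stream)] == \
               [o.id for o in to_observations(stream)]

    def test_unknown_input_rejected(self):
        with pytest.raises(TypeError):
            to_observations(42)


class TestGraph:
    def test_observed_property_triple_present(self):
        stream = make_stream("steps", [300], start=datetime(2021, 3, 1, 9))
        (obs,) = observations_from_stream(stream)
        kg = build_graph([obs])
        assert (MS[obs.id], SOSA.observedProperty, MS["property/steps"]) in kg

    def test_empty_graph(self):
        assert len(build_graph([])) == 0

    def test_triple_count_matches_counting_oracle(self):
        obs = (observations_from_stream(make_stream("steps", [1, 2]))
               + observations_from_stream(make_stream("heart_rate", [70]))
               + observations_from_sessions([make_session()]))
        expected = sum(len(o.inferred_classes) + TRIPLES_PER_OBSERVATION_BESIDES_TYPES
                       for o in obs)
        assert len(build_graph(obs)) == expected

    def test_add_is_idempotent(self):
        (obs,) = observations_from_stream(make_stream("steps", [5]))
        kg = build_graph([obs])
        n = len(kg)
        kg.add_observation(obs)
        assert len(kg) == n

    @pytest.mark.parametrize("fmt", ["turtle", "json-ld"])
    def test_serialization_round_trip(self, fmt):
        obs = observations_from_stream(make_stream("steps", [1, 2, 3]))
        kg = build_graph(obs)
        back = KnowledgeGraph.parse(serialize_graph(kg, fmt), fmt)
        assert set(back.graph) == set(kg.graph)

    def test_empty_graph_serializes_parseably(self):
        kg = KnowledgeGraph()
        assert len(KnowledgeGraph.parse(kg.serialize("turtle"), "turtle")) == 0

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            KnowledgeGraph().serialize("rdfxml")
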