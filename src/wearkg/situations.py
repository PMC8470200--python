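"""Problem situations under the Descriptions-and-Situations (DnS) pattern.

A detected problem is a *situation*: it groups the observations it
interprets and carries a *view* (a description) that defines concepts
classifying the entities involved, making the interpretive context of the
detection explicit in the graph. The modelled axioms are:

    Problem   is-a Situation, has >= 1 view, interprets >= 1 Observation
    View      is-a Description, defines >= 1 Concept that classifies an
              entity of the situation
    hasView   subproperty-of satisfies
    interprets subproperty-of isSettingFor
    Observation is-a Event

Problems also map onto the Web Annotation Data Model: a problem is an
annotation whose bodies are its views and whose targets are the
interpreted observations (0+ bodies, 1+ targets).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, model_validator
from rdflib import RDF, XSD, Literal, URIRef

from wearkg.kg import DUL, EM, MS, OA, SOSA, TIME, KnowledgeGraph
from wearkg.observations import Observation

PROBLEM_TYPES = (
    "Insomnia", "Restlessness", "TooMuchSleep", "LackOfSleep",
    "IncreasedNapping", "NapCloseToBedtime", "LowSleepQuality",
    "StressOrPain", "LowHeartRate",
    "Inactivity", "LackOfMovement", "LackOfExercise",
)

#: Problem type -> category, following the three branches of the core
#: vocabulary (sleep-, heart- and activity-related problems). Overridable
#: via the ``category_map`` argument of :func:`instantiate_problem`.
DEFAULT_CATEGORIES = {
    "Insomnia": "SleepProblem",
    "Restlessness": "SleepProblem",
    "TooMuchSleep": "SleepProblem",
    "LackOfSleep": "SleepProblem",
    "IncreasedNapping": "SleepProblem",
    "NapCloseToBedtime": "SleepProblem",
    "LowSleepQuality": "SleepProblem",
    "StressOrPain": "HeartProblem",
    "LowHeartRate": "HeartProblem",
    "Inactivity": "ActivityProblem",
    "LackOfMovement": "ActivityProblem",
    "LackOfExercise": "ActivityProblem",
}


class View(BaseModel):
    """A description: concepts classifying the entities of a situation."""

    id: str
    defined_concepts: list[tuple[str, str]]  # (concept name, classified entity id)

    @model_validator(mode="after")
    def _non_empty(self) -> "View":
        if not self.defined_concepts:
            raise ValueError("a view must define at least one concept")
        return self


class ProblemSituation(BaseModel):
    """A detected health-related event instantiating the DnS pattern."""

    id: str
    problem_type: str
    category: str
    subject_id: str
    view: View
    interpreted_observation_ids: list[str]
    temporal_extent: tuple[datetime, datetime]

    @model_validator(mode="after")
    def _check(self) -> "ProblemSituation":
        if self.problem_type not in PROBLEM_TYPES:
            raise ValueError(f"unknown problem type: {self.problem_type!r}")
        if not self.interpreted_observation_ids:
            raise ValueError("a problem must interpret at least one observation")
        interpreted_props = {
            pid.split("/")[2] for pid in self.interpreted_observation_ids
            if pid.startswith("obs/") and len(pid.split("/")) >= 4
        }
        for _concept, entity in self.view.defined_concepts:
            if entity.startswith("property/") and interpreted_props:
                if entity.split("/", 1)[1] not in interpreted_props:
                    raise ValueError(
                        f"concept classifies {entity!r}, which no interpreted "
                        "observation references"
                    )
        return self


class WadmAnnotation(BaseModel):
    """A Web-Annotation record: 0+ bodies, 1+ targets."""

    id: str
    bodies: list[str] = Field(default_factory=list)
    targets: list[str]

    @model_validator(mode="after")
    def _check(self) -> "WadmAnnotation":
        if not self.targets:
            raise ValueError("an annotation requires at least one target")
        return self


def problem_id(subject_id: str, problem_type: str, extent_start: datetime) -> str:
    """Deterministic problem identifier from (subject, type, extent start)."""
    digest = hashlib.sha1(
        f"{subject_id}|{problem_type}|{extent_start.isoformat()}".encode()
    ).hexdigest()[:10]
    return f"problem/{subject_id}/{problem_type}/{digest}"


def instantiate_problem(
    problem_type: str,
    observations: Sequence[Observation],
    temporal_extent: tuple[datetime, datetime],
    category_map: dict[str, str] | None = None,
) -> ProblemSituation:
    """Build a problem situation over the given observations.

    The view defines one concept per distinct feature of interest among the
    observations (e.g. "movement"), each classifying the corresponding
    observed-property entity (e.g. "steps"); a composite detection touching
    two features yields one view defining two concepts.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("a problem must interpret at least one observation")
    subjects = {o.subject_id for o in observations}
    if len(subjects) != 1:
        raise ValueError(f"observations span multiple subjects: {sorted(subjects)}")
    subject_id = subjects.pop()
    categories = dict(DEFAULT_CATEGORIES)
    if category_map:
        categories.update(category_map)
    if problem_type not in categories:
        raise ValueError(f"no category for problem type {problem_type!r}")

    pid = problem_id(subject_id, problem_type, temporal_extent[0])
    pairs = sorted({(o.feature_of_interest, o.observed_property) for o in observations})
    concepts = [(feature, f"property/{prop}") for feature, prop in pairs]
    view = View(id=f"{pid}/view", defined_concepts=concepts)
    return ProblemSituation(
        id=pid,
        problem_type=problem_type,
        category=categories[problem_type],
        subject_id=subject_id,
        view=view,
        interpreted_observation_ids=[o.id for o in observations],
        temporal_extent=temporal_extent,
    )


def problem_to_graph(problem: ProblemSituation, kg: KnowledgeGraph) -> URIRef:
    """Materialise a problem into the graph in full DnS shape.

    Subproperty entailments are materialised alongside the asserted
    triples: every hasView gets a satisfies, every interprets gets an
    isSettingFor.
    """
    p = MS[problem.id]
    v = MS[problem.view.id]
    kg.add((p, RDF.type, EM.Problem))
    kg.add((p, RDF.type, EM[problem.problem_type]))
    kg.add((p, RDF.type, EM[problem.category]))
    kg.add((p, RDF.type, DUL.Situation))
    kg.add((p, EM.hasView, v))
    kg.add((p, DUL.satisfies, v))
    kg.add((v, RDF.type, EM.View))
    kg.add((v, RDF.type, DUL.Description))
    for concept_name, entity in problem.view.defined_concepts:
        c = MS[f"{problem.view.id}/concept/{concept_name}"]
        kg.add((v, DUL.defines, c))
        kg.add((c, RDF.type, DUL.Concept))
        kg.add((c, DUL.classifies, MS[entity]))
    for oid in problem.interpreted_observation_ids:
        o = MS[oid]
        kg.add((p, EM.interprets, o))
        kg.add((p, DUL.isSettingFor, o))
    interval = MS[f"{problem.id}/time"]
    start, end = problem.temporal_extent
    kg.add((p, EM.temporalExtent, interval))
    kg.add((interval, RDF.type, TIME.Interval))
    kg.add((interval, TIME.hasBeginning, Literal(start.isoformat(), datatype=XSD.dateTime)))
    kg.add((interval, TIME.hasEnd, Literal(end.isoformat(), datatype=XSD.dateTime)))
    return p


@dataclass
class Violation:
    problem: str
    code: str
    message: str


@dataclass
class ValidationReport:
    n_problems: int = 0
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_descriptive_context(kg: KnowledgeGraph) -> ValidationReport:
    """Structurally validate every problem in the graph against the pattern.

    Checks, per problem: at least one view; at least one interpreted
    entity typed as an observation; the view defines at least one concept;
    each concept classifies an entity; and the subproperty expansion is
    materialised (hasView accompanied by satisfies, interprets by
    isSettingFor). Failures become report entries, never exceptions.
    """
    report = ValidationReport()
    g = kg.graph
    for p in sorted(set(g.subjects(RDF.type, EM.Problem))):
        report.n_problems += 1
        pname = str(p)
        views = list(g.objects(p, EM.hasView))
        if not views:
            report.violations.append(Violation(
                pname, "missing-view",
                "problem axiom requires at least one hasView (Problem ⊑ ∃hasView.View)"))
        interpreted = list(g.objects(p, EM.interprets))
        if not interpreted:
            report.violations.append(Violation(
                pname, "missing-interprets",
                "problem axiom requires at least one interpreted observation "
                "(Problem ⊑ ∃interprets.Observation)"))
        else:
            typed = [o for o in interpreted if (o, RDF.type, SOSA.Observation) in g]
            if not typed:
                report.violations.append(Violation(
                    pname, "interprets-not-observation",
                    "no interpreted entity is typed sosa:Observation"))
        for v in views:
            if (p, DUL.satisfies, v) not in g:
                report.violations.append(Violation(
                    pname, "missing-satisfies",
                    "hasView lacks its entailed dul:satisfies (hasView ⊑ satisfies)"))
            concepts = list(g.objects(v, DUL.defines))
            if not concepts:
                report.violations.append(Violation(
                    pname, "view-defines-nothing",
                    "view axiom requires at least one defined concept "
                    "(View ⊑ ∃defines.Concept)"))
            for c in concepts:
                if not list(g.objects(c, DUL.classifies)):
                    report.violations.append(Violation(
                        pname, "concept-classifies-nothing",
                        "defined concept classifies no entity"))
        for o in interpreted:
            if (p, DUL.isSettingFor, o) not in g:
                report.violations.append(Violation(
                    pname, "missing-is-setting-for",
                    "interprets lacks its entailed dul:isSettingFor "
                    "(interprets ⊑ isSettingFor)"))
    return report


# -- WADM ------------------------------------------------------------------

def export_wadm(problem: ProblemSituation) -> WadmAnnotation:
    """Map a problem to a Web Annotation: views become bodies, interpreted
    observations become targets."""
    if not problem.interpreted_observation_ids:
        raise ValueError("cannot annotate a problem with no interpreted observations")
    return WadmAnnotation(
        id=problem.id,
        bodies=[problem.view.id],
        targets=list(problem.interpreted_observation_ids),
    )


def wadm_to_jsonld(annotation: WadmAnnotation) -> dict:
    return {
        "@context": "http://www.w3.org/ns/anno.jsonld",
        "id": str(MS[annotation.id]),
        "type": "Annotation",
        "body": [str(MS[b]) for b in annotation.bodies],
        "target": [str(MS[t]) for t in annotation.targets],
    }


def import_wadm(doc: dict | WadmAnnotation) -> WadmAnnotation:
    """Read a WADM JSON-LD record back into an annotation."""
    if isinstance(doc, WadmAnnotation):
        return doc
    ms = str(MS)

    def local(iri: str) -> str:
        return iri[len(ms):] if iri.startswith(ms) else iri

    body = doc.get("body", [])
    target = doc.get("target", [])
    if isinstance(body, str):
        body = [body]
    if isinstance(target, str):
        target = [target]
    return WadmAnnotation(
        id=local(doc["id"]),
        bodies=[local(b) for b in body],
        targets=[local(t) for t in target],
    )


def annotations_to_jsonld(problems: Iterable[ProblemSituation]) -> list[dict]:
    return [wadm_to_jsonld(export_wadm(p)) for p in problems]
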