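"""RDF knowledge-graph container for observations and detected situations.

A thin wrapper over :class:`rdflib.Graph` fixing the namespace table used
throughout the package:

==========  =========================================================
prefix      vocabulary
==========  =========================================================
``sosa``    sensor/observation core (Observation, observedProperty, ...)
``dul``     upper ontology (Situation, Description, satisfies, ...)
``oa``      Web Annotation vocabulary (Annotation, hasBody, hasTarget)
``em``      domain extension vocabulary (observation/problem classes,
            hasView, interprets)
``ms``      data namespace for generated instances
``time``    OWL-Time (interval begin/end)
==========  =========================================================

Graphs are sets of triples (adding an existing triple is a no-op), and
every generated node has a deterministic IRI — no blank nodes — so that
identical inputs serialize identically.
"""

from __future__ import annotations

from typing import Iterable

from rdflib import RDF, XSD, Graph, Literal, Namespace, URIRef

from wearkg.observations import Observation

SOSA = Namespace("http://www.w3.org/ns/sosa/")
DUL = Namespace("http://www.ontologydesignpatterns.org/ont/dul/DUL.owl#")
OA = Namespace("http://www.w3.org/ns/oa#")
EM = Namespace("https://w3id.org/wearkg/em#")
MS = Namespace("https://w3id.org/wearkg/ms/")
TIME = Namespace("http://www.w3.org/2006/time#")

NAMESPACES = {"sosa": SOSA, "dul": DUL, "oa": OA, "em": EM, "ms": MS, "time": TIME}

#: Triples emitted per observation in addition to one rdf:type per class.
TRIPLES_PER_OBSERVATION_BESIDES_TYPES = 7

_SERIALIZE_FORMATS = {"turtle": "turtle", "json-ld": "json-ld"}


class KnowledgeGraph:
    """A triple store holding observations, situations and annotations."""

    def __init__(self) -> None:
        self.graph = Graph()
        for prefix, ns in NAMESPACES.items():
            self.graph.bind(prefix, ns)

    def add(self, triple: tuple) -> None:
        self.graph.add(triple)

    def __len__(self) -> int:
        return len(self.graph)

    def __contains__(self, triple: tuple) -> bool:
        return triple in self.graph

    def triples(self, pattern=(None, None, None)):
        return self.graph.triples(pattern)

    def add_observation(self, obs: Observation) -> URIRef:
        """Add the full SOSA shape for one classified observation.

        Emits one ``rdf:type`` per inferred class ("Observation" maps to
        ``sosa:Observation``, the others to ``em:`` classes), the observed
        property and feature-of-interest links, the simple result, and a
        named phenomenon-time interval with begin/end instants.
        """
        node = MS[obs.id]
        for cls in sorted(obs.inferred_classes):
            target = SOSA.Observation if cls == "Observation" else EM[cls]
            self.add((node, RDF.type, target))
        self.add((node, SOSA.observedProperty, MS[f"property/{obs.observed_property}"]))
        self.add((node, SOSA.hasFeatureOfInterest, MS[f"feature/{obs.feature_of_interest}"]))
        self.add((node, SOSA.hasSimpleResult, Literal(obs.result, datatype=XSD.double)))
        interval = MS[f"{obs.id}/time"]
        start, end = obs.phenomenon_time
        self.add((node, SOSA.phenomenonTime, interval))
        self.add((interval, RDF.type, TIME.Interval))
        self.add((interval, TIME.hasBeginning, Literal(start.isoformat(), datatype=XSD.dateTime)))
        self.add((interval, TIME.hasEnd, Literal(end.isoformat(), datatype=XSD.dateTime)))
        return node

    def serialize(self, format: str = "turtle") -> bytes:
        """Serialize as Turtle or JSON-LD; losslessly re-parseable.

        Turtle output is a canonical flat form — prefix declarations
        followed by one sorted triple per line — which is byte-stable for
        a given triple set and orders of magnitude faster to emit than a
        pretty-printer on minute-resolution graphs.
        """
        if format not in _SERIALIZE_FORMATS:
            raise ValueError(f"unknown serialization format: {format!r}")
        if format == "json-ld":
            return self.graph.serialize(format="json-ld", encoding="utf-8")
        nsm = self.graph.namespace_manager
        header = "".join(f"@prefix {prefix}: <{ns}> .\n"
                         for prefix, ns in sorted(self.graph.namespaces()))
        lines = sorted(f"{s.n3(nsm)} {p.n3(nsm)} {o.n3(nsm)} ."
                       for s, p, o in self.graph)
        return (header + "\n" + "\n".join(lines) + ("\n" if lines else "")).encode("utf-8")

    def canonical_nt(self) -> bytes:
        """Sorted N-Triples: a byte-stable canonical form for comparisons."""
        lines = sorted(
            f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in self.graph
        )
        return ("\n".join(lines) + ("\n" if lines else "")).encode("utf-8")

    @classmethod
    def parse(cls, data: bytes | str, format: str = "turtle") -> "KnowledgeGraph":
        kg = cls()
        kg.graph.parse(data=data, format=format)
        return kg


def build_graph(observations: Iterable[Observation]) -> KnowledgeGraph:
    """Materialise classified observations into a fresh knowledge graph."""
    kg = KnowledgeGraph()
    for obs in observations:
        kg.add_observation(obs)
    return kg


def serialize_graph(kg: KnowledgeGraph, format: str = "turtle") -> bytes:
    return kg.serialize(format=format)
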