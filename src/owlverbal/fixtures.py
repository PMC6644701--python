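"""Offline fixture ontologies and synthetic rating sets.

Two ontologies back every test in the package:

* the *worked-examples* ontology — exactly the axioms behind the four
  canonical sentences (an ICO-style subclass axiom, an existential
  restriction, the "Saturday is a week day" modelling curiosity, and a
  subclass whose superclass comes from an unimported ontology and so has no
  label);
* the *people* ontology — a small family-domain teaching ontology with 13
  classes, 8 properties and 9 individuals that exercises all fourteen
  supported axiom types (11 SubClassOf and 4 ObjectPropertyDomain axioms,
  matching the published per-type counts for this kind of ontology).

Synthetic ratings emulate a panel: rater 1 draws from a fixed categorical
distribution; each further rater copies rater 1 and independently perturbs
each dimension (to a *different* score) with the given probability, so the
expected exact-match agreement is exactly ``1 - disagreement_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdflib import BNode, Graph, Literal as RLiteral, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, XSD

from .harness import RatingRecord
from .model import VerbalizationRecord

__all__ = [
    "FixtureSpec",
    "PAPER_EXAMPLES_SPEC",
    "PEOPLE_SPEC",
    "build_paper_examples",
    "build_people_fixture",
    "simulate_ratings",
    "generate_all",
]

OBO = Namespace("http://purl.obolibrary.org/obo/")
PEOPLE = Namespace("http://example.org/people#")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a fixture: what the built file must contain."""

    name: str
    composition: dict[str, int]  # axiom type -> count
    labels: dict[str, Optional[str]]  # IRI -> label (None = deliberately absent)
    seed: int = 0

    @property
    def n_axioms(self) -> int:
        return sum(self.composition.values())


PAPER_EXAMPLES_SPEC = FixtureSpec(
    name="worked-examples",
    composition={"SubClassOf": 4},
    labels={
        str(OBO.ICO_0000062): "human subject unable to give informed consent",
        str(OBO.ICO_0000073): "human subject",
        str(OBO.ICO_0000171): "answer option text entity",
        str(OBO.IAO_0000136): "is about",
        str(OBO.ICO_0000064): "study requiring informed consent",
        str(OBO.TEO_0000048): "Saturday",
        str(OBO.TEO_0000084): "week day",
        str(OBO.TEO_0000100): "duration measurement",
        str(OBO.IAO_0000032): None,  # defining ontology not imported
    },
)

PEOPLE_SPEC = FixtureSpec(
    name="people",
    composition={
        "SubClassOf": 11,
        "EquivalentClasses": 1,
        "DisjointClasses": 1,
        "ClassAssertion": 4,
        "ObjectPropertyDomain": 4,
        "ObjectPropertyRange": 2,
        "DataPropertyDomain": 1,
        "DataPropertyRange": 2,
        "SymmetricObjectProperty": 1,
        "FunctionalObjectProperty": 1,
        "FunctionalDataProperty": 1,
        "ObjectPropertyAssertion": 3,
        "DataPropertyAssertion": 2,
        "DifferentIndividuals": 2,
    },
    labels={},  # every people entity is labeled; see _people_graph
)


def paper_examples_graph() -> Graph:
    """The worked-examples ontology as an in-memory RDF graph."""
    g = Graph()
    g.bind("obo", OBO)
    g.bind("owl", OWL)
    onto = URIRef("http://example.org/worked-examples")
    g.add((onto, RDF.type, OWL.Ontology))

    for iri, label in PAPER_EXAMPLES_SPEC.labels.items():
        node = URIRef(iri)
        if iri == str(OBO.IAO_0000136):
            g.add((node, RDF.type, OWL.ObjectProperty))
        elif iri == str(OBO.IAO_0000032):
            continue  # referenced but never declared or labeled
        else:
            g.add((node, RDF.type, OWL.Class))
        if label is not None:
            g.add((node, RDFS.label, RLiteral(label)))

    g.add((OBO.ICO_0000062, RDFS.subClassOf, OBO.ICO_0000073))
    g.add((OBO.TEO_0000048, RDFS.subClassOf, OBO.TEO_0000084))
    g.add((OBO.TEO_0000100, RDFS.subClassOf, OBO.IAO_0000032))
    restriction = BNode("existential1")
    g.add((restriction, RDF.type, OWL.Restriction))
    g.add((restriction, OWL.onProperty, OBO.IAO_0000136))
    g.add((restriction, OWL.someValuesFrom, OBO.ICO_0000064))
    g.add((OBO.ICO_0000171, RDFS.subClassOf, restriction))
    return g


_PEOPLE_CLASSES = {
    "Person": "person", "Man": "man", "Woman": "woman", "Parent": "parent",
    "Mother": "mother", "Father": "father", "Child": "child",
    "Grandparent": "grandparent", "Adult": "adult", "Driver": "driver",
    "Pet": "pet", "Dog": "dog", "Cat": "cat",
}
_PEOPLE_OBJECT_PROPS = {
    "hasChild": "has child", "hasPet": "has pet", "hasParent": "has parent",
    "isMarriedTo": "is married to", "drives": "drives", "likes": "likes",
}
_PEOPLE_DATA_PROPS = {"hasAge": "has age", "hasName": "has name"}
_PEOPLE_INDIVIDUALS = (
    "Bill", "Mary", "John", "Susan", "Fred", "Jane", "Mick", "Rex", "Tibbs",
)


def people_graph() -> Graph:
    """The family-domain teaching ontology as an in-memory RDF graph."""
    g = Graph()
    g.bind("people", PEOPLE)
    g.bind("owl", OWL)
    onto = URIRef("http://example.org/people")
    g.add((onto, RDF.type, OWL.Ontology))

    for local, label in _PEOPLE_CLASSES.items():
        g.add((PEOPLE[local], RDF.type, OWL.Class))
        g.add((PEOPLE[local], RDFS.label, RLiteral(label)))
    for local, label in _PEOPLE_OBJECT_PROPS.items():
        g.add((PEOPLE[local], RDF.type, OWL.ObjectProperty))
        g.add((PEOPLE[local], RDFS.label, RLiteral(label)))
    for local, label in _PEOPLE_DATA_PROPS.items():
        g.add((PEOPLE[local], RDF.type, OWL.DatatypeProperty))
        g.add((PEOPLE[local], RDFS.label, RLiteral(label)))
    for local in _PEOPLE_INDIVIDUALS:
        g.add((PEOPLE[local], RDF.type, OWL.NamedIndividual))
        g.add((PEOPLE[local], RDFS.label, RLiteral(local)))

    sub = [
        ("Man", "Person"), ("Woman", "Person"), ("Child", "Person"),
        ("Adult", "Person"), ("Driver", "Adult"), ("Mother", "Woman"),
        ("Father", "Man"), ("Grandparent", "Parent"), ("Dog", "Pet"),
        ("Cat", "Pet"),
    ]
    for c, d in sub:
        g.add((PEOPLE[c], RDFS.subClassOf, PEOPLE[d]))
    # the 11th SubClassOf: parent is something that has a person as child
    restriction = BNode("parentRestriction")
    g.add((restriction, RDF.type, OWL.Restriction))
    g.add((restriction, OWL.onProperty, PEOPLE.hasChild))
    g.add((restriction, OWL.someValuesFrom, PEOPLE.Person))
    g.add((PEOPLE.Parent, RDFS.subClassOf, restriction))

    # mother = woman and parent; the RDF list is built from named blank
    # nodes so both serializations are byte-stable across runs
    conj = BNode("motherConj")
    cell1, cell2 = BNode("motherMembers1"), BNode("motherMembers2")
    g.add((cell1, RDF.first, PEOPLE.Woman))
    g.add((cell1, RDF.rest, cell2))
    g.add((cell2, RDF.first, PEOPLE.Parent))
    g.add((cell2, RDF.rest, RDF.nil))
    g.add((conj, RDF.type, OWL.Class))
    g.add((conj, OWL.intersectionOf, cell1))
    g.add((PEOPLE.Mother, OWL.equivalentClass, conj))

    g.add((PEOPLE.Dog, OWL.disjointWith, PEOPLE.Cat))

    for ind, cls in (("Bill", "Man"), ("Mary", "Woman"), ("Rex", "Dog"), ("Mick", "Driver")):
        g.add((PEOPLE[ind], RDF.type, PEOPLE[cls]))

    for prop, cls in (
        ("hasChild", "Person"), ("hasPet", "Person"),
        ("isMarriedTo", "Person"), ("drives", "Adult"),
    ):
        g.add((PEOPLE[prop], RDFS.domain, PEOPLE[cls]))
    g.add((PEOPLE.hasPet, RDFS.range, PEOPLE.Pet))
    g.add((PEOPLE.hasParent, RDFS.range, PEOPLE.Parent))
    g.add((PEOPLE.hasAge, RDFS.domain, PEOPLE.Person))
    g.add((PEOPLE.hasAge, RDFS.range, XSD.integer))
    g.add((PEOPLE.hasName, RDFS.range, XSD.string))

    g.add((PEOPLE.isMarriedTo, RDF.type, OWL.SymmetricProperty))
    g.add((PEOPLE.isMarriedTo, RDF.type, OWL.FunctionalProperty))
    g.add((PEOPLE.hasAge, RDF.type, OWL.FunctionalProperty))

    g.add((PEOPLE.Bill, PEOPLE.hasChild, PEOPLE.Mary))
    g.add((PEOPLE.Fred, PEOPLE.likes, PEOPLE.Rex))
    g.add((PEOPLE.John, PEOPLE.isMarriedTo, PEOPLE.Susan))
    g.add((PEOPLE.Bill, PEOPLE.hasAge, RLiteral(42)))
    g.add((PEOPLE.Jane, PEOPLE.hasName, RLiteral("Jane Doe")))
    g.add((PEOPLE.Bill, OWL.differentFrom, PEOPLE.John))
    g.add((PEOPLE.Rex, OWL.differentFrom, PEOPLE.Tibbs))
    return g


def _deterministic_rdfxml(graph: Graph) -> str:
    """Serialize a graph as flat RDF/XML with fully sorted output.

    rdflib's serializers order subjects hash-dependently, which breaks the
    bit-identical-regeneration guarantee across interpreter runs; this
    writer sorts subjects and predicate-object pairs and names blank nodes
    by their (fixed) labels.
    """
    import re
    from xml.sax.saxutils import escape, quoteattr

    def split_iri(iri: str) -> tuple[str, str]:
        m = re.search(r"[^#/]+$", iri)
        if m is None or not re.match(r"[A-Za-z_][\w\-.]*$", m.group(0)):
            raise ValueError(f"cannot form a QName for predicate {iri}")
        return iri[: m.start()], m.group(0)

    bound = {}
    for prefix, ns in graph.namespaces():
        bound.setdefault(str(ns), prefix)
    ns_prefix: dict[str, str] = {str(RDF): "rdf"}
    for p in sorted({str(p) for p in graph.predicates()}):
        ns, _ = split_iri(p)
        if ns not in ns_prefix:
            candidate = bound.get(ns)
            ns_prefix[ns] = candidate if candidate else f"ns{len(ns_prefix)}"

    def qname(p) -> str:
        ns, local = split_iri(str(p))
        return f"{ns_prefix[ns]}:{local}"

    lines = ['<?xml version="1.0" encoding="utf-8"?>', "<rdf:RDF"]
    for ns, prefix in sorted(ns_prefix.items(), key=lambda kv: kv[1]):
        lines.append(f"   xmlns:{prefix}={quoteattr(ns)}")
    lines.append(">")
    for s in sorted(set(graph.subjects()), key=lambda n: (isinstance(n, BNode), str(n))):
        attr = (
            f"rdf:nodeID={quoteattr(str(s))}"
            if isinstance(s, BNode)
            else f"rdf:about={quoteattr(str(s))}"
        )
        lines.append(f"  <rdf:Description {attr}>")
        for p, o in sorted(graph.predicate_objects(s), key=lambda po: (str(po[0]), str(po[1]))):
            tag = qname(p)
            if isinstance(o, RLiteral):
                extra = ""
                if o.datatype is not None:
                    extra = f" rdf:datatype={quoteattr(str(o.datatype))}"
                elif o.language:
                    extra = f' xml:lang="{o.language}"'
                lines.append(f"    <{tag}{extra}>{escape(str(o))}</{tag}>")
            elif isinstance(o, BNode):
                lines.append(f"    <{tag} rdf:nodeID={quoteattr(str(o))}/>")
            else:
                lines.append(f"    <{tag} rdf:resource={quoteattr(str(o))}/>")
        lines.append("  </rdf:Description>")
    lines.append("</rdf:RDF>")
    return "\n".join(lines) + "\n"


def _write(graph: Graph, directory: Path, stem: str, fmt: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "turtle":
        path = directory / f"{stem}.ttl"
        payload = graph.serialize(format="turtle")
    elif fmt in ("rdfxml", "xml"):
        path = directory / f"{stem}.owl"
        payload = _deterministic_rdfxml(graph)
    else:
        raise ValueError(f"unsupported fixture serialization {fmt!r}")
    path.write_text(payload, encoding="utf-8")
    return path


def build_paper_examples(directory: str | Path, fmt: str = "turtle") -> Path:
    """Write the worked-examples ontology and return its path."""
    return _write(paper_examples_graph(), Path(directory), "worked_examples", fmt)


def build_people_fixture(directory: str | Path, fmt: str = "turtle") -> Path:
    """Write the people ontology and return its path."""
    return _write(people_graph(), Path(directory), "people", fmt)


# -- synthetic ratings ------------------------------------------------------

# Marginal score distributions for the baseline rater: mostly-clear,
# mostly-faithful ratings, the regime reported for small well-curated
# ontologies (clarity mean near 1.2, ~90% yes).
_CLARITY_P = (0.80, 0.15, 0.05)
_DOMAIN_P = (0.85, 0.10, 0.05)
_P_YES = 0.90


def simulate_ratings(
    records: Sequence[VerbalizationRecord],
    n_raters: int = 2,
    disagreement_rate: float = 0.1,
    seed: int = 0,
) -> list[RatingRecord]:
    """Draw a fully reproducible synthetic rating set for the given items.

    Rater 1 samples each dimension from the fixed categorical distributions
    above; raters 2..n copy rater 1 and, independently per item and
    dimension, switch to a different score with probability
    ``disagreement_rate``.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must be within [0, 1]")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(records)
    clarity = rng.choice([1, 2, 3], size=n, p=_CLARITY_P)
    domain = rng.choice([1, 2, 3], size=n, p=_DOMAIN_P)
    nl = np.where(rng.random(n) < _P_YES, "yes", "no")

    out: list[RatingRecord] = []
    for i, rec in enumerate(records):
        out.append(
            RatingRecord(rec.item_id, "rater1", int(clarity[i]), str(nl[i]), int(domain[i]))
        )
    for r in range(2, n_raters + 1):
        flip = rng.random((n, 3)) < disagreement_rate
        for i, rec in enumerate(records):
            c, d, y = int(clarity[i]), int(domain[i]), str(nl[i])
            if flip[i, 0]:
                c = int(rng.choice([v for v in (1, 2, 3) if v != c]))
            if flip[i, 1]:
                y = "no" if y == "yes" else "yes"
            if flip[i, 2]:
                d = int(rng.choice([v for v in (1, 2, 3) if v != d]))
            out.append(RatingRecord(rec.item_id, f"rater{r}", c, y, d))
    return out


def generate_all(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write every fixture file (both serializations) under ``directory``."""
    directory = Path(directory)
    paths = {
        "worked_examples_ttl": build_paper_examples(directory, "turtle"),
        "worked_examples_owl": build_paper_examples(directory, "rdfxml"),
        "people_ttl": build_people_fixture(directory, "turtle"),
        "people_owl": build_people_fixture(directory, "rdfxml"),
    }
    from .harness import write_ratings
    from .ontology_io import load_ontology
    from .verbalizer import verbalize_all

    axset = load_ontology(paths["people_ttl"])
    records = verbalize_all(axset)
    ratings = simulate_ratings(records, n_raters=2, disagreement_rate=0.1, seed=seed)
    paths["people_ratings"] = write_ratings(ratings, directory / "people_ratings.csv")
    return paths
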