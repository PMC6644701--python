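"""Load OWL2 ontologies from standard serializations into the axiom model.

RDF/XML and Turtle are parsed with :mod:`rdflib` and the axioms are
reconstructed from the OWL-to-RDF mapping (restriction blank nodes, RDF
lists for intersections, ``owl:AllDisjointClasses`` frames, ...).  OWL/XML
and OWL functional syntax do not have an installed parser, so this module
carries small readers for the subset of both languages that covers the
fourteen supported axiom types; both feed the same intermediate form, which
guarantees that the same ontology loads identically from every dialect.

Imports are *not* auto-resolved: an entity whose defining ontology was not
merged into the file simply has no ``rdfs:label``, and verbalizes from its
IRI fragment ("iao 0000032").  An opt-in ``follow_imports`` flag follows
``owl:imports`` for local files only, keeping everything offline.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from pathlib import Path
from typing import Optional, Union

import rdflib
from lxml import etree
from rdflib import BNode, Graph, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .manchester import render_manchester
from .model import (
    Axiom,
    AxiomSet,
    ClassExpr,
    Entity,
    EntityKind,
    Literal,
    SUPPORTED_AXIOM_TYPES,
)

logger = logging.getLogger(__name__)

__all__ = ["load_ontology", "count_by_type", "OntologyParseError"]

_XSD_NS = str(XSD)
_RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"

_SYMMETRIC_TYPES = frozenset({"EquivalentClasses", "DisjointClasses", "DifferentIndividuals"})

_DEFAULT_PREFIXES = {
    "owl": str(OWL),
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "xsd": _XSD_NS,
}


class OntologyParseError(ValueError):
    """The file could not be parsed in the requested (or detected) dialect."""


# ---------------------------------------------------------------------------
# Intermediate builder shared by all three readers
# ---------------------------------------------------------------------------

# class-expression AST nodes:
#   ("named", iri) ("intersection", [ast...]) ("union", [ast...])
#   ("complement", ast) ("some"|"only", prop_iri, filler_ast)
#   ("has_value", prop_iri, filler_ast) ("datatype", iri) ("ind", iri)
#   ("lit", lexical, datatype_iri_or_None) ("unsupported", text)


class _Builder:
    def __init__(self) -> None:
        self.prefixes: dict[str, str] = dict(_DEFAULT_PREFIXES)
        self.kinds: dict[str, EntityKind] = {}
        self.labels: dict[str, list[str]] = {}
        self.axiom_asts: list[tuple] = []
        self.unsupported: Counter = Counter()

    # -- declarations -------------------------------------------------------

    def declare(self, iri: str, kind: EntityKind) -> None:
        prev = self.kinds.get(iri)
        if prev is not None and prev is not kind:
            logger.warning("entity %s declared both %s and %s", iri, prev.value, kind.value)
        self.kinds[iri] = kind

    def suggest(self, iri: str, kind: EntityKind) -> None:
        """Record a kind inferred from usage position (declaration wins)."""
        self.kinds.setdefault(iri, kind)

    def add_label(self, iri: str, value: str, lang: Optional[str]) -> None:
        # English-tagged labels sort ahead of other labels; ties break
        # lexicographically — a deterministic choice where OWL allows many.
        tag = 0 if (lang is None or lang.startswith("en")) else 1
        self.labels.setdefault(iri, []).append((tag, value))  # type: ignore[arg-type]

    def label_of(self, iri: str) -> Optional[str]:
        values = self.labels.get(iri)
        if not values:
            return None
        if len(values) > 1:
            logger.info("entity %s has %d rdfs:label values; using the smallest", iri, len(values))
        return min(values)[1]

    # -- materialization ----------------------------------------------------

    def _entity(self, iri: str, fallback: EntityKind) -> Entity:
        kind = self.kinds.get(iri, fallback)
        return Entity(iri=iri, kind=kind, raw_label=self.label_of(iri))

    def _expr(self, ast: tuple) -> ClassExpr:
        tag = ast[0]
        if tag == "named":
            return ClassExpr.named(self._entity(ast[1], EntityKind.CLASS))
        if tag == "intersection":
            return ClassExpr.intersection(*(self._expr(a) for a in ast[1]))
        if tag == "union":
            return ClassExpr.union(*(self._expr(a) for a in ast[1]))
        if tag == "complement":
            return ClassExpr.complement(self._expr(ast[1]))
        if tag in ("some", "only", "has_value"):
            _, prop_iri, filler_ast = ast
            prop = self._entity(prop_iri, EntityKind.OBJECT_PROPERTY)
            filler = self._filler(filler_ast)
            ctor = {"some": ClassExpr.some, "only": ClassExpr.only, "has_value": ClassExpr.has_value}[tag]
            return ctor(prop, filler)
        if tag == "unsupported":
            return ClassExpr.unsupported(ast[1])
        raise AssertionError(f"bad expression AST {ast!r}")

    def _filler(self, ast: tuple):
        tag = ast[0]
        if tag == "datatype":
            return self._entity(ast[1], EntityKind.DATATYPE)
        if tag == "ind":
            return self._entity(ast[1], EntityKind.NAMED_INDIVIDUAL)
        if tag == "lit":
            return _make_literal(ast[1], ast[2])
        return self._expr(ast)

    def _axiom(self, ast: tuple) -> Axiom:
        t = ast[0]
        if t in ("SubClassOf", "EquivalentClasses"):
            return Axiom(t, (self._expr(ast[1]), self._expr(ast[2])))
        if t == "DisjointClasses":
            return Axiom(t, tuple(self._expr(a) for a in ast[1]))
        if t == "ClassAssertion":
            return Axiom(t, (self._expr(ast[1]), self._entity(ast[2], EntityKind.NAMED_INDIVIDUAL)))
        if t in ("ObjectPropertyDomain", "ObjectPropertyRange"):
            return Axiom(t, (self._entity(ast[1], EntityKind.OBJECT_PROPERTY), self._expr(ast[2])))
        if t == "DataPropertyDomain":
            return Axiom(t, (self._entity(ast[1], EntityKind.DATA_PROPERTY), self._expr(ast[2])))
        if t == "DataPropertyRange":
            return Axiom(
                t,
                (self._entity(ast[1], EntityKind.DATA_PROPERTY), self._entity(ast[2], EntityKind.DATATYPE)),
            )
        if t == "SymmetricObjectProperty" or t == "FunctionalObjectProperty":
            return Axiom(t, (self._entity(ast[1], EntityKind.OBJECT_PROPERTY),))
        if t == "FunctionalDataProperty":
            return Axiom(t, (self._entity(ast[1], EntityKind.DATA_PROPERTY),))
        if t == "ObjectPropertyAssertion":
            return Axiom(
                t,
                (
                    self._entity(ast[1], EntityKind.OBJECT_PROPERTY),
                    self._entity(ast[2], EntityKind.NAMED_INDIVIDUAL),
                    self._entity(ast[3], EntityKind.NAMED_INDIVIDUAL),
                ),
            )
        if t == "DataPropertyAssertion":
            return Axiom(
                t,
                (
                    self._entity(ast[1], EntityKind.DATA_PROPERTY),
                    self._entity(ast[2], EntityKind.NAMED_INDIVIDUAL),
                    _make_literal(ast[3][1], ast[3][2]),
                ),
            )
        if t == "DifferentIndividuals":
            return Axiom(t, tuple(self._entity(i, EntityKind.NAMED_INDIVIDUAL) for i in ast[1]))
        raise AssertionError(f"bad axiom AST {ast!r}")

    def finalize(self, source_format: str) -> AxiomSet:
        prefix_map = {p: ns for p, ns in self.prefixes.items() if p}
        axioms = [self._axiom(ast) for ast in self.axiom_asts]

        # canonicalize operand order of symmetric n-ary axioms so that every
        # serialization (which may state either direction) loads identically
        canonical: dict[str, Axiom] = {}
        for ax in axioms:
            if ax.type in _SYMMETRIC_TYPES:
                ax = _canonicalize_symmetric(ax, prefix_map)
            key = f"{ax.type}\x00{render_manchester(ax, 'curie', prefix_map)}"
            canonical.setdefault(key, ax)
        ordered = sorted(
            canonical.values(),
            key=lambda a: (a.type, render_manchester(a, "curie", prefix_map)),
        )

        entities: dict[str, Entity] = {}
        for iri, kind in self.kinds.items():
            entities[iri] = Entity(iri=iri, kind=kind, raw_label=self.label_of(iri))
        for ax in ordered:
            for ent in ax.iter_entities():
                entities.setdefault(ent.iri, ent)

        n_unlabeled = sum(1 for e in entities.values() if e.raw_label is None)
        logger.info(
            "loaded %d supported axioms (%d unsupported dropped), %d entities (%d unlabeled)",
            len(ordered), sum(self.unsupported.values()), len(entities), n_unlabeled,
        )
        for name, cnt in sorted(self.unsupported.items()):
            logger.info("  unsupported axiom type %s: %d", name, cnt)
        return AxiomSet(
            axioms=tuple(ordered),
            entities=entities,
            source_format=source_format,
            prefix_map=prefix_map,
            unsupported=self.unsupported,
        )


def _make_literal(lexical: str, datatype: Optional[str]) -> Literal:
    if datatype == _XSD_NS + "string":
        datatype = None  # plain and xsd:string literals are the same value
    return Literal(lexical, datatype)


def _sort_key_operand(op, prefix_map: dict[str, str]) -> tuple:
    from .manchester import curie, render_expr

    if isinstance(op, Entity):
        return (0, curie(op.iri, prefix_map))
    named = 0 if op.kind.value == "named" else 1
    return (named, render_expr(op, "curie", prefix_map))


def _canonicalize_symmetric(ax: Axiom, prefix_map: dict[str, str]) -> Axiom:
    ops = tuple(sorted(ax.operands, key=lambda o: _sort_key_operand(o, prefix_map)))
    return Axiom(ax.type, ops)


# ---------------------------------------------------------------------------
# RDF reader (RDF/XML and Turtle via rdflib)
# ---------------------------------------------------------------------------

_DECLARATION_TYPES = {
    OWL.Class: EntityKind.CLASS,
    RDFS.Class: EntityKind.CLASS,
    OWL.ObjectProperty: EntityKind.OBJECT_PROPERTY,
    OWL.DatatypeProperty: EntityKind.DATA_PROPERTY,
    OWL.NamedIndividual: EntityKind.NAMED_INDIVIDUAL,
    RDFS.Datatype: EntityKind.DATATYPE,
}

# rdf:type objects that are OWL machinery, not class assertions
_VOCAB_TYPES = set(_DECLARATION_TYPES) | {
    OWL.Ontology,
    OWL.AnnotationProperty,
    OWL.FunctionalProperty,
    OWL.SymmetricProperty,
    OWL.TransitiveProperty,
    OWL.InverseFunctionalProperty,
    OWL.ReflexiveProperty,
    OWL.IrreflexiveProperty,
    OWL.AsymmetricProperty,
    OWL.AllDisjointClasses,
    OWL.AllDifferent,
    OWL.Restriction,
}

_UNSUPPORTED_PREDICATES = {
    RDFS.subPropertyOf: "SubPropertyOf",
    OWL.inverseOf: "InverseObjectProperties",
    OWL.sameAs: "SameIndividual",
    OWL.propertyDisjointWith: "DisjointObjectProperties",
    OWL.equivalentProperty: "EquivalentProperties",
}

_UNSUPPORTED_CHARACTERISTICS = {
    OWL.TransitiveProperty: "TransitiveObjectProperty",
    OWL.InverseFunctionalProperty: "InverseFunctionalObjectProperty",
    OWL.ReflexiveProperty: "ReflexiveObjectProperty",
    OWL.IrreflexiveProperty: "IrreflexiveObjectProperty",
    OWL.AsymmetricProperty: "AsymmetricObjectProperty",
}


class _RdfReader:
    def __init__(self, graph: Graph, builder: _Builder):
        self.g = graph
        self.b = builder

    def run(self) -> None:
        g, b = self.g, self.b
        for prefix, ns in g.namespace_manager.namespaces():
            if prefix:
                b.prefixes[prefix] = str(ns)

        for s, o in g.subject_objects(RDF.type):
            if isinstance(s, URIRef) and o in _DECLARATION_TYPES:
                b.declare(str(s), _DECLARATION_TYPES[o])
        for s, o in g.subject_objects(RDFS.label):
            if isinstance(s, URIRef) and isinstance(o, rdflib.Literal):
                b.add_label(str(s), str(o), o.language)

        self._class_axioms()
        self._property_axioms()
        self._individual_axioms()

    # -- helpers ------------------------------------------------------------

    def _rdf_list(self, node) -> list:
        return list(Collection(self.g, node))

    def _is_datatype_ref(self, node) -> bool:
        return isinstance(node, URIRef) and (
            str(node).startswith(_XSD_NS)
            or self.b.kinds.get(str(node)) is EntityKind.DATATYPE
            or (node, RDF.type, RDFS.Datatype) in self.g
        )

    def _expr(self, node) -> tuple:
        g = self.g
        if isinstance(node, URIRef):
            return ("named", str(node))
        if not isinstance(node, BNode):
            return ("unsupported", f"non-class node {node}")
        members = g.value(node, OWL.intersectionOf)
        if members is not None:
            return ("intersection", [self._expr(m) for m in self._rdf_list(members)])
        members = g.value(node, OWL.unionOf)
        if members is not None:
            return ("union", [self._expr(m) for m in self._rdf_list(members)])
        comp = g.value(node, OWL.complementOf)
        if comp is not None:
            return ("complement", self._expr(comp))
        prop = g.value(node, OWL.onProperty)
        if prop is not None:
            prop_iri = str(prop)
            some = g.value(node, OWL.someValuesFrom)
            if some is not None:
                return ("some", prop_iri, self._restriction_filler(prop_iri, some))
            only = g.value(node, OWL.allValuesFrom)
            if only is not None:
                return ("only", prop_iri, self._restriction_filler(prop_iri, only))
            hv = g.value(node, OWL.hasValue)
            if hv is not None:
                if isinstance(hv, rdflib.Literal):
                    self.b.suggest(prop_iri, EntityKind.DATA_PROPERTY)
                    return ("has_value", prop_iri, ("lit", str(hv), _dt(hv)))
                self.b.suggest(prop_iri, EntityKind.OBJECT_PROPERTY)
                return ("has_value", prop_iri, ("ind", str(hv)))
            return self._unsupported_restriction(node, prop_iri)
        if g.value(node, OWL.oneOf) is not None:
            names = ", ".join(str(m).rsplit("/", 1)[-1] for m in self._rdf_list(g.value(node, OWL.oneOf)))
            return ("unsupported", "{" + names + "}")
        return ("unsupported", f"anonymous class {node}")

    def _restriction_filler(self, prop_iri: str, node) -> tuple:
        if self._is_datatype_ref(node):
            self.b.suggest(prop_iri, EntityKind.DATA_PROPERTY)
            return ("datatype", str(node))
        self.b.suggest(prop_iri, EntityKind.OBJECT_PROPERTY)
        return self._expr(node)

    def _unsupported_restriction(self, node, prop_iri: str) -> tuple:
        g = self.g
        for pred, kw in (
            (OWL.minCardinality, "min"),
            (OWL.maxCardinality, "max"),
            (OWL.cardinality, "exactly"),
            (OWL.minQualifiedCardinality, "min"),
            (OWL.maxQualifiedCardinality, "max"),
            (OWL.qualifiedCardinality, "exactly"),
        ):
            n = g.value(node, pred)
            if n is not None:
                local = prop_iri.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
                return ("unsupported", f"{local} {kw} {n}")
        if g.value(node, OWL.hasSelf) is not None:
            local = prop_iri.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
            return ("unsupported", f"{local} Self")
        return ("unsupported", f"restriction on {prop_iri}")

    # -- axiom extraction ---------------------------------------------------

    def _class_axioms(self) -> None:
        g, b = self.g, self.b
        for s, o in g.subject_objects(RDFS.subClassOf):
            b.axiom_asts.append(("SubClassOf", self._expr(s), self._expr(o)))
        for s, o in g.subject_objects(OWL.equivalentClass):
            b.axiom_asts.append(("EquivalentClasses", self._expr(s), self._expr(o)))
        for s, o in g.subject_objects(OWL.disjointWith):
            b.axiom_asts.append(("DisjointClasses", [self._expr(s), self._expr(o)]))
        for frame in g.subjects(RDF.type, OWL.AllDisjointClasses):
            members = g.value(frame, OWL.members)
            if members is not None:
                b.axiom_asts.append(
                    ("DisjointClasses", [self._expr(m) for m in self._rdf_list(members)])
                )

    def _property_axioms(self) -> None:
        g, b = self.g, self.b

        def prop_kind(p: URIRef, range_node=None) -> EntityKind:
            kind = b.kinds.get(str(p))
            if kind in (EntityKind.OBJECT_PROPERTY, EntityKind.DATA_PROPERTY):
                return kind
            if range_node is not None and self._is_datatype_ref(range_node):
                return EntityKind.DATA_PROPERTY
            return EntityKind.OBJECT_PROPERTY

        for s, o in g.subject_objects(RDFS.domain):
            if not isinstance(s, URIRef):
                continue
            kind = prop_kind(s)
            t = "DataPropertyDomain" if kind is EntityKind.DATA_PROPERTY else "ObjectPropertyDomain"
            b.suggest(str(s), kind)
            b.axiom_asts.append((t, str(s), self._expr(o)))
        for s, o in g.subject_objects(RDFS.range):
            if not isinstance(s, URIRef):
                continue
            kind = prop_kind(s, o)
            b.suggest(str(s), kind)
            if kind is EntityKind.DATA_PROPERTY:
                b.axiom_asts.append(("DataPropertyRange", str(s), str(o)))
            else:
                b.axiom_asts.append(("ObjectPropertyRange", str(s), self._expr(o)))
        for s in g.subjects(RDF.type, OWL.SymmetricProperty):
            if isinstance(s, URIRef):
                b.suggest(str(s), EntityKind.OBJECT_PROPERTY)
                b.axiom_asts.append(("SymmetricObjectProperty", str(s)))
        for s in g.subjects(RDF.type, OWL.FunctionalProperty):
            if not isinstance(s, URIRef):
                continue
            kind = prop_kind(s)
            b.suggest(str(s), kind)
            t = "FunctionalDataProperty" if kind is EntityKind.DATA_PROPERTY else "FunctionalObjectProperty"
            b.axiom_asts.append((t, str(s)))
        for typ, name in _UNSUPPORTED_CHARACTERISTICS.items():
            for _ in g.subjects(RDF.type, typ):
                b.unsupported[name] += 1
        for pred, name in _UNSUPPORTED_PREDICATES.items():
            for _ in g.subject_objects(pred):
                b.unsupported[name] += 1

    def _individual_axioms(self) -> None:
        g, b = self.g, self.b
        for s, o in g.subject_objects(RDF.type):
            if not isinstance(s, URIRef) or o in _VOCAB_TYPES:
                continue
            if isinstance(o, URIRef) and str(o).startswith((str(OWL), str(RDF), str(RDFS))):
                continue
            b.suggest(str(s), EntityKind.NAMED_INDIVIDUAL)
            b.axiom_asts.append(("ClassAssertion", self._expr(o), str(s)))
        for s, o in g.subject_objects(OWL.differentFrom):
            b.axiom_asts.append(("DifferentIndividuals", [str(s), str(o)]))
        for frame in g.subjects(RDF.type, OWL.AllDifferent):
            members = g.value(frame, OWL.distinctMembers) or g.value(frame, OWL.members)
            if members is not None:
                b.axiom_asts.append(("DifferentIndividuals", [str(m) for m in self._rdf_list(members)]))
        for s, p, o in g:
            if not isinstance(s, URIRef) or not isinstance(p, URIRef):
                continue
            kind = b.kinds.get(str(p))
            if kind is EntityKind.OBJECT_PROPERTY and isinstance(o, URIRef):
                b.axiom_asts.append(("ObjectPropertyAssertion", str(p), str(s), str(o)))
            elif kind is EntityKind.DATA_PROPERTY and isinstance(o, rdflib.Literal):
                b.axiom_asts.append(("DataPropertyAssertion", str(p), str(s), ("lit", str(o), _dt(o))))


def _dt(lit: rdflib.Literal) -> Optional[str]:
    return str(lit.datatype) if lit.datatype is not None else None


# ---------------------------------------------------------------------------
# OWL functional-syntax reader
# ---------------------------------------------------------------------------

_FUNC_TOKEN = re.compile(
    r"""
    \s+ | \#[^\n]*                          # whitespace / comments (skipped)
  | (?P<iri><[^>]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<dtsep>\^\^)
  | (?P<lang>@[A-Za-z\-]+)
  | (?P<assign>:=)
  | (?P<lpar>\() | (?P<rpar>\))
  | (?P<name>[A-Za-z_][\w\-.]*:[\w\-.]*|:[\w\-.]+|[A-Za-z_][\w\-.]*)
    """,
    re.VERBOSE,
)


def _func_tokenize(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    for m in _FUNC_TOKEN.finditer(text):
        if m.start() != pos:
            raise OntologyParseError(f"functional syntax: cannot tokenize {text[pos:m.start()]!r}")
        pos = m.end()
        if m.lastgroup:
            tokens.append((m.lastgroup, m.group(m.lastgroup)))
    if pos != len(text):
        raise OntologyParseError(f"functional syntax: cannot tokenize {text[pos:]!r}")
    return tokens


class _FuncNode:
    __slots__ = ("name", "args")

    def __init__(self, name: str, args: list):
        self.name = name
        self.args = args  # _FuncNode | ("iri", iri) | ("lit", lex, dt, lang)


class _FuncReader:
    def __init__(self, text: str, builder: _Builder):
        self.tokens = _func_tokenize(text)
        self.i = 0
        self.b = builder

    def run(self) -> None:
        # Prefix(...) declarations are collected (and stripped) up front by
        # _load_functional; anything reaching here is Ontology(...) or axioms.
        while self.i < len(self.tokens):
            node = self._read_node()
            if node.name == "Ontology":
                for arg in node.args:
                    if isinstance(arg, _FuncNode):
                        self._interpret(arg)
            else:
                self._interpret(node)

    # -- s-expression reading ----------------------------------------------

    def _read_node(self) -> _FuncNode:
        kind, val = self.tokens[self.i]
        if kind != "name":
            raise OntologyParseError(f"functional syntax: expected constructor, got {val!r}")
        self.i += 1
        if self.i >= len(self.tokens) or self.tokens[self.i][0] != "lpar":
            raise OntologyParseError(f"functional syntax: expected '(' after {val}")
        self.i += 1
        args: list = []
        while True:
            if self.i >= len(self.tokens):
                raise OntologyParseError(f"functional syntax: unclosed {val}(")
            kind2, val2 = self.tokens[self.i]
            if kind2 == "rpar":
                self.i += 1
                return _FuncNode(val, args)
            if kind2 == "name" and self.i + 1 < len(self.tokens) and self.tokens[self.i + 1][0] == "lpar":
                args.append(self._read_node())
            elif kind2 == "name" or kind2 == "iri":
                args.append(("iri", self._resolve_name(kind2, val2)))
                self.i += 1
            elif kind2 == "string":
                lex = val2[1:-1].replace('\\"', '"')
                dt = lang = None
                self.i += 1
                if self.i < len(self.tokens) and self.tokens[self.i][0] == "dtsep":
                    self.i += 1
                    k3, v3 = self.tokens[self.i]
                    dt = self._resolve_name(k3, v3)
                    self.i += 1
                elif self.i < len(self.tokens) and self.tokens[self.i][0] == "lang":
                    lang = self.tokens[self.i][1][1:]
                    self.i += 1
                args.append(("lit", lex, dt, lang))
            elif kind2 == "assign":
                args.append(("assign", val2))
                self.i += 1
            else:
                raise OntologyParseError(f"functional syntax: unexpected token {val2!r}")

    def _resolve_name(self, kind: str, val: str) -> str:
        if kind == "iri":
            return val[1:-1]
        prefix, _, local = val.partition(":")
        if not _ and local == "":
            return val  # bare word (shouldn't occur as an IRI)
        ns = self.b.prefixes.get(prefix or "")
        if ns is None:
            raise OntologyParseError(f"functional syntax: undeclared prefix {prefix!r}:")
        return ns + local

    # -- interpretation ------------------------------------------------------

    _ENTITY_DECL = {
        "Class": EntityKind.CLASS,
        "ObjectProperty": EntityKind.OBJECT_PROPERTY,
        "DataProperty": EntityKind.DATA_PROPERTY,
        "NamedIndividual": EntityKind.NAMED_INDIVIDUAL,
        "Datatype": EntityKind.DATATYPE,
    }

    def _iri(self, arg) -> str:
        if isinstance(arg, tuple) and arg[0] == "iri":
            return arg[1]
        if isinstance(arg, _FuncNode) and len(arg.args) == 1:
            return self._iri(arg.args[0])
        raise OntologyParseError(f"functional syntax: expected an IRI, got {arg!r}")

    def _expr_ast(self, arg) -> tuple:
        if isinstance(arg, tuple) and arg[0] == "iri":
            return ("named", arg[1])
        assert isinstance(arg, _FuncNode)
        name, args = arg.name, arg.args
        if name == "ObjectIntersectionOf":
            return ("intersection", [self._expr_ast(a) for a in args])
        if name == "ObjectUnionOf":
            return ("union", [self._expr_ast(a) for a in args])
        if name == "ObjectComplementOf":
            return ("complement", self._expr_ast(args[0]))
        if name in ("ObjectSomeValuesFrom", "ObjectAllValuesFrom"):
            prop = self._iri(args[0])
            self.b.suggest(prop, EntityKind.OBJECT_PROPERTY)
            tag = "some" if name == "ObjectSomeValuesFrom" else "only"
            return (tag, prop, self._expr_ast(args[1]))
        if name in ("DataSomeValuesFrom", "DataAllValuesFrom"):
            prop = self._iri(args[0])
            self.b.suggest(prop, EntityKind.DATA_PROPERTY)
            tag = "some" if name == "DataSomeValuesFrom" else "only"
            return (tag, prop, ("datatype", self._iri(args[1])))
        if name == "ObjectHasValue":
            prop = self._iri(args[0])
            self.b.suggest(prop, EntityKind.OBJECT_PROPERTY)
            return ("has_value", prop, ("ind", self._iri(args[1])))
        if name == "DataHasValue":
            prop = self._iri(args[0])
            self.b.suggest(prop, EntityKind.DATA_PROPERTY)
            lit = args[1]
            return ("has_value", prop, ("lit", lit[1], lit[2]))
        return ("unsupported", name)

    def _interpret(self, node: _FuncNode) -> None:
        b, name, args = self.b, node.name, node.args
        if name == "Declaration":
            inner = args[0]
            kind = self._ENTITY_DECL.get(inner.name)
            if kind is not None:
                b.declare(self._iri(inner.args[0]), kind)
            return
        if name == "AnnotationAssertion":
            prop = self._iri(args[0])
            if prop == _RDFS_LABEL and isinstance(args[2], tuple) and args[2][0] == "lit":
                b.add_label(self._iri(args[1]), args[2][1], args[2][3])
            return
        if name in ("Annotation", "Import"):
            return
        if name == "SubClassOf":
            b.axiom_asts.append(("SubClassOf", self._expr_ast(args[0]), self._expr_ast(args[1])))
        elif name == "EquivalentClasses":
            first = self._expr_ast(args[0])
            for other in args[1:]:
                b.axiom_asts.append(("EquivalentClasses", first, self._expr_ast(other)))
        elif name == "DisjointClasses":
            b.axiom_asts.append(("DisjointClasses", [self._expr_ast(a) for a in args]))
        elif name == "ClassAssertion":
            b.axiom_asts.append(("ClassAssertion", self._expr_ast(args[0]), self._iri(args[1])))
        elif name in ("ObjectPropertyDomain", "ObjectPropertyRange"):
            prop = self._iri(args[0])
            b.suggest(prop, EntityKind.OBJECT_PROPERTY)
            b.axiom_asts.append((name, prop, self._expr_ast(args[1])))
        elif name == "DataPropertyDomain":
            prop = self._iri(args[0])
            b.suggest(prop, EntityKind.DATA_PROPERTY)
            b.axiom_asts.append((name, prop, self._expr_ast(args[1])))
        elif name == "DataPropertyRange":
            prop = self._iri(args[0])
            b.suggest(prop, EntityKind.DATA_PROPERTY)
            b.axiom_asts.append((name, prop, self._iri(args[1])))
        elif name in ("SymmetricObjectProperty", "FunctionalObjectProperty"):
            prop = self._iri(args[0])
            b.suggest(prop, EntityKind.OBJECT_PROPERTY)
            b.axiom_asts.append((name, prop))
        elif name == "FunctionalDataProperty":
            prop = self._iri(args[0])
            b.suggest(prop, EntityKind.DATA_PROPERTY)
            b.axiom_asts.append((name, prop))
        elif name == "ObjectPropertyAssertion":
            b.axiom_asts.append(
                (name, self._iri(args[0]), self._iri(args[1]), self._iri(args[2]))
            )
        elif name == "DataPropertyAssertion":
            lit = args[2]
            b.axiom_asts.append(
                (name, self._iri(args[0]), self._iri(args[1]), ("lit", lit[1], lit[2]))
            )
        elif name == "DifferentIndividuals":
            b.axiom_asts.append((name, [self._iri(a) for a in args]))
        else:
            b.unsupported[name] += 1


def _func_collect_prefixes(text: str, builder: _Builder) -> None:
    for m in re.finditer(r"Prefix\(\s*([\w\-.]*):\s*:?=\s*<([^>]*)>\s*\)", text):
        prefix, ns = m.group(1), m.group(2)
        builder.prefixes[prefix or ""] = ns


def _load_functional(text: str, builder: _Builder) -> None:
    _func_collect_prefixes(text, builder)
    body = re.sub(r"Prefix\(\s*[\w\-.]*:\s*:?=\s*<[^>]*>\s*\)", "", text)
    _FuncReader(body, builder).run()


# ---------------------------------------------------------------------------
# OWL/XML reader
# ---------------------------------------------------------------------------

_OWLXML_NS = "http://www.w3.org/2002/07/owl#"


class _OwlXmlReader:
    def __init__(self, root, builder: _Builder):
        self.root = root
        self.b = builder

    def run(self) -> None:
        for pfx in self.root.findall(f"{{{_OWLXML_NS}}}Prefix"):
            name = pfx.get("name") or ""
            if name:
                self.b.prefixes[name] = pfx.get("IRI", "")
        func = _FuncReader.__new__(_FuncReader)
        func.b = self.b
        for child in self.root:
            tag = etree.QName(child).localname
            if tag == "Prefix":
                continue
            node = self._to_node(child)
            if node is not None:
                func._interpret(node)

    def _resolve(self, elem) -> str:
        iri = elem.get("IRI")
        if iri is not None:
            return iri
        abbrev = elem.get("abbreviatedIRI")
        if abbrev is not None:
            prefix, _, local = abbrev.partition(":")
            ns = self.b.prefixes.get(prefix)
            if ns is None:
                raise OntologyParseError(f"OWL/XML: undeclared prefix {prefix!r}")
            return ns + local
        raise OntologyParseError(f"OWL/XML: element {elem.tag} lacks an IRI")

    def _to_node(self, elem) -> Optional[_FuncNode]:
        tag = etree.QName(elem).localname
        args: list = []
        for child in elem:
            ctag = etree.QName(child).localname
            if ctag in ("Class", "ObjectProperty", "DataProperty", "NamedIndividual",
                        "Datatype", "AnnotationProperty"):
                if tag == "Declaration":
                    args.append(_FuncNode(ctag, [("iri", self._resolve(child))]))
                else:
                    args.append(("iri", self._resolve(child)))
            elif ctag == "IRI":
                args.append(("iri", child.text or ""))
            elif ctag == "AbbreviatedIRI":
                prefix, _, local = (child.text or "").partition(":")
                ns = self.b.prefixes.get(prefix)
                if ns is None:
                    raise OntologyParseError(f"OWL/XML: undeclared prefix {prefix!r}")
                args.append(("iri", ns + local))
            elif ctag == "Literal":
                dt = child.get("datatypeIRI")
                lang = child.get("{http://www.w3.org/XML/1998/namespace}lang")
                args.append(("lit", child.text or "", dt, lang))
            else:
                sub = self._to_node(child)
                if sub is not None:
                    args.append(sub)
        return _FuncNode(tag, args)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

_FORMAT_ALIASES = {
    "ttl": "turtle", "turtle": "turtle", "n3": "turtle",
    "rdf": "rdfxml", "rdfxml": "rdfxml", "rdf/xml": "rdfxml", "xml": "rdfxml",
    "owx": "owlxml", "owlxml": "owlxml", "owl/xml": "owlxml",
    "ofn": "functional", "functional": "functional",
}

_EXTENSION_FORMATS = {
    ".ttl": "turtle", ".n3": "turtle", ".ofn": "functional", ".owx": "owlxml",
}


def detect_format(path: Path, text: str) -> str:
    """Guess the serialization from the extension, then the content."""
    ext_format = _EXTENSION_FORMATS.get(path.suffix.lower())
    if ext_format:
        return ext_format
    head = re.sub(r"^\s*(#[^\n]*\n\s*)*", "", text)[:4000]
    if re.match(r"(Prefix|Ontology)\s*\(", head):
        return "functional"
    if head.startswith("<"):
        stripped = re.sub(r"<\?xml[^>]*\?>\s*|<!--.*?-->\s*", "", head, flags=re.DOTALL)
        if re.match(r"<(\w+:)?Ontology[\s>]", stripped) and _OWLXML_NS in head:
            return "owlxml"
        return "rdfxml"
    return "turtle"


def load_ontology(
    path: Union[str, Path],
    format: Optional[str] = None,
    follow_imports: bool = False,
) -> AxiomSet:
    """Load an ontology file into an :class:`AxiomSet`.

    Only axioms among the fourteen supported types are returned; anything
    else is counted in ``AxiomSet.unsupported`` and logged.  An empty
    ontology document yields an empty (valid) axiom set.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise OntologyParseError(f"cannot read ontology file {path}: {exc}") from exc

    if format is not None:
        fmt = _FORMAT_ALIASES.get(format.lower())
        if fmt is None:
            raise OntologyParseError(f"unknown serialization format {format!r}")
    else:
        fmt = detect_format(path, text)

    builder = _Builder()
    if fmt in ("turtle", "rdfxml"):
        graph = Graph()
        rdflib_fmt = "turtle" if fmt == "turtle" else "xml"
        try:
            graph.parse(data=text, format=rdflib_fmt, publicID=path.resolve().as_uri())
        except Exception as exc:
            raise OntologyParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
        if follow_imports:
            _follow_local_imports(graph, path)
        _RdfReader(graph, builder).run()
    elif fmt == "functional":
        try:
            _load_functional(text, builder)
        except OntologyParseError:
            raise
        except Exception as exc:
            raise OntologyParseError(f"cannot parse {path} as functional syntax: {exc}") from exc
    elif fmt == "owlxml":
        try:
            root = etree.fromstring(text.encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            raise OntologyParseError(f"cannot parse {path} as OWL/XML: {exc}") from exc
        _OwlXmlReader(root, builder).run()
    else:  # pragma: no cover
        raise OntologyParseError(f"unknown serialization format {fmt!r}")
    return builder.finalize(fmt)


def _follow_local_imports(graph: Graph, path: Path) -> None:
    for _, imported in graph.subject_objects(OWL.imports):
        target = str(imported)
        if target.startswith("file://"):
            local = Path(target[len("file://"):])
        else:
            local = path.parent / target
        if local.exists():
            graph.parse(local.as_posix())
        else:
            logger.warning("owl:imports target %s not found locally; skipped", target)


def count_by_type(axset: AxiomSet) -> dict[str, int]:
    """Count the loaded axioms per supported type name.

    Keys are exactly the type names present; the counts sum to
    ``len(axset)``.
    """
    counts = Counter(ax.type for ax in axset.axioms)
    return {t: counts[t] for t in SUPPORTED_AXIOM_TYPES if t in counts}
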