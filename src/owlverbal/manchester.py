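"""Manchester syntax rendering (and a subset parser for round-trip checks).

Rendering follows the W3C Manchester syntax note for the fourteen supported
axiom types: frame-style keywords (``SubClassOf:``, ``EquivalentTo:``,
``DisjointWith:``, ``Domain:``, ``Range:``, ``Types:``, ``Facts:``,
``Characteristics:``) and the class-expression keywords ``some``, ``only``,
``value``, ``and``, ``or``, ``not``.

Entity names follow a policy:

* ``curie``  — compact IRI via the prefix map; OBO-style IRIs
  (``.../obo/ICO_0000062``) abbreviate to their ID space (``ICO:0000062``).
  Unknown namespaces fall back to ``<full-iri>``.
* ``label``  — the ``rdfs:label``, single-quoted when it contains spaces
  (for human-facing sheets).

The parser accepts exactly the renderer's output language; it is written as
an ordinary tokenizer + recursive-descent parser over the grammar, not by
inverting the templates, so it can serve as an independent round-trip check.
"""

from __future__ import annotations

import re
from typing import Optional

from .model import (
    Axiom,
    ClassExpr,
    Entity,
    EntityKind,
    ExprKind,
    Literal,
)

__all__ = ["render_manchester", "render_expr", "parse_manchester", "curie"]

_OBO_RE = re.compile(r"^(https?://purl\.obolibrary\.org/obo/)([A-Za-z]+)_([A-Za-z0-9]+)$")

_XSD = "http://www.w3.org/2001/XMLSchema#"
_NUMERIC_XSD = {_XSD + t for t in ("integer", "int", "long", "decimal", "float", "double")}


def curie(iri: str, prefix_map: dict[str, str]) -> str:
    """Compact an IRI against a prefix map (longest-namespace match wins)."""
    m = _OBO_RE.match(iri)
    if m:
        return f"{m.group(2)}:{m.group(3)}"
    best: Optional[tuple[str, str]] = None
    for prefix, ns in prefix_map.items():
        if iri.startswith(ns) and len(iri) > len(ns):
            if best is None or len(ns) > len(best[1]):
                best = (prefix, ns)
    if best is not None:
        local = iri[len(best[1]):]
        if re.fullmatch(r"[A-Za-z_][\w\-.]*", local):
            return f"{best[0]}:{local}"
    return f"<{iri}>"


def _name(entity: Entity, name_policy: str, prefix_map: dict[str, str]) -> str:
    if name_policy == "label" and entity.raw_label:
        label = entity.raw_label
        if re.fullmatch(r"[\w\-.]+", label):
            return label
        return "'" + label.replace("'", "\\'") + "'"
    return curie(entity.iri, prefix_map)


def _literal(lit: Literal) -> str:
    if lit.datatype in _NUMERIC_XSD and re.fullmatch(r"-?\d+(\.\d+)?", lit.lexical):
        return lit.lexical
    return '"' + lit.lexical.replace('"', '\\"') + '"'


def render_expr(
    expr: ClassExpr, name_policy: str = "curie", prefix_map: Optional[dict[str, str]] = None
) -> str:
    """Render a class expression; sub-expressions are parenthesized as needed."""
    pm = prefix_map or {}

    def atom(e: ClassExpr) -> str:
        s = go(e)
        if e.kind is ExprKind.NAMED:
            return s
        return f"({s})"

    def filler_str(f) -> str:
        if isinstance(f, Entity):
            return _name(f, name_policy, pm)
        if isinstance(f, Literal):
            return _literal(f)
        return atom(f)

    def go(e: ClassExpr) -> str:
        if e.kind is ExprKind.NAMED:
            return _name(e.entity, name_policy, pm)
        if e.kind is ExprKind.INTERSECTION:
            return " and ".join(atom(c) for c in e.children)
        if e.kind is ExprKind.UNION:
            return " or ".join(atom(c) for c in e.children)
        if e.kind is ExprKind.COMPLEMENT:
            return "not " + atom(e.children[0])
        if e.kind is ExprKind.SOME_VALUES:
            return f"{_name(e.prop, name_policy, pm)} some {filler_str(e.filler)}"
        if e.kind is ExprKind.ALL_VALUES:
            return f"{_name(e.prop, name_policy, pm)} only {filler_str(e.filler)}"
        if e.kind is ExprKind.HAS_VALUE:
            return f"{_name(e.prop, name_policy, pm)} value {filler_str(e.filler)}"
        return e.text  # unsupported constructor: carried-through description

    return go(expr)


def render_manchester(
    axiom: Axiom, name_policy: str = "curie", prefix_map: Optional[dict[str, str]] = None
) -> str:
    """Render one axiom as a single Manchester-syntax line."""
    pm = prefix_map or {}

    def n(entity: Entity) -> str:
        return _name(entity, name_policy, pm)

    def x(expr: ClassExpr) -> str:
        return render_expr(expr, name_policy, pm)

    t, ops = axiom.type, axiom.operands
    if t == "SubClassOf":
        return f"{x(ops[0])} SubClassOf: {x(ops[1])}"
    if t == "EquivalentClasses":
        return f"{x(ops[0])} EquivalentTo: {x(ops[1])}"
    if t == "DisjointClasses":
        if len(ops) == 2:
            return f"{x(ops[0])} DisjointWith: {x(ops[1])}"
        return "DisjointClasses: " + ", ".join(x(o) for o in ops)
    if t == "ClassAssertion":
        return f"{n(ops[1])} Types: {x(ops[0])}"
    if t == "ObjectPropertyDomain" or t == "DataPropertyDomain":
        return f"{n(ops[0])} Domain: {x(ops[1])}"
    if t == "ObjectPropertyRange":
        return f"{n(ops[0])} Range: {x(ops[1])}"
    if t == "DataPropertyRange":
        return f"{n(ops[0])} Range: {n(ops[1])}"
    if t == "SymmetricObjectProperty":
        return f"{n(ops[0])} Characteristics: Symmetric"
    if t in ("FunctionalObjectProperty", "FunctionalDataProperty"):
        return f"{n(ops[0])} Characteristics: Functional"
    if t == "ObjectPropertyAssertion":
        return f"{n(ops[1])} Facts: {n(ops[0])} {n(ops[2])}"
    if t == "DataPropertyAssertion":
        return f"{n(ops[1])} Facts: {n(ops[0])} {_literal(ops[2])}"
    if t == "DifferentIndividuals":
        if len(ops) == 2:
            return f"{n(ops[0])} DifferentFrom: {n(ops[1])}"
        return "DifferentIndividuals: " + ", ".join(n(o) for o in ops)
    raise AssertionError(f"unhandled axiom type {t}")


# ---------------------------------------------------------------------------
# Subset parser (round-trip verification)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    '(?P<qname>(?:[^'\\]|\\.)*)'      # single-quoted name
  | "(?P<string>(?:[^"\\]|\\.)*)"     # double-quoted literal
  | <(?P<iri>[^>]*)>                  # full IRI
  | (?P<frame>\w+:)(?=\s)             # frame keyword like SubClassOf:
  | (?P<num>-?\d+(?:\.\d+)?)          # numeric literal
  | (?P<name>[\w\-.]+:[\w\-.]+|\w[\w\-.]*)  # CURIE or bare word
  | (?P<lpar>\() | (?P<rpar>\))
  | (?P<comma>,)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"some", "only", "value", "and", "or", "not"}


class ManchesterParseError(ValueError):
    pass


class _NameResolver:
    """Resolve rendered names (CURIEs, labels, IRIs) back to entities."""

    def __init__(self, entities: dict[str, Entity], prefix_map: dict[str, str]):
        self.by_iri = entities
        self.by_curie = {curie(e.iri, prefix_map): e for e in entities.values()}
        self.by_label = {e.raw_label: e for e in entities.values() if e.raw_label}

    def resolve(self, token_kind: str, value: str) -> Entity:
        if token_kind == "iri":
            if value in self.by_iri:
                return self.by_iri[value]
        elif token_kind == "qname":
            label = value.replace("\\'", "'")
            if label in self.by_label:
                return self.by_label[label]
        else:
            if value in self.by_curie:
                return self.by_curie[value]
            if value in self.by_label:
                return self.by_label[value]
        raise ManchesterParseError(f"unknown entity name: {value!r}")


class _Parser:
    def __init__(self, text: str, resolver: _NameResolver):
        self.tokens: list[tuple[str, str]] = []
        pos = 0
        for m in _TOKEN_RE.finditer(text):
            if text[pos:m.start()].strip():
                raise ManchesterParseError(f"cannot tokenize {text[pos:m.start()]!r}")
            self.tokens.append((m.lastgroup, m.group(m.lastgroup)))
            pos = m.end()
        if text[pos:].strip():
            raise ManchesterParseError(f"cannot tokenize {text[pos:]!r}")
        self.i = 0
        self.resolver = resolver

    def peek(self) -> Optional[tuple[str, str]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ManchesterParseError("unexpected end of input")
        self.i += 1
        return tok

    def expect_keyword(self, *words: str) -> str:
        kind, val = self.next()
        if kind not in ("name",) or val not in words:
            raise ManchesterParseError(f"expected one of {words}, got {val!r}")
        return val

    # -- expressions --------------------------------------------------------

    def parse_expr(self) -> ClassExpr:
        left = self.parse_conjunction()
        parts = [left]
        while self.peek() == ("name", "or"):
            self.next()
            parts.append(self.parse_conjunction())
        return parts[0] if len(parts) == 1 else ClassExpr.union(*parts)

    def parse_conjunction(self) -> ClassExpr:
        parts = [self.parse_unary()]
        while self.peek() == ("name", "and"):
            self.next()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else ClassExpr.intersection(*parts)

    def parse_unary(self) -> ClassExpr:
        if self.peek() == ("name", "not"):
            self.next()
            return ClassExpr.complement(self.parse_unary())
        return self.parse_primary()

    def parse_primary(self) -> ClassExpr:
        kind, val = self.next()
        if kind == "lpar":
            inner = self.parse_expr()
            if self.next()[0] != "rpar":
                raise ManchesterParseError("missing closing parenthesis")
            return inner
        if kind in ("name", "qname", "iri"):
            nxt = self.peek()
            if nxt is not None and nxt[0] == "name" and nxt[1] in ("some", "only", "value"):
                prop = self.resolver.resolve(kind, val)
                op = self.next()[1]
                filler = self.parse_filler()
                if op == "some":
                    return ClassExpr.some(prop, filler)
                if op == "only":
                    return ClassExpr.only(prop, filler)
                return ClassExpr.has_value(prop, filler)
            entity = self.resolver.resolve(kind, val)
            if entity.kind in (EntityKind.DATATYPE, EntityKind.NAMED_INDIVIDUAL):
                raise ManchesterParseError(f"{val!r} is not a class")
            return ClassExpr.named(entity)
        raise ManchesterParseError(f"unexpected token {val!r}")

    def parse_filler(self):
        kind, val = self.peek()
        if kind == "string":
            self.next()
            return Literal(val.replace('\\"', '"'))
        if kind == "num":
            self.next()
            dt = _XSD + ("decimal" if "." in val else "integer")
            return Literal(val, dt)
        if kind in ("name", "qname", "iri") and val not in _KEYWORDS:
            # peek one further: a bare entity may itself start a restriction
            save = self.i
            self.next()
            nxt = self.peek()
            self.i = save
            if not (nxt is not None and nxt[0] == "name" and nxt[1] in ("some", "only", "value")):
                entity = self.resolver.resolve(kind, val)
                self.next()
                if entity.kind in (EntityKind.DATATYPE, EntityKind.NAMED_INDIVIDUAL):
                    return entity
                return ClassExpr.named(entity)
        expr = self.parse_unary()
        return expr

    # -- axioms -------------------------------------------------------------

    def parse_entity(self) -> Entity:
        kind, val = self.next()
        if kind not in ("name", "qname", "iri"):
            raise ManchesterParseError(f"expected a name, got {val!r}")
        return self.resolver.resolve(kind, val)

    def parse_axiom(self) -> Axiom:
        # n-ary frames start with the frame keyword
        if self.peek()[0] == "frame":
            frame = self.next()[1]
            if frame == "DisjointClasses:":
                exprs = [self.parse_expr()]
                while self.peek() == ("comma", ","):
                    self.next()
                    exprs.append(self.parse_expr())
                return Axiom("DisjointClasses", tuple(exprs))
            if frame == "DifferentIndividuals:":
                inds = [self.parse_entity()]
                while self.peek() == ("comma", ","):
                    self.next()
                    inds.append(self.parse_entity())
                return Axiom("DifferentIndividuals", tuple(inds))
            raise ManchesterParseError(f"unknown frame {frame!r}")

        # A subject may be any entity (individual/property frames) or a
        # class expression (class frames, incl. complex GCI left sides).
        subject_ent: Optional[Entity] = None
        subject_expr: Optional[ClassExpr] = None
        if (
            self.peek()[0] in ("name", "qname", "iri")
            and self.i + 1 < len(self.tokens)
            and self.tokens[self.i + 1][0] == "frame"
        ):
            subject_ent = self.parse_entity()
            if subject_ent.kind is EntityKind.CLASS:
                subject_expr = ClassExpr.named(subject_ent)
        else:
            subject_expr = self.parse_expr()
        kind, frame = self.next()
        if kind != "frame":
            raise ManchesterParseError(f"expected a frame keyword, got {frame!r}")

        def subject_entity() -> Entity:
            if subject_ent is None:
                raise ManchesterParseError(f"frame {frame!r} requires a named subject")
            return subject_ent

        def subject_class() -> ClassExpr:
            if subject_expr is None:
                raise ManchesterParseError(f"frame {frame!r} requires a class subject")
            return subject_expr

        if frame == "SubClassOf:":
            return Axiom("SubClassOf", (subject_class(), self.parse_expr()))
        if frame == "EquivalentTo:":
            return Axiom("EquivalentClasses", (subject_class(), self.parse_expr()))
        if frame == "DisjointWith:":
            return Axiom("DisjointClasses", (subject_class(), self.parse_expr()))
        if frame == "Types:":
            ind = subject_entity()
            return Axiom("ClassAssertion", (self.parse_expr(), ind))
        if frame == "DifferentFrom:":
            return Axiom("DifferentIndividuals", (subject_entity(), self.parse_entity()))
        if frame == "Domain:":
            prop = subject_entity()
            t = "DataPropertyDomain" if prop.kind is EntityKind.DATA_PROPERTY else "ObjectPropertyDomain"
            return Axiom(t, (prop, self.parse_expr()))
        if frame == "Range:":
            prop = subject_entity()
            if prop.kind is EntityKind.DATA_PROPERTY:
                return Axiom("DataPropertyRange", (prop, self.parse_entity()))
            return Axiom("ObjectPropertyRange", (prop, self.parse_expr()))
        if frame == "Characteristics:":
            prop = subject_entity()
            trait = self.expect_keyword("Symmetric", "Functional")
            if trait == "Symmetric":
                return Axiom("SymmetricObjectProperty", (prop,))
            t = "FunctionalDataProperty" if prop.kind is EntityKind.DATA_PROPERTY else "FunctionalObjectProperty"
            return Axiom(t, (prop,))
        if frame == "Facts:":
            subj = subject_entity()
            prop = self.parse_entity()
            if prop.kind is EntityKind.DATA_PROPERTY:
                kind, val = self.next()
                if kind == "string":
                    lit = Literal(val.replace('\\"', '"'))
                elif kind == "num":
                    dt = _XSD + ("decimal" if "." in val else "integer")
                    lit = Literal(val, dt)
                else:
                    raise ManchesterParseError(f"expected a literal, got {val!r}")
                return Axiom("DataPropertyAssertion", (prop, subj, lit))
            return Axiom("ObjectPropertyAssertion", (prop, subj, self.parse_entity()))
        raise ManchesterParseError(f"unknown frame {frame!r}")


def parse_manchester(
    text: str, entities: dict[str, Entity], prefix_map: Optional[dict[str, str]] = None
) -> Axiom:
    """Parse one rendered Manchester line back into an :class:`Axiom`.

    Names are resolved against the given entity index (CURIE, label, or full
    IRI).  Raises :class:`ManchesterParseError` on anything outside the
    supported subset.
    """
    parser = _Parser(text, _NameResolver(entities, prefix_map or {}))
    axiom = parser.parse_axiom()
    if parser.peek() is not None:
        raise ManchesterParseError(f"trailing tokens from {parser.peek()!r}")
    return axiom
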