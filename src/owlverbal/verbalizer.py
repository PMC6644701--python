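"""Template-based verbalization of OWL axioms into English sentences.

Each of the fourteen supported axiom types has a fixed sentence template;
class expressions are verbalized by structural recursion, with existential
restrictions in predicate position introducing the relative construction
"something that <verb phrase>".  Two discourse styles are offered:

* ``explicit`` (default) — always uses "is something that ..." for
  restrictions in predicate position, e.g. "every answer option text entity
  is something that is about a study requiring informed consent";
* ``compact``  — when the restriction's property is itself copular ("is
  about"), the relative construction is elided: "every answer option text
  entity is about a study requiring informed consent".  All other sentences
  are identical between the two styles.

Sentences are emitted without sentence-initial capitalization and without a
final period; label tokens are never case-modified or re-inflected.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Optional, Union

from .lexicon import Lexicon, LexSource, PhraseForm, VerbPhrase
from .manchester import render_manchester
from .model import (
    Axiom,
    AxiomSet,
    ClassExpr,
    Entity,
    EntityKind,
    ExprKind,
    Literal,
    SUPPORTED_AXIOM_TYPES,
    VerbalizationRecord,
)
from .morphology import indefinite_article

logger = logging.getLogger(__name__)

_XSD_NS = "http://www.w3.org/2001/XMLSchema#"


def _builtin_datatype(entity: Entity) -> bool:
    # XSD datatypes have no rdfs:label anywhere; their fragment ("integer")
    # is the canonical name, not an unresolved-import fallback.
    return entity.kind is EntityKind.DATATYPE and entity.iri.startswith(_XSD_NS)

__all__ = [
    "Style",
    "Position",
    "verbalize_axiom",
    "verbalize_class_expr",
    "realize_article",
    "verbalize_all",
    "SUPPORTED_AXIOM_TYPES",
]


class Style(str, Enum):
    EXPLICIT = "explicit"
    COMPACT = "compact"


class Position(str, Enum):
    SUBJECT = "subject"
    PREDICATE_NP = "predicate_np"
    RELATIVE_CLAUSE = "relative_clause"


def realize_article(noun_phrase_head: str) -> str:
    """Choose the indefinite article for a noun-phrase head word."""
    return indefinite_article(noun_phrase_head)


def _np(text: str) -> str:
    """Indefinite noun phrase from a bare nominal: 'week day' -> 'a week day'."""
    head = text.split()[0]
    return f"{realize_article(head)} {text}"


class _Realizer:
    """Stateful walk over one axiom, accumulating diagnostic flags."""

    def __init__(self, lexicon: Lexicon, style: Style):
        self.lex = lexicon
        self.style = style
        self.flags: set[str] = set()

    # -- lexical access -----------------------------------------------------

    def surface(self, entity: Entity) -> str:
        entry = self.lex.entry(entity)
        if entry.source is LexSource.IRI_FRAGMENT and not _builtin_datatype(entity):
            self.flags.add("unlabeled_entity")
        return entry.text

    def vp(self, prop: Entity) -> VerbPhrase:
        entry = self.lex.entry(prop)
        if entry.source is LexSource.IRI_FRAGMENT:
            self.flags.add("unlabeled_entity")
        from .lexicon import classify_property

        return classify_property(entry)

    # -- class expressions --------------------------------------------------

    def filler_phrase(self, filler: Union[ClassExpr, Entity, Literal]) -> str:
        if isinstance(filler, Literal):
            return filler.lexical
        if isinstance(filler, Entity):
            if filler.kind is EntityKind.DATATYPE:
                return _np(self.surface(filler) + " value")
            return self.surface(filler)  # named individual
        return self.expr(filler, Position.PREDICATE_NP)

    def verb_phrase(self, prop: Entity, filler) -> str:
        """Realize '<property> <filler>' as an English verb phrase.

        copular     "is about" + C        -> "is about a C"
        plain verb  "precedes" + C        -> "precedes a C"
        possessive  "has child" + C       -> "has a C as child"
        """
        phrase = self.vp(prop)
        obj = self.filler_phrase(filler)
        if phrase.form is PhraseForm.POSSESSIVE and phrase.complement:
            return f"{phrase.head} {obj} as {' '.join(phrase.complement)}"
        return f"{' '.join(phrase.tokens)} {obj}"

    def expr(self, expr: ClassExpr, position: Position) -> str:
        """Verbalize a class expression for the given syntactic position."""
        k = expr.kind
        if k is ExprKind.NAMED:
            text = self.surface(expr.entity)
            return text if position is Position.SUBJECT else _np(text)
        if k is ExprKind.INTERSECTION:
            return " and ".join(self.expr(c, position) for c in expr.children)
        if k is ExprKind.UNION:
            return " or ".join(self.expr(c, position) for c in expr.children)
        if k is ExprKind.COMPLEMENT:
            return "not " + self.expr(expr.children[0], Position.PREDICATE_NP)
        if k in (ExprKind.SOME_VALUES, ExprKind.HAS_VALUE):
            clause = self.verb_phrase(expr.prop, expr.filler)
        elif k is ExprKind.ALL_VALUES:
            phrase = self.vp(expr.prop)
            clause = f"{' '.join(phrase.tokens)} only {self.filler_phrase(expr.filler)}"
        else:  # unsupported constructor
            self.flags.add("generic_fallback")
            clause = expr.text
            return clause
        if position is Position.RELATIVE_CLAUSE:
            return clause
        return f"something that {clause}"

    def predicate(self, expr: ClassExpr) -> str:
        """Full predicate (including the verb) for 'every <C> <predicate>'."""
        if (
            self.style is Style.COMPACT
            and expr.kind in (ExprKind.SOME_VALUES, ExprKind.HAS_VALUE)
            and self.vp(expr.prop).form is PhraseForm.COPULAR
        ):
            # elide "is something that": the copular property supplies "is"
            return self.expr(expr, Position.RELATIVE_CLAUSE)
        return "is " + self.expr(expr, Position.PREDICATE_NP)

    def subject(self, expr: ClassExpr) -> str:
        if expr.kind is ExprKind.NAMED:
            return "every " + self.expr(expr, Position.SUBJECT)
        # general class inclusion with a complex left-hand side
        return "everything that is " + self.expr(expr, Position.PREDICATE_NP)


def verbalize_class_expr(
    expr: ClassExpr,
    position: Position | str = Position.PREDICATE_NP,
    lexicon: Optional[Lexicon] = None,
    style: Style | str = Style.EXPLICIT,
) -> str:
    """Verbalize one class expression as a phrase for the given position."""
    realizer = _Realizer(lexicon or Lexicon(), Style(style))
    return realizer.expr(expr, Position(position))


def _sentence(r: _Realizer, axiom: Axiom) -> str:
    t, ops = axiom.type, axiom.operands
    if t == "SubClassOf":
        return f"{r.subject(ops[0])} {r.predicate(ops[1])}"
    if t == "EquivalentClasses":
        return f"{r.subject(ops[0])} {r.predicate(ops[1])} and vice versa"
    if t == "DisjointClasses":
        pairs = [
            f"no {r.expr(a, Position.SUBJECT)} is {r.expr(b, Position.PREDICATE_NP)}"
            for i, a in enumerate(ops)
            for b in ops[i + 1 :]
        ]
        return " and ".join(pairs)
    if t == "ClassAssertion":
        return f"{r.surface(ops[1])} {r.predicate(ops[0])}"
    if t == "ObjectPropertyDomain":
        phrase = r.vp(ops[0])
        if phrase.form is PhraseForm.POSSESSIVE and phrase.complement:
            vp = f"{phrase.head} {_np(' '.join(phrase.complement))}"
        else:
            vp = f"{' '.join(phrase.tokens)} something"
        return f"everything that {vp} is {r.expr(ops[1], Position.PREDICATE_NP)}"
    if t == "ObjectPropertyRange":
        phrase = r.vp(ops[0])
        if phrase.form is PhraseForm.POSSESSIVE and phrase.complement:
            vp = f"{phrase.head} as {' '.join(phrase.complement)}"
        else:
            vp = " ".join(phrase.tokens)
        return f"everything that something {vp} is {r.expr(ops[1], Position.PREDICATE_NP)}"
    if t == "DataPropertyDomain":
        noun = " ".join(r.vp(ops[0]).noun)
        return f"everything that has {_np(noun)} is {r.expr(ops[1], Position.PREDICATE_NP)}"
    if t == "DataPropertyRange":
        noun = " ".join(r.vp(ops[0]).noun)
        return f"every {noun} is {_np(r.surface(ops[1]) + ' value')}"
    if t == "SymmetricObjectProperty":
        vp = " ".join(r.vp(ops[0]).tokens)
        return f"if X {vp} Y then Y {vp} X"
    if t == "FunctionalObjectProperty":
        phrase = r.vp(ops[0])
        if phrase.form is PhraseForm.POSSESSIVE and phrase.complement:
            return f"everything has at most one {' '.join(phrase.complement)}"
        return f"everything {' '.join(phrase.tokens)} at most one thing"
    if t == "FunctionalDataProperty":
        noun = " ".join(r.vp(ops[0]).noun)
        return f"everything has at most one {noun}"
    if t == "ObjectPropertyAssertion":
        vp = " ".join(r.vp(ops[0]).tokens)
        return f"{r.surface(ops[1])} {vp} {r.surface(ops[2])}"
    if t == "DataPropertyAssertion":
        noun = " ".join(r.vp(ops[0]).noun)
        return f"the {noun} of {r.surface(ops[1])} is {ops[2].lexical}"
    if t == "DifferentIndividuals":
        names = [r.surface(o) for o in ops]
        if len(names) == 2:
            listed = f"{names[0]} and {names[1]}"
        else:
            listed = ", ".join(names[:-1]) + f" and {names[-1]}"
        return f"{listed} are different"
    raise AssertionError(f"unhandled axiom type {t}")


def verbalize_axiom(
    axiom: Axiom,
    lexicon: Optional[Lexicon] = None,
    style: Style | str = Style.EXPLICIT,
    prefix_map: Optional[dict[str, str]] = None,
    name_policy: str = "curie",
) -> VerbalizationRecord:
    """Render one axiom as a :class:`VerbalizationRecord`.

    Never raises for well-formed axioms: an unsupported class-expression
    constructor in a template position yields a sentence with the Manchester
    text inlined and the ``generic_fallback`` flag set.
    """
    manchester = render_manchester(axiom, name_policy, prefix_map)
    realizer = _Realizer(lexicon or Lexicon(), Style(style))
    sentence = _sentence(realizer, axiom)
    sentence = " ".join(sentence.split())  # single line, no double spaces
    return VerbalizationRecord(
        axiom_type=axiom.type,
        manchester=manchester,
        sentence=sentence,
        flags=frozenset(realizer.flags),
    )


def verbalize_all(
    axset: AxiomSet,
    style: Style | str = Style.EXPLICIT,
    lexicon: Optional[Lexicon] = None,
    name_policy: str = "curie",
) -> list[VerbalizationRecord]:
    """Verbalize every axiom of a loaded ontology, in its deterministic order."""
    lex = lexicon or Lexicon()
    records = [
        verbalize_axiom(ax, lex, style, axset.prefix_map, name_policy)
        for ax in axset.axioms
    ]
    n_fallback = sum(1 for rec in records if "generic_fallback" in rec.flags)
    n_unlabeled = sum(1 for rec in records if "unlabeled_entity" in rec.flags)
    logger.info(
        "verbalized %d axioms (%d with unlabeled entities, %d generic fallbacks)",
        len(records), n_unlabeled, n_fallback,
    )
    return records
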