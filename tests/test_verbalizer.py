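"""Sentence templates, class-expression recursion, realization invariants."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from owlverbal import (
    Axiom,
    ClassExpr,
    Entity,
    EntityKind,
    Literal,
    SUPPORTED_AXIOM_TYPES,
    realize_article,
    verbalize_all,
    verbalize_axiom,
    verbalize_class_expr,
)
from owlverbal.manchester import parse_manchester, render_manchester
from owlverbal.verbalizer import Position, Style

GOLDEN = {
    "ICO:0000062 SubClassOf: ICO:0000073":
        "every human subject unable to give informed consent is a human subject",
    "ICO:0000171 SubClassOf: IAO:0000136 some ICO:0000064":
        "every answer option text entity is something that is about a study requiring informed consent",
    "TEO:0000048 SubClassOf: TEO:0000084":
        "every Saturday is a week day",
    "TEO:0000100 SubClassOf: IAO:0000032":
        "every duration measurement is an iao 0000032",
}


def test_golden_sentences_reproduce_byte_exactly(paper_axset):
    records = verbalize_all(paper_axset)
    got = {r.manchester: r.sentence for r in records}
    assert got == GOLDEN


def test_compact_style_elides_is_something_that(paper_axset):
    records = verbalize_all(paper_axset, style="compact")
    sentences = {r.sentence for r in records}
    assert (
        "every answer option text entity is about a study requiring informed consent"
        in sentences
    )


def test_unlabeled_entity_flagged(paper_axset):
    rec = next(
        r for r in verbalize_all(paper_axset) if "iao 0000032" in r.sentence
    )
    assert rec.flags == {"unlabeled_entity"}
    others = [r for r in verbalize_all(paper_axset) if r.manchester != rec.manchester]
    assert all(not r.flags for r in others)


def test_style_equivalence_only_copular_existentials_change(paper_axset):
    explicit = verbalize_all(paper_axset, style="explicit")
    compact = verbalize_all(paper_axset, style="compact")
    for e, c in zip(explicit, compact):
        if e.sentence == c.sentence:
            continue
        diff = Counter(e.sentence.split()) - Counter(c.sentence.split())
        assert diff == Counter({"is": 1, "something": 1, "that": 1})


# -- class-expression phrases -----------------------------------------------


def _cls(name: str, label: str | None = None) -> ClassExpr:
    return ClassExpr.named(Entity(f"http://x#{name}", EntityKind.CLASS, label))


def _prop(name: str, label: str) -> Entity:
    return Entity(f"http://x#{name}", EntityKind.OBJECT_PROPERTY, label)


def test_named_predicate_noun_phrase_gets_article():
    assert verbalize_class_expr(_cls("W", "week day"), Position.PREDICATE_NP) == "a week day"
    assert verbalize_class_expr(_cls("W", "week day"), Position.SUBJECT) == "week day"


def test_existential_predicate_uses_something_that():
    expr = ClassExpr.some(_prop("r", "is about"), _cls("S", "study requiring informed consent"))
    assert (
        verbalize_class_expr(expr, Position.PREDICATE_NP)
        == "something that is about a study requiring informed consent"
    )


def test_nested_existential_recursion():
    expr = ClassExpr.some(
        _prop("p", "precedes"),
        ClassExpr.some(_prop("q", "follows"), _cls("D", "meeting")),
    )
    assert (
        verbalize_class_expr(expr, Position.PREDICATE_NP)
        == "something that precedes something that follows a meeting"
    )


def test_boolean_and_complement_phrases():
    woman, parent = _cls("W", "woman"), _cls("P", "parent")
    assert (
        verbalize_class_expr(ClassExpr.intersection(woman, parent), Position.PREDICATE_NP)
        == "a woman and a parent"
    )
    assert (
        verbalize_class_expr(ClassExpr.union(woman, parent), Position.PREDICATE_NP)
        == "a woman or a parent"
    )
    assert (
        verbalize_class_expr(ClassExpr.complement(parent), Position.PREDICATE_NP)
        == "not a parent"
    )


def test_universal_restriction_phrase():
    expr = ClassExpr.only(_prop("h", "has pet"), _cls("D", "dog"))
    assert verbalize_class_expr(expr, Position.PREDICATE_NP) == "something that has pet only a dog"


@pytest.mark.parametrize(
    "head, article",
    [("iao", "an"), ("human", "a"), ("hour", "an"), ("answer", "an"),
     ("week", "a"), ("unique", "a"), ("integer", "an")],
)
def test_realize_article(head, article):
    assert realize_article(head) == article


# -- whole-ontology properties ----------------------------------------------


def test_every_supported_type_verbalizes_without_fallback(people_records):
    assert len(SUPPORTED_AXIOM_TYPES) == 14
    types_seen = {r.axiom_type for r in people_records}
    assert types_seen == set(SUPPORTED_AXIOM_TYPES)
    assert all("generic_fallback" not in r.flags for r in people_records)


def test_record_count_matches_axiom_count(people_axset, people_records):
    assert len(people_records) == len(people_axset)


def test_verbalize_all_is_deterministic(people_axset):
    assert verbalize_all(people_axset) == verbalize_all(people_axset)


def test_sentence_surface_invariants(people_records, paper_axset):
    records = list(people_records) + verbalize_all(paper_axset)
    for r in records:
        assert r.sentence
        assert "\n" not in r.sentence
        assert "  " not in r.sentence
        assert not r.sentence.endswith(".")


def test_unsupported_constructor_yields_flagged_generic_fallback():
    weird = ClassExpr.unsupported("hasPart min 2")
    axiom = Axiom("SubClassOf", (_cls("A", "assembly"), weird))
    rec = verbalize_axiom(axiom)
    assert "generic_fallback" in rec.flags
    assert "hasPart min 2" in rec.sentence


def test_data_property_assertion_template():
    age = Entity("http://x#hasAge", EntityKind.DATA_PROPERTY, "has age")
    bill = Entity("http://x#Bill", EntityKind.NAMED_INDIVIDUAL, "Bill")
    rec = verbalize_axiom(Axiom("DataPropertyAssertion", (age, bill, Literal("42", None))))
    assert rec.sentence == "the age of Bill is 42"


# -- property-based: random class expressions stay well-formed ---------------

_POOL_CLASSES = [_cls(f"C{i}", lbl) for i, lbl in enumerate(
    ["gene", "protein", "tissue sample", "organism", None]
)]
_POOL_PROPS = [
    _prop("p0", "is about"), _prop("p1", "has part"), _prop("p2", "regulates"),
]

_expr_strategy = st.recursive(
    st.sampled_from(_POOL_CLASSES),
    lambda children: st.one_of(
        st.tuples(children, children).map(lambda t: ClassExpr.intersection(*t)),
        st.tuples(children, children).map(lambda t: ClassExpr.union(*t)),
        children.map(ClassExpr.complement),
        st.tuples(st.sampled_from(_POOL_PROPS), children).map(
            lambda t: ClassExpr.some(*t)
        ),
        st.tuples(st.sampled_from(_POOL_PROPS), children).map(
            lambda t: ClassExpr.only(*t)
        ),
    ),
    max_leaves=6,
)


@settings(max_examples=120, derandomize=True, deadline=None)
@given(expr=_expr_strategy)
def test_random_expressions_verbalize_and_roundtrip(expr):
    axiom = Axiom("SubClassOf", (_cls("A", "assay"), expr))
    rec = verbalize_axiom(axiom)
    assert rec.sentence and "  " not in rec.sentence and not rec.sentence.endswith(".")
    entities = {e.iri: e for e in axiom.iter_entities()}
    assert parse_manchester(rec.manchester, entities) == axiom


def test_verbalization_record_item_ids_are_stable_and_typed(people_records):
    ids = [r.item_id for r in people_records]
    assert len(set(ids)) == len(ids)
    for r in people_records:
        assert r.item_id.startswith(r.axiom_type + "-")
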