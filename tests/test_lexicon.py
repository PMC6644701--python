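"""Lexicalization, property-phrase classification and lemmatization."""

from __future__ import annotations

import pytest

from owlverbal import classify_property, lemmatize_token, lexicalize
from owlverbal.lexicon import LexSource, PhraseForm, PhraseKind
from owlverbal.model import Entity, EntityKind
from owlverbal.morphology import pluralize_noun, third_person_singular

OBO = "http://purl.obolibrary.org/obo/"


@pytest.mark.parametrize(
    "entity, tokens, source",
    [
        (
            Entity(OBO + "IAO_0000032", EntityKind.CLASS),
            ("iao", "0000032"),
            LexSource.IRI_FRAGMENT,
        ),
        (
            Entity(OBO + "ICO_0000073", EntityKind.CLASS, "human subject"),
            ("human", "subject"),
            LexSource.LABEL,
        ),
        (
            Entity("http://example.org/x#HappyPerson", EntityKind.CLASS),
            ("happy", "person"),
            LexSource.IRI_FRAGMENT,
        ),
        (
            Entity("http://example.org/x#hasSpouse", EntityKind.OBJECT_PROPERTY),
            ("has", "spouse"),
            LexSource.IRI_FRAGMENT,
        ),
    ],
)
def test_lexicalize(entity, tokens, source):
    entry = lexicalize(entity)
    assert entry.surface == tokens
    assert entry.source is source


def test_label_case_is_preserved():
    entry = lexicalize(Entity("http://x#Sat", EntityKind.CLASS, "Saturday"))
    assert entry.surface == ("Saturday",)


def test_property_entries_are_verb_phrases():
    prop = Entity(OBO + "IAO_0000136", EntityKind.OBJECT_PROPERTY, "is about")
    assert lexicalize(prop).phrase_kind is PhraseKind.VERB_PHRASE


def test_fallback_injectivity_over_distinct_iris():
    iris = [OBO + f"IAO_{n:07d}" for n in range(20)] + [
        "http://example.org/x#AlphaBeta",
        "http://example.org/x#alpha_beta2",
    ]
    surfaces = {lexicalize(Entity(i, EntityKind.CLASS)).text for i in iris}
    assert len(surfaces) == len(iris)


@pytest.mark.parametrize(
    "label, form",
    [
        ("is about", PhraseForm.COPULAR),
        ("is married to", PhraseForm.COPULAR),
        ("has child", PhraseForm.POSSESSIVE),
        ("has part", PhraseForm.POSSESSIVE),
        ("precedes", PhraseForm.PLAIN_VERB),
        ("likes", PhraseForm.PLAIN_VERB),
        ("regulates", PhraseForm.PLAIN_VERB),
    ],
)
def test_classify_property_prefix_rules(label, form):
    prop = Entity("http://x#p", EntityKind.OBJECT_PROPERTY, label)
    assert classify_property(lexicalize(prop)).form is form


def test_classify_rejects_non_property_entries():
    entry = lexicalize(Entity("http://x#C", EntityKind.CLASS, "thing"))
    with pytest.raises(ValueError):
        classify_property(entry)


@pytest.mark.parametrize(
    "base, inflected",
    [
        ("precede", "precedes"), ("like", "likes"), ("regulate", "regulates"),
        ("be", "is"), ("have", "has"), ("do", "does"), ("go", "goes"),
        ("carry", "carries"), ("push", "pushes"), ("fix", "fixes"),
        ("catch", "catches"), ("buzz", "buzzes"), ("play", "plays"),
        ("occur", "occurs"), ("cause", "causes"), ("produce", "produces"),
        ("contain", "contains"), ("derive", "derives"), ("bind", "binds"),
        ("inhibit", "inhibits"), ("activate", "activates"), ("encode", "encodes"),
        ("express", "expresses"), ("modify", "modifies"), ("host", "hosts"),
    ],
)
def test_third_person_singular_inflection(base, inflected):
    assert third_person_singular(base) == inflected


@pytest.mark.parametrize(
    "token, lemma",
    [
        ("data", "data"),  # must never become "da"
        ("is", "be"),
        ("are", "be"),
        ("has", "have"),
        ("analysis", "analysis"),
        ("analyses", "analysis"),
        ("species", "species"),
        ("status", "status"),
        ("studies", "study"),
        ("children", "child"),
        ("viruses", "virus"),
        ("houses", "house"),
        ("boxes", "box"),
        ("measurement", "measurement"),
    ],
)
def test_lemmatize_token(token, lemma):
    assert lemmatize_token(token) == lemma


_REGULAR_NOUNS = [
    "cat", "dog", "gene", "protein", "sample", "ontology", "axiom", "label",
    "study", "property", "entity", "class", "subject", "consent", "document",
    "form", "event", "measurement", "duration", "interval", "relation",
    "concept", "term", "expert", "review", "rating", "score", "sentence",
    "statement", "phrase", "clause", "template", "pattern", "rule", "table",
    "sheet", "column", "row", "value", "number", "name", "person", "man",
    "woman", "parent", "mother", "father", "child", "driver", "pet", "week",
    "day", "hour", "minute", "second", "year", "month", "test", "result",
    "error", "warning", "flag", "file", "path", "folder", "graph", "node",
    "edge", "tree", "branch", "leaf", "root", "library", "module", "package",
    "function", "method", "object", "string", "integer", "float", "boolean",
    "list", "tuple", "record", "item", "group", "panel", "rater", "reviewer",
    "domain", "range", "union", "restriction", "assertion", "equivalence",
    "box", "church", "city", "country", "key",
]


def test_lemmatize_inverts_pluralize_for_regular_nouns():
    assert len(_REGULAR_NOUNS) >= 100
    failures = [w for w in _REGULAR_NOUNS if lemmatize_token(pluralize_noun(w)) != w]
    assert failures == []


def test_user_lexicon_overrides_automatic_entry(tmp_path):
    from owlverbal import Lexicon

    path = tmp_path / "lexicon.csv"
    path.write_text(
        "iri,surface,phrase_kind\n"
        f"{OBO}IAO_0000032,scalar measurement datum,noun_phrase\n"
    )
    lex = Lexicon.from_csv(path)
    entry = lex.entry(Entity(OBO + "IAO_0000032", EntityKind.CLASS))
    assert entry.text == "scalar measurement datum"


def test_no_suffix_stripping_nonwords():
    # a lemmatizer must map every regression word to itself, not to a stem
    for word in ("data", "analysis", "species", "status"):
        assert lemmatize_token(word) == word
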