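"""Lexicalization: turn ontology entities into words usable in sentences.

An entity with an ``rdfs:label`` is verbalized from the label tokens with
letter case preserved exactly (ontology authors' capitalization such as
"Saturday" is meaningful).  An entity without a label — typically a term
whose defining ontology was not imported — falls back to its IRI local
fragment, split on underscores and camelCase and lowercased, so that e.g.
``IAO_0000032`` surfaces as "iao 0000032" rather than vanishing.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

from .model import Entity, EntityKind
from .morphology import lemmatize

logger = logging.getLogger(__name__)

__all__ = [
    "LexicalEntry",
    "VerbPhrase",
    "PhraseForm",
    "Lexicon",
    "lexicalize",
    "classify_property",
    "lemmatize_token",
]


class LexSource(str, Enum):
    LABEL = "label"
    IRI_FRAGMENT = "iri_fragment"


class PhraseKind(str, Enum):
    NOUN_PHRASE = "noun_phrase"
    VERB_PHRASE = "verb_phrase"


@dataclass(frozen=True)
class LexicalEntry:
    entity_iri: str
    surface: tuple[str, ...]
    source: LexSource
    phrase_kind: PhraseKind
    flagged: bool = False  # True when even the IRI fragment was unusable

    @property
    def text(self) -> str:
        return " ".join(self.surface)


class PhraseForm(str, Enum):
    COPULAR = "copular"  # "is about", "is married to"
    POSSESSIVE = "possessive"  # "has child", "has age"
    PLAIN_VERB = "plain_verb"  # "precedes", "likes"


@dataclass(frozen=True)
class VerbPhrase:
    """Decomposition of a property label into a verb-phrase structure."""

    form: PhraseForm
    tokens: tuple[str, ...]

    @property
    def head(self) -> str:
        return self.tokens[0]

    @property
    def complement(self) -> tuple[str, ...]:
        """Tokens after the verb head ("child" in "has child")."""
        return self.tokens[1:]

    @property
    def noun(self) -> tuple[str, ...]:
        """Noun reading of a property label: "has age" -> ("age",)."""
        if self.form in (PhraseForm.POSSESSIVE, PhraseForm.COPULAR) and self.complement:
            return self.complement
        return self.tokens


_CAMEL_RE = re.compile(
    r"[A-Z]+(?=[A-Z][a-z])|[A-Z]?[a-z]+|[A-Z]+|[0-9]+"
)


def _split_fragment(fragment: str) -> list[str]:
    """Split an IRI local fragment on underscores, hyphens and camelCase."""
    tokens: list[str] = []
    for chunk in re.split(r"[_\-.]+", fragment):
        tokens.extend(m.group(0).lower() for m in _CAMEL_RE.finditer(chunk))
    return tokens


def lexicalize(entity: Entity) -> LexicalEntry:
    """Build the lexical entry for an entity.

    Label tokens keep their original case; fragment-derived tokens are
    lowercased (``IAO_0000032`` -> ``iao 0000032``).
    """
    phrase_kind = (
        PhraseKind.VERB_PHRASE
        if entity.kind in (EntityKind.OBJECT_PROPERTY, EntityKind.DATA_PROPERTY)
        else PhraseKind.NOUN_PHRASE
    )
    if entity.raw_label is not None:
        tokens = tuple(entity.raw_label.split())
        if tokens:
            return LexicalEntry(entity.iri, tokens, LexSource.LABEL, phrase_kind)
    fragment = entity.local_name
    tokens = tuple(_split_fragment(fragment))
    if tokens:
        return LexicalEntry(entity.iri, tokens, LexSource.IRI_FRAGMENT, phrase_kind)
    logger.warning("entity %s has no label and no usable IRI fragment", entity.iri)
    return LexicalEntry(
        entity.iri, (entity.iri,), LexSource.IRI_FRAGMENT, phrase_kind, flagged=True
    )


def classify_property(entry: LexicalEntry) -> VerbPhrase:
    """Classify a property label into a copular / possessive / plain verb phrase.

    Biomedical ontology property labels follow strong conventions — "is
    about", "has part", "precedes" — so a prefix rule is both adequate and
    deterministic.  Single-token labels classify as plain verbs.
    """
    if entry.phrase_kind is not PhraseKind.VERB_PHRASE:
        raise ValueError(f"{entry.entity_iri} is not a property lexical entry")
    tokens = entry.surface
    head = tokens[0].lower()
    if len(tokens) > 1 and head in ("is", "are"):
        return VerbPhrase(PhraseForm.COPULAR, tokens)
    if len(tokens) > 1 and head in ("has", "have"):
        return VerbPhrase(PhraseForm.POSSESSIVE, tokens)
    if head in ("has", "have"):
        return VerbPhrase(PhraseForm.POSSESSIVE, tokens)
    return VerbPhrase(PhraseForm.PLAIN_VERB, tokens)


def lemmatize_token(token: str) -> str:
    """Dictionary lemma of one token — lemmatization, never suffix stripping."""
    return lemmatize(token)


class Lexicon:
    """Lexicalization context: per-entity entries with optional user overrides.

    A user lexicon is a CSV ``iri,surface,phrase_kind`` whose rows replace
    the automatic lexicalization for the listed IRIs.
    """

    def __init__(self, overrides: Optional[dict[str, LexicalEntry]] = None) -> None:
        self._overrides = dict(overrides or {})
        self._cache: dict[str, LexicalEntry] = {}

    @classmethod
    def from_csv(cls, path: str | Path) -> "Lexicon":
        overrides: dict[str, LexicalEntry] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                kind = PhraseKind(row.get("phrase_kind") or "noun_phrase")
                overrides[row["iri"]] = LexicalEntry(
                    row["iri"], tuple(row["surface"].split()), LexSource.LABEL, kind
                )
        return cls(overrides)

    def entry(self, entity: Entity) -> LexicalEntry:
        if entity.iri in self._overrides:
            return self._overrides[entity.iri]
        cached = self._cache.get(entity.iri)
        if cached is None:
            cached = lexicalize(entity)
            self._cache[entity.iri] = cached
        return cached

    def verb_phrase(self, prop: Entity) -> VerbPhrase:
        return classify_property(self.entry(prop))
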