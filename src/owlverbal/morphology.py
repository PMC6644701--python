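"""Rule-based English morphology for surface realization.

Deliberately a *lemmatizer*, not a suffix-stripping stemmer: stemming is
known to mangle domain vocabulary ("data" -> "da", "analysis" -> "analysi"),
which is unacceptable in sentences shown to subject-matter experts.  The
rules here only map a word to another *word* (an entry in the irregular
tables or the result of a conservative suffix rule), and words already in
lemma form pass through unchanged.
"""

from __future__ import annotations

# Mass/invariant nouns and words whose surface form IS the lemma even though
# they end in -s or look plural.  Guards against over-stripping.
_INVARIANT = frozenset(
    {
        "data",
        "metadata",
        "species",
        "series",
        "information",
        "status",
        "corpus",
        "virus",
        "analysis",
        "diagnosis",
        "hypothesis",
        "basis",
        "axis",
        "news",
        "physics",
        "mathematics",
        "genetics",
        "ethics",
        "lens",
        "consensus",
        "apparatus",
        "bias",
        "gas",
        "atlas",
        "canvas",
        "iris",
        "thus",
        "plus",
        "bus",
        "process",  # ends in -ss anyway, listed for clarity
    }
)

_IRREGULAR_NOUNS = {
    "children": "child",
    "people": "person",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "geese": "goose",
    "analyses": "analysis",
    "diagnoses": "diagnosis",
    "hypotheses": "hypothesis",
    "theses": "thesis",
    "crises": "crisis",
    "bases": "basis",
    "axes": "axis",
    "indices": "index",
    "matrices": "matrix",
    "vertices": "vertex",
    "appendices": "appendix",
    "criteria": "criterion",
    "phenomena": "phenomenon",
    "genera": "genus",
    "corpora": "corpus",
    "loci": "locus",
    "nuclei": "nucleus",
    "stimuli": "stimulus",
    "fungi": "fungus",
    "bacteria": "bacterium",
    "media": "medium",
    "leaves": "leaf",
    "lives": "life",
    "knives": "knife",
    "wives": "wife",
    "wolves": "wolf",
    "halves": "half",
    "shelves": "shelf",
}

# Inflected verb forms -> lemma (the copula and common auxiliaries).
_IRREGULAR_VERBS = {
    "is": "be",
    "are": "be",
    "am": "be",
    "was": "be",
    "were": "be",
    "been": "be",
    "being": "be",
    "has": "have",
    "have": "have",
    "had": "have",
    "having": "have",
    "does": "do",
    "did": "do",
    "done": "do",
}

_VOWELS = "aeiou"


def lemmatize(token: str) -> str:
    """Return the dictionary lemma of a single alphabetic token.

    A word already in lemma form returns itself; in particular the regression
    set {data, analysis, species, status} is returned verbatim.
    """
    w = token.lower()
    if w in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[w]
    if w in _INVARIANT:
        return w
    if w in _IRREGULAR_NOUNS:
        return _IRREGULAR_NOUNS[w]
    if len(w) > 3 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 4 and w.endswith(("xes", "ches", "shes", "sses", "zzes")):
        return w[:-2]
    if len(w) > 4 and w.endswith("uses") and w[-5] not in _VOWELS:
        # viruses -> virus, statuses -> status; but houses -> (next rule) house
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


_PLURAL_IRREGULAR = {v: k for k, v in _IRREGULAR_NOUNS.items()}


def pluralize_noun(noun: str) -> str:
    """Pluralize an English noun (inverse of :func:`lemmatize` on nouns)."""
    w = noun.lower()
    if w in _INVARIANT:
        return noun
    if w in _PLURAL_IRREGULAR:
        return _PLURAL_IRREGULAR[w]
    if w.endswith(("s", "x", "z", "ch", "sh")):
        return noun + "es"
    if len(w) > 1 and w.endswith("y") and w[-2] not in _VOWELS:
        return noun[:-1] + "ies"
    return noun + "s"


_THIRD_SG_IRREGULAR = {"be": "is", "have": "has", "do": "does", "go": "goes"}


def third_person_singular(verb: str) -> str:
    """Inflect a base-form verb for a third-person-singular subject."""
    w = verb.lower()
    if w in _THIRD_SG_IRREGULAR:
        return _THIRD_SG_IRREGULAR[w]
    if w.endswith(("s", "x", "z", "ch", "sh", "o")):
        return verb + "es"
    if len(w) > 1 and w.endswith("y") and w[-2] not in _VOWELS:
        return verb[:-1] + "ies"
    return verb + "s"


# Consonant-letter words pronounced with an initial vowel (silent h ...).
_AN_EXCEPTIONS = frozenset(
    {"hour", "hourly", "honest", "honestly", "honor", "honour", "heir", "heiress", "herb"}
)
# Vowel-letter words pronounced with an initial consonant (/ju:/, /w/ ...).
_A_EXCEPTIONS = frozenset(
    {
        "one",
        "once",
        "user",
        "user-defined",
        "unique",
        "unit",
        "uniform",
        "union",
        "university",
        "universal",
        "universe",
        "unicorn",
        "useful",
        "usual",
        "usable",
        "utility",
        "ubiquitous",
        "european",
        "eulogy",
        "euro",
        "ewe",
        "uri",
        "url",
        "utensil",
    }
)


def indefinite_article(head: str) -> str:
    """Choose "a" or "an" for the head word of a noun phrase.

    Vowel-letter heuristic with pronunciation exception lists; this is what
    yields "an iao 0000032" but "a human subject" and "an hour".
    """
    w = head.lower()
    if w in _AN_EXCEPTIONS:
        return "an"
    if w in _A_EXCEPTIONS:
        return "a"
    return "an" if w[:1] in _VOWELS else "a"
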