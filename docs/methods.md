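# Methods

## Scope and model

`owlverbal` translates a fixed inventory of fourteen OWL2 axiom types into
single English sentences and provides the statistics of a three-scale
expert-review protocol. The translation is deliberately template-based and
deterministic: for ontology *verification* the goal is an unambiguous,
reproducible rendering of each axiom, not fluent prose. Document-level
generation (aggregation, pronouns, discourse planning) is out of scope, as
are axiom types outside the inventory (cardinality restrictions, property
chains, oneOf, hasSelf and datatype facets verbalize as flagged generic
fallbacks with the Manchester text inlined).

## Loading

RDF/XML and Turtle are parsed with `rdflib`; axioms are reconstructed from
the OWL-to-RDF mapping (restriction blank nodes, RDF lists,
`owl:AllDisjointClasses` / `owl:AllDifferent` frames). OWL/XML and OWL
functional syntax are read by small subset parsers written in this package;
all readers feed one intermediate form, so a given ontology loads
identically from every serialization. Axioms are ordered by (type name,
Manchester rendering) and symmetric n-ary axioms (EquivalentClasses,
DisjointClasses, DifferentIndividuals) are canonicalized by sorting named
operands first; repeated loads therefore yield byte-identical downstream
CSV regardless of dialect or statement order.

Imports are not auto-resolved. An entity whose defining ontology is not
merged into the file simply has no `rdfs:label`; nothing is fetched and no
label is invented. An opt-in `follow_imports` flag follows `owl:imports`
for local files only. When an entity carries several labels, the
lexicographically smallest English-tagged label wins (then the smallest
overall) — a deterministic choice where OWL imposes none; conflicts are
logged.

## Lexicalization

Labeled entities verbalize from their label tokens with letter case
preserved exactly (authors' capitalization, as in "Saturday", is
meaningful). Unlabeled entities fall back to the IRI local fragment split
on underscores, hyphens and camelCase and lowercased (`IAO_0000032` →
"iao 0000032"); built-in XSD datatypes use their fragment ("integer")
without being flagged, since that *is* their canonical name.

Property labels are classified by a prefix rule: labels starting "is"/"are"
are copular verb phrases, "has"/"have" possessive, anything else a plain
verb with the first token as head. Biomedical ontology property naming
conventions ("is about", "has part", "precedes") make this reliable, and it
avoids the nondeterminism of a POS tagger. How a multi-word label with an
embedded preposition ("is realized in") segments into verb and complement
is not further analyzed; the whole label is used as the verb phrase.

Token normalization uses a rule-based *lemmatizer* (irregular tables plus
conservative suffix rules), never a suffix-stripping stemmer: stemmers
produce non-words on domain vocabulary ("data" → "da"), which is
unacceptable in sentences shown to experts. The regression set
{data, analysis, species, status} maps to itself, and
`lemmatize(pluralize(w)) = w` holds on regular nouns.

## Sentence templates

With `C`/`D` class expressions, `R` a property, `a`,`b` individuals, `v` a
literal and `T` a datatype:

| Axiom | Template |
|---|---|
| SubClassOf(C, D) | every C is D′ |
| EquivalentClasses(C, D) | every C is D′ and vice versa |
| DisjointClasses(C₁…Cₙ) | no Cᵢ is a Cⱼ (all pairs, joined by "and") |
| ClassAssertion(C, a) | a is C′ |
| ObjectPropertyDomain(R, C) | everything that R something is a C |
| ObjectPropertyRange(R, C) | everything that something R is a C |
| DataPropertyDomain(R, C) | everything that has a R-noun is a C |
| DataPropertyRange(R, T) | every R-noun is a T value |
| SymmetricObjectProperty(R) | if X R Y then Y R X |
| FunctionalObjectProperty(R) | everything R at most one thing |
| FunctionalDataProperty(R) | everything has at most one R-noun |
| ObjectPropertyAssertion(R, a, b) | a R b |
| DataPropertyAssertion(R, a, v) | the R-noun of a is v |
| DifferentIndividuals(a…) | a, b and c are different |

D′ is the predicate form of D: a named class becomes an indefinite noun
phrase ("a week day", with a/an chosen by a vowel-letter heuristic plus
pronunciation exception lists — "an hour", "a unique identifier");
intersections join with "and", unions with "or", complements prefix "not";
an existential restriction becomes "something that <verb phrase>", and
nested restrictions recurse ("something that P something that Q a D").
Possessive properties realize their complement naturally: ∃hasChild.Person
reads "has a person as child", domain axioms read "everything that has a
child ...". R-noun strips the possessive/copular head ("has age" → "age").

Sentences carry no sentence-initial capital and no final period, and label
tokens are never re-inflected — both choices keep the rendering as close as
possible to the ontology's own vocabulary.

Two styles are offered. The default `explicit` style always introduces
restrictions with "is something that ...", which is precise but
stilted; the `compact` style elides the construction when the property is
itself copular ("every answer option text entity is about a study requiring
informed consent"). The styles differ in nothing else, a property the test
suite enforces. Range-axiom sentences ("everything that something is about
is a ...") are deliberately awkward-but-faithful; smoothing them is
possible future work but would trade fidelity for fluency.

Where a template for a type is not constrained by any canonical example
(EquivalentClasses, Disjoint, Functional, assertions), the simplest
declarative form was committed once for determinism; they are design
decisions, not reconstructions of any other tool's output.

## Manchester rendering and round-trip

The second CSV column renders each axiom in Manchester syntax (W3C
keywords; `and`/`or`/`not`/`some`/`only`/`value`). The default naming
policy is CURIEs — OBO-style IRIs abbreviate to their ID space
(`ICO:0000062`) and unknown namespaces fall back to `<full-iri>` — with a
label policy (quoted multi-word labels) for human-facing sheets. A subset
Manchester parser, written as an independent tokenizer + recursive-descent
grammar rather than by inverting the templates, re-parses every rendering;
structural equality of the round-trip is part of the test suite. It is not
a general-purpose Manchester reader.

## Rating protocol statistics

Ratings are long-form records (item, rater, clarity ∈ {1,2,3},
nl_fidelity ∈ {yes,no}, domain_fidelity ∈ {1,2,3}). Summaries compute:

* mean and **population** SD (ddof = 0) of per-item mean scores across
  raters — a group of identically-scored items reports σ = 0;
* percent "yes" over all fidelity votes;
* interrater agreement as the plain percentage of items with identical
  scores, averaged over rater pairs — no chance correction, matching how
  such panels conventionally report agreement;
* Spearman's ρ between per-item mean clarity and per-item mean domain
  fidelity, tie-corrected (scipy), p from the large-sample approximation.
  Mean pooling across raters is used because the protocol records, rather
  than adjudicates, disagreements; pooling is rater-symmetric. A constant
  score vector makes ρ undefined and it is reported as NaN with an explicit
  flag, never coerced to 0.

Irreconcilable disagreements remain as both raters' rows; the data model
has no adjudicated third value.

## Fixtures and the synthetic rating generator

The *worked-examples* ontology contains exactly the four canonical axioms
(including one whose superclass is referenced but neither declared nor
labeled). The *people* ontology is a family-domain teaching ontology with
13 classes, 8 properties and 9 individuals covering all fourteen axiom
types, with 11 SubClassOf and 4 ObjectPropertyDomain axioms — the published
per-type counts for an ontology of this kind. It is an emulation honoring
those published constraints, not a reconstruction of any distributed file
(whose content is unpublished; the source's "9 instances (90 total)" count
is internally unclear and the fixture uses 9 individuals). Both are
regenerated bit-identically from code; no data files ship with the package.

Synthetic ratings emulate a review panel: rater 1 draws clarity from
(0.80, 0.15, 0.05) over {1,2,3}, domain fidelity from (0.85, 0.10, 0.05)
and "yes" with probability 0.90 — the mostly-clear, mostly-faithful regime
observed for small well-curated ontologies; each further rater copies
rater 1 and independently switches each dimension to a *different* score
with the configured disagreement probability, so expected exact-match
agreement is exactly 1 − rate. The generator reproduces marginal score
distributions and independent disagreement; it does not model per-item
difficulty, rater bias or correlated errors, so passing statistics validate
the estimators, not the behavior of human panels.

The acceptance script simulates panels of 1000 items at per-dimension
disagreement rates (0.14, 0.09, 0.10), sizes at which the binomial 99%
confidence band is about ±3 percentage points; its Spearman check compares
the implementation against a brute-force sort-based ranking oracle at
1e-12.

## Known limitations

* Verb phrases are taken from labels as-is; no subject–verb agreement is
  computed beyond what labels already encode, and labels that flout the
  is/has conventions will classify as plain verbs.
* GCI axioms (complex left-hand side of SubClassOf) verbalize structurally
  ("everything that is ... is ...") but have no curated examples.
* The Manchester parser exists for round-trip verification only.
* Percent agreement is the only agreement statistic; kappa-style chance
  correction is intentionally not provided.
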