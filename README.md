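# owlverbal

Translate the logical axioms of an OWL2 ontology into plain English
sentences so that subject-matter experts — clinicians, biologists,
terminologists — can review an ontology's content without reading
description logic, and run the accompanying three-scale expert-rating
protocol over the result.

## The problem

Biomedical ontologies encode domain knowledge as description-logic axioms
such as

```
ICO:0000062 ⊑ ICO:0000073
ICO:0000171 ⊑ ∃ IAO:0000136.ICO:0000064
```

Verifying that these axioms faithfully represent the domain requires
experts who usually have no knowledge-engineering background. `owlverbal`
renders every axiom as one English sentence built from the ontology's own
`rdfs:label` annotations:

```
every human subject unable to give informed consent is a human subject
every answer option text entity is something that is about a study requiring informed consent
```

Fourteen axiom types are supported (SubClassOf, EquivalentClasses,
DisjointClasses, ClassAssertion, object/data property domain and range,
symmetric and functional property characteristics, object/data property
assertions, DifferentIndividuals), with recursive verbalization of class
expressions (intersection, union, complement, existential/universal
restrictions, has-value). Each output row also carries the axiom in OWL
Manchester syntax for traceability.

The rating harness implements a review protocol with three scales per
sentence — *Clarity* (1–3), *NL fidelity to axiom* (yes/no) and *axiom
fidelity to domain* (1–3) — and computes the summary statistics: per-group
means μ and standard deviations σ, percent "yes", pairwise exact-match
interrater agreement, and Spearman's ρ between clarity and domain fidelity
(tie-corrected, with ρ reported as undefined rather than 0 when a score
vector is constant).

## Worked example

```sh
owlverbal fixtures generate -d fixtures --seed 1
owlverbal verbalize fixtures/worked_examples.ttl -o sentences.csv
```

`sentences.csv` then contains (one row per axiom):

```
axiom_type,manchester,nl_sentence
SubClassOf,ICO:0000062 SubClassOf: ICO:0000073,every human subject unable to give informed consent is a human subject
SubClassOf,ICO:0000171 SubClassOf: IAO:0000136 some ICO:0000064,every answer option text entity is something that is about a study requiring informed consent
SubClassOf,TEO:0000048 SubClassOf: TEO:0000084,every Saturday is a week day
SubClassOf,TEO:0000100 SubClassOf: IAO:0000032,every duration measurement is an iao 0000032
```

The last sentence shows the unresolved-import behavior: `IAO:0000032` has
no label in the file, so its IRI fragment is used verbatim (and the row is
flagged). The third shows why expert review matters — the sentence is a
faithful rendering of an axiom that models Saturday as a week day.

With `--style compact` the existential sentence reads
`every answer option text entity is about a study requiring informed consent`.

Rating workflow:

```sh
owlverbal make-sheet fixtures/people.ttl --raters 2 -o sheet.csv
owlverbal evaluate fixtures/people_ratings.csv -o summary.csv
```

`summary.csv` reports, pooled and per axiom type: `n_items`,
`clarity_mean`, `clarity_sd`, `nl_fidelity_pct_yes`,
`domain_fidelity_mean`, `domain_fidelity_sd`, the three agreement
percentages, and `spearman_rho`/`spearman_p` (left empty when undefined).

Everything is also available as a library:

```python
from owlverbal import load_ontology, verbalize_all

axset = load_ontology("fixtures/people.ttl")
for record in verbalize_all(axset):
    print(record.axiom_type, "|", record.sentence)
```

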