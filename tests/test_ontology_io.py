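"""Loading OWL2 serializations into the axiom model."""

from __future__ import annotations

import pytest

from owlverbal import count_by_type, load_ontology
from owlverbal.fixtures import PEOPLE_SPEC
from owlverbal.model import EntityKind
from owlverbal.ontology_io import OntologyParseError

OBO = "http://purl.obolibrary.org/obo/"

MINIMAL_TTL = f"""\
@prefix obo: <{OBO}> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
obo:ICO_0000062 a owl:Class ;
    rdfs:label "human subject unable to give informed consent" ;
    rdfs:subClassOf obo:ICO_0000073 .
obo:ICO_0000073 a owl:Class ; rdfs:label "human subject" .
"""

FUNCTIONAL_DOC = """\
Prefix(ex:=<http://example.org/f#>)
Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
Ontology(<http://example.org/f>
Declaration(Class(ex:A)) Declaration(Class(ex:B)) Declaration(ObjectProperty(ex:r))
AnnotationAssertion(rdfs:label ex:A "alpha thing")
AnnotationAssertion(rdfs:label ex:B "beta thing"@en)
AnnotationAssertion(rdfs:label ex:r "relates to")
SubClassOf(ex:A ObjectSomeValuesFrom(ex:r ex:B))
DisjointClasses(ex:A ex:B)
)
"""

OWLXML_DOC = """\
<?xml version="1.0"?>
<Ontology xmlns="http://www.w3.org/2002/07/owl#" ontologyIRI="http://example.org/f">
  <Prefix name="ex" IRI="http://example.org/f#"/>
  <Prefix name="rdfs" IRI="http://www.w3.org/2000/01/rdf-schema#"/>
  <Declaration><Class IRI="http://example.org/f#A"/></Declaration>
  <Declaration><Class IRI="http://example.org/f#B"/></Declaration>
  <Declaration><ObjectProperty IRI="http://example.org/f#r"/></Declaration>
  <AnnotationAssertion>
    <AnnotationProperty abbreviatedIRI="rdfs:label"/>
    <IRI>http://example.org/f#A</IRI><Literal>alpha thing</Literal>
  </AnnotationAssertion>
  <AnnotationAssertion>
    <AnnotationProperty abbreviatedIRI="rdfs:label"/>
    <IRI>http://example.org/f#B</IRI><Literal xml:lang="en">beta thing</Literal>
  </AnnotationAssertion>
  <AnnotationAssertion>
    <AnnotationProperty abbreviatedIRI="rdfs:label"/>
    <IRI>http://example.org/f#r</IRI><Literal>relates to</Literal>
  </AnnotationAssertion>
  <SubClassOf>
    <Class IRI="http://example.org/f#A"/>
    <ObjectSomeValuesFrom>
      <ObjectProperty IRI="http://example.org/f#r"/>
      <Class IRI="http://example.org/f#B"/>
    </ObjectSomeValuesFrom>
  </SubClassOf>
  <DisjointClasses>
    <Class IRI="http://example.org/f#A"/>
    <Class IRI="http://example.org/f#B"/>
  </DisjointClasses>
</Ontology>
"""


def test_minimal_subclass_file_loads_one_axiom_two_labeled_classes(tmp_path):
    path = tmp_path / "minimal.ttl"
    path.write_text(MINIMAL_TTL)
    axset = load_ontology(path)
    assert len(axset) == 1
    assert axset.axioms[0].type == "SubClassOf"
    labeled = [e for e in axset.entities.values() if e.raw_label]
    assert len(labeled) == 2
    assert axset.entity(OBO + "ICO_0000073").raw_label == "human subject"


def test_empty_ontology_document_is_valid_and_empty(tmp_path):
    path = tmp_path / "empty.ttl"
    path.write_text("@prefix owl: <http://www.w3.org/2002/07/owl#> .\n")
    axset = load_ontology(path)
    assert len(axset) == 0
    assert axset.entities == {}
    assert count_by_type(axset) == {}


def test_turtle_and_rdfxml_serializations_load_identically(people_ttl, people_owl):
    a, b = load_ontology(people_ttl), load_ontology(people_owl)
    assert a.axioms == b.axioms
    assert a.entities == b.entities
    assert a.source_format == "turtle" and b.source_format == "rdfxml"


def test_functional_and_owlxml_readers_agree(tmp_path):
    f = tmp_path / "tiny.ofn"
    f.write_text(FUNCTIONAL_DOC)
    x = tmp_path / "tiny.owx"
    x.write_text(OWLXML_DOC)
    af, ax = load_ontology(f), load_ontology(x)
    assert af.source_format == "functional" and ax.source_format == "owlxml"
    assert af.axioms == ax.axioms
    assert af.entities == ax.entities
    assert count_by_type(af) == {"SubClassOf": 1, "DisjointClasses": 1}


def test_count_by_type_matches_fixture_composition(people_axset):
    counts = count_by_type(people_axset)
    assert counts == PEOPLE_SPEC.composition
    assert sum(counts.values()) == len(people_axset)
    assert counts["SubClassOf"] == 11
    assert counts["ObjectPropertyDomain"] == 4


def test_people_entity_census(people_axset):
    kinds = {}
    for e in people_axset.entities.values():
        kinds[e.kind] = kinds.get(e.kind, 0) + 1
    assert kinds[EntityKind.CLASS] == 13
    assert kinds[EntityKind.OBJECT_PROPERTY] + kinds[EntityKind.DATA_PROPERTY] == 8
    assert kinds[EntityKind.NAMED_INDIVIDUAL] == 9


def test_no_label_is_invented_for_unimported_entities(paper_axset):
    entity = paper_axset.entity(OBO + "IAO_0000032")
    assert entity.raw_label is None
    unlabeled = [e for e in paper_axset.entities.values() if e.raw_label is None]
    assert unlabeled == [entity]


def test_multiple_labels_choose_smallest_english(tmp_path):
    path = tmp_path / "labels.ttl"
    path.write_text(
        """@prefix ex: <http://example.org/x#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
ex:A a owl:Class ; rdfs:label "zebra"@en, "aardvark"@fr, "monkey"@en ;
     rdfs:subClassOf ex:B .
ex:B a owl:Class .
"""
    )
    axset = load_ontology(path)
    assert axset.entity("http://example.org/x#A").raw_label == "monkey"


def test_unsupported_axioms_are_counted_not_returned(tmp_path):
    path = tmp_path / "extra.ttl"
    path.write_text(
        """@prefix ex: <http://example.org/x#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
ex:p a owl:ObjectProperty, owl:TransitiveProperty ; rdfs:subPropertyOf ex:q .
ex:q a owl:ObjectProperty .
ex:A a owl:Class ; rdfs:subClassOf ex:B . ex:B a owl:Class .
"""
    )
    axset = load_ontology(path)
    assert count_by_type(axset) == {"SubClassOf": 1}
    assert axset.unsupported["TransitiveObjectProperty"] == 1
    assert axset.unsupported["SubPropertyOf"] == 1


def test_missing_file_raises_input_error_naming_path(tmp_path):
    missing = tmp_path / "nope.ttl"
    with pytest.raises(OntologyParseError, match="nope.ttl"):
        load_ontology(missing)


def test_unparseable_content_raises_parse_error(tmp_path):
    path = tmp_path / "broken.ttl"
    path.write_text("@prefix broken here ;;; not turtle at all <<<")
    with pytest.raises(OntologyParseError, match="turtle"):
        load_ontology(path)


def test_repeated_loads_are_identical(people_ttl):
    a, b = load_ontology(people_ttl), load_ontology(people_ttl)
    assert a.axioms == b.axioms and a.entities == b.entities
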