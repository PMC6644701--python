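"""Core data model: entities, class expressions, axioms, and axiom sets.

The model mirrors the OWL2 structural specification, restricted to the
fourteen axiom types this package verbalizes and the class-expression
constructors they use (named classes, intersection, union, complement,
existential/universal restrictions, has-value).  Anything outside that
inventory is carried as an *unsupported* node so that downstream code can
emit a flagged generic fallback instead of crashing.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Union


class EntityKind(str, Enum):
    CLASS = "class"
    OBJECT_PROPERTY = "object_property"
    DATA_PROPERTY = "data_property"
    NAMED_INDIVIDUAL = "named_individual"
    DATATYPE = "datatype"


@dataclass(frozen=True)
class Entity:
    """An IRI-identified ontology term.

    ``raw_label`` is the value of ``rdfs:label`` exactly as found in the
    loaded closure, or ``None`` when the defining ontology was not imported
    (which is what makes sentences like "an iao 0000032" appear downstream).
    """

    iri: str
    kind: EntityKind
    raw_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.iri:
            raise ValueError("Entity.iri must be non-empty")

    @property
    def local_name(self) -> str:
        """Fragment after the last '#' or '/' of the IRI ('' if none)."""
        for sep in ("#", "/"):
            if sep in self.iri:
                frag = self.iri.rsplit(sep, 1)[1]
                if frag:
                    return frag
        if ":" in self.iri:
            return self.iri.rsplit(":", 1)[1]
        return self.iri


@dataclass(frozen=True)
class Literal:
    """A data value: lexical form plus optional datatype IRI."""

    lexical: str
    datatype: Optional[str] = None


class ExprKind(str, Enum):
    NAMED = "named"
    INTERSECTION = "intersection"
    UNION = "union"
    COMPLEMENT = "complement"
    SOME_VALUES = "some_values"
    ALL_VALUES = "all_values"
    HAS_VALUE = "has_value"
    UNSUPPORTED = "unsupported"


Filler = Union["ClassExpr", Entity, Literal]


@dataclass(frozen=True)
class ClassExpr:
    """Recursive class expression tree.

    Invariants (enforced at construction):
      * ``named`` nodes carry exactly an entity, no children, no property;
      * ``some_values``/``all_values``/``has_value`` carry one property and
        one filler (a class expression, datatype entity, individual entity,
        or literal);
      * ``intersection``/``union`` carry >= 2 children;
      * ``complement`` carries exactly 1 child;
      * ``unsupported`` carries a textual description only.
    """

    kind: ExprKind
    entity: Optional[Entity] = None
    prop: Optional[Entity] = None
    filler: Optional[Filler] = None
    children: tuple["ClassExpr", ...] = ()
    text: str = ""  # only for UNSUPPORTED nodes

    def __post_init__(self) -> None:
        k = self.kind
        if k is ExprKind.NAMED:
            if self.entity is None or self.children or self.prop is not None:
                raise ValueError("named expression must hold exactly one entity")
        elif k in (ExprKind.SOME_VALUES, ExprKind.ALL_VALUES, ExprKind.HAS_VALUE):
            if self.prop is None or self.filler is None or self.children:
                raise ValueError(f"{k.value} requires one property and one filler")
        elif k in (ExprKind.INTERSECTION, ExprKind.UNION):
            if len(self.children) < 2:
                raise ValueError(f"{k.value} requires at least two operands")
        elif k is ExprKind.COMPLEMENT:
            if len(self.children) != 1:
                raise ValueError("complement requires exactly one operand")
        elif k is ExprKind.UNSUPPORTED:
            if not self.text:
                raise ValueError("unsupported expression requires descriptive text")

    # -- convenience constructors ------------------------------------------

    @staticmethod
    def named(entity: Entity) -> "ClassExpr":
        return ClassExpr(ExprKind.NAMED, entity=entity)

    @staticmethod
    def intersection(*children: "ClassExpr") -> "ClassExpr":
        return ClassExpr(ExprKind.INTERSECTION, children=tuple(children))

    @staticmethod
    def union(*children: "ClassExpr") -> "ClassExpr":
        return ClassExpr(ExprKind.UNION, children=tuple(children))

    @staticmethod
    def complement(child: "ClassExpr") -> "ClassExpr":
        return ClassExpr(ExprKind.COMPLEMENT, children=(child,))

    @staticmethod
    def some(prop: Entity, filler: Filler) -> "ClassExpr":
        return ClassExpr(ExprKind.SOME_VALUES, prop=prop, filler=filler)

    @staticmethod
    def only(prop: Entity, filler: Filler) -> "ClassExpr":
        return ClassExpr(ExprKind.ALL_VALUES, prop=prop, filler=filler)

    @staticmethod
    def has_value(prop: Entity, filler: Filler) -> "ClassExpr":
        return ClassExpr(ExprKind.HAS_VALUE, prop=prop, filler=filler)

    @staticmethod
    def unsupported(text: str) -> "ClassExpr":
        return ClassExpr(ExprKind.UNSUPPORTED, text=text)

    def iter_entities(self) -> Iterable[Entity]:
        if self.entity is not None:
            yield self.entity
        if self.prop is not None:
            yield self.prop
        if isinstance(self.filler, Entity):
            yield self.filler
        elif isinstance(self.filler, ClassExpr):
            yield from self.filler.iter_entities()
        for child in self.children:
            yield from child.iter_entities()

    @property
    def is_supported(self) -> bool:
        if self.kind is ExprKind.UNSUPPORTED:
            return False
        if isinstance(self.filler, ClassExpr) and not self.filler.is_supported:
            return False
        return all(c.is_supported for c in self.children)


#: The axiom-type inventory this package translates into English.
SUPPORTED_AXIOM_TYPES: tuple[str, ...] = (
    "SubClassOf",
    "EquivalentClasses",
    "DisjointClasses",
    "ClassAssertion",
    "ObjectPropertyDomain",
    "ObjectPropertyRange",
    "DataPropertyDomain",
    "DataPropertyRange",
    "SymmetricObjectProperty",
    "FunctionalObjectProperty",
    "FunctionalDataProperty",
    "ObjectPropertyAssertion",
    "DataPropertyAssertion",
    "DifferentIndividuals",
)

Operand = Union[ClassExpr, Entity, Literal]

# expected operand shapes, used for construction-time validation
_AXIOM_SHAPES: dict[str, tuple] = {
    "SubClassOf": (ClassExpr, ClassExpr),
    "EquivalentClasses": (ClassExpr, ClassExpr),
    "DisjointClasses": None,  # n >= 2 class expressions
    "ClassAssertion": (ClassExpr, Entity),
    "ObjectPropertyDomain": (Entity, ClassExpr),
    "ObjectPropertyRange": (Entity, ClassExpr),
    "DataPropertyDomain": (Entity, ClassExpr),
    "DataPropertyRange": (Entity, Entity),
    "SymmetricObjectProperty": (Entity,),
    "FunctionalObjectProperty": (Entity,),
    "FunctionalDataProperty": (Entity,),
    "ObjectPropertyAssertion": (Entity, Entity, Entity),
    "DataPropertyAssertion": (Entity, Entity, Literal),
    "DifferentIndividuals": None,  # n >= 2 individuals
}


@dataclass(frozen=True)
class Axiom:
    """A tagged union over the fourteen supported axiom types."""

    type: str
    operands: tuple[Operand, ...]

    def __post_init__(self) -> None:
        if self.type not in _AXIOM_SHAPES:
            raise ValueError(f"unsupported axiom type: {self.type!r}")
        shape = _AXIOM_SHAPES[self.type]
        if shape is None:
            if len(self.operands) < 2:
                raise ValueError(f"{self.type} requires at least two operands")
            want = ClassExpr if self.type == "DisjointClasses" else Entity
            if not all(isinstance(op, want) for op in self.operands):
                raise ValueError(f"{self.type} operands must all be {want.__name__}")
        else:
            if len(self.operands) != len(shape):
                raise ValueError(
                    f"{self.type} expects {len(shape)} operands, got {len(self.operands)}"
                )
            for op, want in zip(self.operands, shape):
                if not isinstance(op, want):
                    raise ValueError(
                        f"{self.type} operand {op!r} is not a {want.__name__}"
                    )

    def iter_entities(self) -> Iterable[Entity]:
        for op in self.operands:
            if isinstance(op, Entity):
                yield op
            elif isinstance(op, ClassExpr):
                yield from op.iter_entities()


@dataclass
class AxiomSet:
    """A loaded ontology: supported axioms plus an entity index.

    ``axioms`` are kept in a deterministic order (axiom type name, then
    Manchester rendering) so repeated loads of the same file — in any
    serialization — produce byte-identical downstream output.
    """

    axioms: tuple[Axiom, ...]
    entities: dict[str, Entity]
    source_format: str = "rdfxml"
    prefix_map: dict[str, str] = field(default_factory=dict)
    unsupported: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.axioms)

    def entity(self, iri: str) -> Entity:
        return self.entities[iri]


@dataclass(frozen=True)
class VerbalizationRecord:
    """One output row: axiom type, Manchester rendering, English sentence."""

    axiom_type: str
    manchester: str
    sentence: str
    flags: frozenset[str] = frozenset()

    @property
    def item_id(self) -> str:
        """Stable identifier: type name + short digest of the Manchester text.

        The type-name prefix lets rating tools recover the axiom type from an
        id alone (rating CSVs carry only item ids).
        """
        digest = hashlib.sha1(self.manchester.encode("utf-8")).hexdigest()[:10]
        return f"{self.axiom_type}-{digest}"


def axiom_type_of_item_id(item_id: str) -> str:
    """Recover the axiom-type name embedded in a ``VerbalizationRecord.item_id``."""
    head, _, _ = item_id.rpartition("-")
    return head if head else item_id
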