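"""Knowledge-base store: concept types, entities, facts, RDF export.

The knowledge base is symptom-centric: ``Symptom`` sits at the middle of the
schema and links to ``Disease``, ``Medicine``, ``Department`` and
``Examination`` through a small, closed property vocabulary.  Symptoms and
medicines are each subdivided into a TCM and a Western-medicine subtype; an
entity may carry both subtypes at once (e.g. a symptom listed by both a TCM
department and a neurology department).

Facts are (subject, predicate, object) triples with per-source provenance;
objects are either entity references or literals.  Predicates outside the
declared vocabulary are rejected at add time: the store guarantees that every
relation it holds has a declared meaning.
"""

from __future__ import annotations

import enum
import hashlib
import json
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import DCTERMS

__all__ = [
    "ConceptType",
    "Entity",
    "Fact",
    "KnowledgeBase",
    "PropertySpec",
    "DuplicateIdError",
    "SchemaError",
    "mint_entity_id",
    "majority_vote",
    "correctness_ratio",
    "default_schema",
]


class SchemaError(ValueError):
    """An operation would violate a store invariant."""


class DuplicateIdError(SchemaError):
    """An entity id is already present in the store."""


class ConceptType(str, enum.Enum):
    SYMPTOM = "Symptom"
    TCM_SYMPTOM = "TCMSymptom"
    WESTERN_SYMPTOM = "WesternSymptom"
    DISEASE = "Disease"
    MEDICINE = "Medicine"
    TCM_MEDICINE = "TCMMedicine"
    WESTERN_MEDICINE = "WesternMedicine"
    DEPARTMENT = "Department"
    EXAMINATION = "Examination"
    OTHER = "Other"

    @property
    def coarse(self) -> "ConceptType":
        return _IMPLIES.get(self, self)


#: Subtype -> implied coarse type.
_IMPLIES: dict[ConceptType, ConceptType] = {
    ConceptType.TCM_SYMPTOM: ConceptType.SYMPTOM,
    ConceptType.WESTERN_SYMPTOM: ConceptType.SYMPTOM,
    ConceptType.TCM_MEDICINE: ConceptType.MEDICINE,
    ConceptType.WESTERN_MEDICINE: ConceptType.MEDICINE,
}

COARSE_TYPES: tuple[ConceptType, ...] = (
    ConceptType.SYMPTOM,
    ConceptType.DISEASE,
    ConceptType.MEDICINE,
    ConceptType.DEPARTMENT,
    ConceptType.EXAMINATION,
    ConceptType.OTHER,
)


def close_types(types: Iterable[ConceptType]) -> frozenset[ConceptType]:
    """Close a type set under subtype->coarse implication."""
    out = set(types)
    for t in list(out):
        if t in _IMPLIES:
            out.add(_IMPLIES[t])
    return frozenset(out)


def coarse_types(types: Iterable[ConceptType]) -> frozenset[ConceptType]:
    return frozenset(t.coarse for t in types)


@dataclass
class Entity:
    """A named medical concept with type labels, provenance and attributes.

    ``attributes`` is a multimap from attribute name (already mapped to the
    schema vocabulary, or raw for quarantined attributes) to literal values.
    """

    id: str
    name: str
    types: set[ConceptType] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("entity name must be non-empty")
        self.types = set(close_types(self.types))

    def add_attribute(self, name: str, value: str) -> None:
        vals = self.attributes.setdefault(name, [])
        if value not in vals:
            vals.append(value)

    def same_as(self, other: "Entity") -> bool:
        return (
            self.id == other.id
            and self.name == other.name
            and self.types == other.types
            and self.sources == other.sources
            and {k: sorted(v) for k, v in self.attributes.items()}
            == {k: sorted(v) for k, v in other.attributes.items()}
        )


@dataclass(frozen=True)
class Fact:
    """A provenance-carrying triple.

    ``object_is_entity`` distinguishes entity references from literals.
    """

    subject: str
    predicate: str
    object: str
    source: str
    object_is_entity: bool = False

    @property
    def key(self) -> tuple[str, str, str, str, bool]:
        return (self.subject, self.predicate, self.object, self.source,
                self.object_is_entity)


@dataclass(frozen=True)
class PropertySpec:
    """A declared property: its name, whether its range is an entity, and
    (optionally) the coarse concept types it may connect."""

    name: str
    entity_valued: bool
    domain: frozenset[ConceptType] | None = None
    range: frozenset[ConceptType] | None = None
    symmetric: bool = False


def default_schema() -> dict[str, PropertySpec]:
    """The symptom-centric property vocabulary."""
    C = ConceptType
    fs = frozenset
    specs = [
        PropertySpec("relevant_disease", True, None, fs({C.DISEASE})),
        PropertySpec("relevant_department", True, None, fs({C.DEPARTMENT})),
        PropertySpec("relevant_examination", True, None, fs({C.EXAMINATION})),
        PropertySpec("relevant_medicine", True, None, fs({C.MEDICINE})),
        PropertySpec("relevant_symptom", True, None, fs({C.SYMPTOM})),
        PropertySpec("symptom_related_symptom", True, fs({C.SYMPTOM}),
                     fs({C.SYMPTOM})),
        PropertySpec("sameAs", True, symmetric=True),
        PropertySpec("exact_match", False),  # cross-terminology link (CUI)
        PropertySpec("location", False),
        PropertySpec("specification", False),
        PropertySpec("description", False),
    ]
    return {p.name: p for p in specs}


def mint_entity_id(source: str, name: str) -> str:
    """Deterministic entity id from (source, name).

    Chinese names are not safe IRI local parts everywhere, so IRIs use this
    stable hash and carry the name as an ``rdfs:label``.
    """
    h = hashlib.sha1(f"{source}\x00{name}".encode("utf-8")).hexdigest()
    return h[:16]


# ---------------------------------------------------------------------------
# The store
# ---------------------------------------------------------------------------

BASE = "http://symptomkb.example.org/"
ENT = Namespace(BASE + "entity/")
ONT = Namespace(BASE + "ontology#")
ATTR = Namespace(BASE + "attribute/")
FACT = Namespace(BASE + "fact/")

_RDF_FORMATS = {"turtle": "turtle", "ntriples": "nt"}


class KnowledgeBase:
    """In-memory KB with referential integrity and a closed vocabulary."""

    def __init__(self, schema: Mapping[str, PropertySpec] | None = None):
        self.schema: dict[str, PropertySpec] = dict(schema or default_schema())
        self.entities: dict[str, Entity] = {}
        self.facts: set[Fact] = set()

    # -- mutation -----------------------------------------------------------

    def add_entity(self, entity: Entity) -> Entity:
        if not entity.name:
            raise SchemaError("entity name must be non-empty")
        if entity.id in self.entities:
            raise DuplicateIdError(
                f"entity id {entity.id!r} already present; "
                "merging duplicates is the fusion step's job"
            )
        self.entities[entity.id] = entity
        return entity

    def get_or_add(self, entity: Entity) -> Entity:
        """Return the stored entity for this id, adding it if new."""
        existing = self.entities.get(entity.id)
        if existing is not None:
            existing.types |= close_types(entity.types)
            existing.sources |= entity.sources
            for k, vals in entity.attributes.items():
                for v in vals:
                    existing.add_attribute(k, v)
            return existing
        return self.add_entity(entity)

    def add_fact(self, fact: Fact) -> Fact:
        spec = self.schema.get(fact.predicate)
        if spec is None:
            raise SchemaError(
                f"predicate {fact.predicate!r} is not in the declared schema"
            )
        if fact.subject not in self.entities:
            raise SchemaError(f"fact subject {fact.subject!r} unresolved")
        if fact.object_is_entity and fact.object not in self.entities:
            raise SchemaError(f"fact object {fact.object!r} unresolved")
        if fact.object_is_entity != spec.entity_valued:
            raise SchemaError(
                f"predicate {fact.predicate!r} expects "
                f"{'entity' if spec.entity_valued else 'literal'} objects"
            )
        self.facts.add(fact)
        return fact

    # -- queries ------------------------------------------------------------

    def entities_of_type(self, ctype: ConceptType) -> list[Entity]:
        return [e for e in self.entities.values() if ctype in e.types]

    def compute_statistics(self) -> dict:
        """Entity counts per type, fact counts per predicate, and the
        per-source contribution table.

        Multi-type entities count once per carried type; the distinct total
        is the store size, so per-type counts may exceed it.
        """
        type_counts = {t.value: 0 for t in ConceptType}
        source_counts: dict[str, int] = {}
        for e in self.entities.values():
            for t in e.types:
                type_counts[t.value] += 1
            for s in sorted(e.sources):
                source_counts[s] = source_counts.get(s, 0) + 1
        pred_counts: dict[str, int] = {}
        for f in self.facts:
            pred_counts[f.predicate] = pred_counts.get(f.predicate, 0) + 1
        return {
            "distinct_entities": len(self.entities),
            "total_facts": len(self.facts),
            "entity_type_counts": type_counts,
            "fact_predicate_counts": dict(sorted(pred_counts.items())),
            "source_entity_counts": dict(sorted(source_counts.items())),
        }

    def sample_facts(self, n: int, seed: int) -> list[Fact]:
        """Simple random sample of facts without replacement.

        Deterministic for a fixed (store contents, n, seed).
        """
        population = sorted(self.facts, key=lambda f: f.key)
        if n > len(population):
            raise ValueError(
                f"sample size {n} exceeds fact population {len(population)}"
            )
        if n < 0:
            raise ValueError("sample size must be non-negative")
        return random.Random(seed).sample(population, n)

    # -- equality -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        if set(self.entities) != set(other.entities):
            return False
        if any(not self.entities[i].same_as(other.entities[i])
               for i in self.entities):
            return False
        return self.facts == other.facts

    # -- RDF ---------------------------------------------------------------

    def to_rdf_graph(self) -> Graph:
        g = Graph()
        g.bind("skb", ONT)
        g.bind("skbe", ENT)
        g.bind("skba", ATTR)
        g.bind("dcterms", DCTERMS)
        for e in self.entities.values():
            iri = ENT[e.id]
            g.add((iri, RDFS.label, Literal(e.name, lang="zh")))
            for t in sorted(e.types, key=lambda t: t.value):
                g.add((iri, RDF.type, ONT[t.value]))
            for s in sorted(e.sources):
                g.add((iri, DCTERMS.source, Literal(s)))
            for aname in sorted(e.attributes):
                for v in e.attributes[aname]:
                    g.add((iri, ATTR[_iri_quote(aname)], Literal(v)))
        for f in sorted(self.facts, key=lambda f: f.key):
            subj = ENT[f.subject]
            pred = ONT[f.predicate]
            obj = ENT[f.object] if f.object_is_entity else Literal(f.object)
            g.add((subj, pred, obj))
            # Reified statement node carrying per-fact provenance.
            node = FACT[hashlib.sha1(
                "\x00".join(map(str, f.key)).encode("utf-8")).hexdigest()[:16]]
            g.add((node, RDF.type, RDF.Statement))
            g.add((node, RDF.subject, subj))
            g.add((node, RDF.predicate, pred))
            g.add((node, RDF.object, obj))
            g.add((node, DCTERMS.source, Literal(f.source)))
        return g

    def serialize_rdf(self, dialect: str = "turtle") -> bytes:
        if dialect not in _RDF_FORMATS:
            raise ValueError(f"unknown RDF dialect {dialect!r}")
        return self.to_rdf_graph().serialize(
            format=_RDF_FORMATS[dialect], encoding="utf-8")

    @classmethod
    def parse_rdf(cls, data: bytes | str, dialect: str = "turtle",
                  schema: Mapping[str, PropertySpec] | None = None,
                  ) -> "KnowledgeBase":
        if dialect not in _RDF_FORMATS:
            raise ValueError(f"unknown RDF dialect {dialect!r}")
        g = Graph()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        g.parse(data=data, format=_RDF_FORMATS[dialect])
        kb = cls(schema=schema)
        ent_prefix = str(ENT)
        ont_prefix = str(ONT)
        attr_prefix = str(ATTR)
        # entities
        for s, p, o in g:
            if not str(s).startswith(ent_prefix):
                continue
            eid = str(s)[len(ent_prefix):]
            ent = kb.entities.get(eid)
            if ent is None:
                ent = Entity(id=eid, name="\x00pending")
                kb.entities[eid] = ent
            if p == RDFS.label:
                ent.name = str(o)
            elif p == RDF.type and str(o).startswith(ont_prefix):
                ent.types.add(ConceptType(str(o)[len(ont_prefix):]))
            elif p == DCTERMS.source:
                ent.sources.add(str(o))
            elif str(p).startswith(attr_prefix):
                ent.add_attribute(_iri_unquote(str(p)[len(attr_prefix):]),
                                  str(o))
        for ent in kb.entities.values():
            ent.attributes = {k: sorted(v) for k, v in ent.attributes.items()}
            if ent.name == "\x00pending":
                raise SchemaError(f"entity {ent.id} has no rdfs:label")
        # facts come from the reified provenance statements
        for node in set(g.subjects(RDF.type, RDF.Statement)):
            subj = str(next(g.objects(node, RDF.subject)))
            pred = str(next(g.objects(node, RDF.predicate)))
            obj = next(g.objects(node, RDF.object))
            source = str(next(g.objects(node, DCTERMS.source)))
            is_ent = isinstance(obj, URIRef) and str(obj).startswith(ent_prefix)
            kb.add_fact(Fact(
                subject=subj[len(ent_prefix):],
                predicate=pred[len(ont_prefix):],
                object=str(obj)[len(ent_prefix):] if is_ent else str(obj),
                source=source,
                object_is_entity=is_ent,
            ))
        return kb

    # -- JSON persistence (CLI chaining) ------------------------------------

    def to_json(self) -> str:
        doc = {
            "entities": [
                {
                    "id": e.id,
                    "name": e.name,
                    "types": sorted(t.value for t in e.types),
                    "sources": sorted(e.sources),
                    "attributes": {k: list(v)
                                   for k, v in sorted(e.attributes.items())},
                }
                for e in sorted(self.entities.values(), key=lambda e: e.id)
            ],
            "facts": [
                {
                    "subject": f.subject, "predicate": f.predicate,
                    "object": f.object, "source": f.source,
                    "object_is_entity": f.object_is_entity,
                }
                for f in sorted(self.facts, key=lambda f: f.key)
            ],
        }
        return json.dumps(doc, ensure_ascii=False, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str,
                  schema: Mapping[str, PropertySpec] | None = None,
                  ) -> "KnowledgeBase":
        doc = json.loads(text)
        kb = cls(schema=schema)
        for ed in doc["entities"]:
            kb.add_entity(Entity(
                id=ed["id"], name=ed["name"],
                types={ConceptType(t) for t in ed["types"]},
                sources=set(ed["sources"]),
                attributes={k: list(v) for k, v in ed["attributes"].items()},
            ))
        for fd in doc["facts"]:
            kb.add_fact(Fact(**fd))
        return kb


def _iri_quote(name: str) -> str:
    from urllib.parse import quote
    return quote(name, safe="")


def _iri_unquote(name: str) -> str:
    from urllib.parse import unquote
    return unquote(name)


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def majority_vote(judgments: list[str]) -> str:
    """Aggregate per-judge labels (``correct``/``incorrect``) into a verdict.

    The strictly most frequent label wins.  An even panel can tie; ties
    resolve to ``incorrect``, the conservative choice for correctness-ratio
    estimation.  (A seven-judge panel, being odd, never ties.)
    """
    if not judgments:
        raise ValueError("empty judgment list")
    bad = set(judgments) - {"correct", "incorrect"}
    if bad:
        raise ValueError(f"unknown judgment labels: {sorted(bad)}")
    n_correct = judgments.count("correct")
    n_incorrect = len(judgments) - n_correct
    return "correct" if n_correct > n_incorrect else "incorrect"


def correctness_ratio(judgment_lists: Iterable[list[str]]) -> float:
    """Fraction of sampled facts whose vote-aggregated verdict is correct."""
    verdicts = [majority_vote(j) for j in judgment_lists]
    if not verdicts:
        raise ValueError("no judgments supplied")
    return verdicts.count("correct") / len(verdicts)
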