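"""Data fusion: type alignment, duplicate-entity mapping, attribute mapping.

Duplicate detection combines two signals.  *Commonness* is a name-string
similarity,

    StringSimilarity(a, b) = |LCS(a, b)| / max(|a|, |b|)

computed at character level over Unicode code points (Chinese medical names
are short and unsegmented).  *Relatedness* is the fraction of attributes
shared by the two entities whose values are themselves similar under the
same string measure.  A pair is mapped when the product
commonness x relatedness exceeds a threshold; clusters are the transitive
closure of mapped pairs, and each cluster merges into one entity whose
canonical name comes from the highest-priority source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .schema import (
    ConceptType,
    Entity,
    Fact,
    KnowledgeBase,
    close_types,
    coarse_types,
)

__all__ = [
    "SourcePriority",
    "MappingScore",
    "AttributeMappingRule",
    "MergeAudit",
    "lcs_length",
    "string_similarity",
    "relatedness",
    "align_type",
    "map_entities",
    "fuse_kb",
    "merge_count_sweep",
    "map_attribute",
    "sort_rules_by_specificity",
]

DEFAULT_PRODUCT_THRESHOLD = 0.5
DEFAULT_VALUE_SIM_THRESHOLD = 0.85


@dataclass(frozen=True)
class SourcePriority:
    """Ordered source identifiers, highest priority first (the original
    ordering criterion was site traffic rank)."""

    order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("duplicate sources in priority list")

    def rank(self, source: str) -> int:
        try:
            return self.order.index(source)
        except ValueError:
            return len(self.order)  # unknown sources rank last

    def best_rank(self, sources: Iterable[str]) -> int:
        ranks = [self.rank(s) for s in sources]
        return min(ranks) if ranks else len(self.order)


@dataclass(frozen=True)
class MappingScore:
    commonness: float
    relatedness: float

    @property
    def product(self) -> float:
        return self.commonness * self.relatedness


@dataclass(frozen=True)
class MergeAudit:
    """One pairwise comparison: the two scores, their product, the verdict,
    and whether the pair shared no attributes at all (manual-review flag)."""

    entity_a: str
    entity_b: str
    commonness: float
    relatedness: float
    product: float
    merged: bool
    no_shared_attributes: bool


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence, per Unicode code point."""
    if not a or not b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur.append(prev[j - 1] + 1)
            else:
                cur.append(max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def string_similarity(a: str, b: str) -> float:
    """LCS length over the longer string's length; 1 iff the strings match.

    Undefined (and an error) when both strings are empty — entity names are
    required to be non-empty anyway.
    """
    if not a and not b:
        raise ValueError("string similarity of two empty strings is undefined")
    return lcs_length(a, b) / max(len(a), len(b))


@dataclass(frozen=True)
class RelatednessResult:
    value: float
    shared_attributes: int
    similar_attributes: int
    no_shared_attributes: bool


def relatedness(a: Entity, b: Entity,
                value_sim_threshold: float = DEFAULT_VALUE_SIM_THRESHOLD,
                ) -> RelatednessResult:
    """Fraction of shared attributes whose values are similar.

    An attribute shared by both entities counts as *similar* when any pair
    of its values across the two entities reaches ``value_sim_threshold``
    under the LCS string similarity.  Entities sharing no attributes get
    relatedness 0 with a flag (name evidence alone never merges).
    """
    if coarse_types(a.types) != coarse_types(b.types):
        raise ValueError(
            f"relatedness requires identically typed entities "
            f"({a.name!r} vs {b.name!r})"
        )
    shared = sorted(set(a.attributes) & set(b.attributes))
    if not shared:
        return RelatednessResult(0.0, 0, 0, True)
    similar = 0
    for attr in shared:
        pairs = ((va, vb) for va in a.attributes[attr]
                 for vb in b.attributes[attr])
        if any(va == vb or (va or vb) and
               string_similarity(va, vb) >= value_sim_threshold
               for va, vb in pairs):
            similar += 1
    return RelatednessResult(similar / len(shared), len(shared), similar, False)


def align_type(votes: Sequence[tuple[ConceptType, str]],
               priority: SourcePriority) -> ConceptType:
    """Resolve conflicting type labels by voting.

    The type with the most votes wins; among tied top types the one backed
    by the highest-priority source wins.  Deterministic: remaining ties (the
    same source voting for two types) break on type name.
    """
    if not votes:
        raise ValueError("empty vote list")
    counts: dict[ConceptType, int] = {}
    backers: dict[ConceptType, set[str]] = {}
    for ctype, source in votes:
        counts[ctype] = counts.get(ctype, 0) + 1
        backers.setdefault(ctype, set()).add(source)
    top = max(counts.values())
    tied = [t for t, c in counts.items() if c == top]
    return min(tied, key=lambda t: (priority.best_rank(backers[t]), t.value))


def _score_pair(a: Entity, b: Entity, value_sim_threshold: float,
                ) -> tuple[MappingScore, RelatednessResult]:
    rel = relatedness(a, b, value_sim_threshold)
    com = string_similarity(a.name, b.name)
    return MappingScore(com, rel.value), rel


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # canonical root = lexicographically smallest id, for
            # order-independence
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def map_entities(entities: Iterable[Entity],
                 product_threshold: float = DEFAULT_PRODUCT_THRESHOLD,
                 value_sim_threshold: float = DEFAULT_VALUE_SIM_THRESHOLD,
                 ) -> tuple[list[list[str]], list[MergeAudit]]:
    """Pairwise duplicate mapping within identically-typed groups.

    Returns clusters (lists of entity ids; singletons included) formed by
    transitive closure of pairs whose commonness x relatedness product is
    strictly above ``product_threshold``, plus the full pairwise audit.
    The result is independent of input order.
    """
    ents = sorted(entities, key=lambda e: e.id)
    groups: dict[frozenset[ConceptType], list[Entity]] = {}
    for e in ents:
        groups.setdefault(coarse_types(e.types), []).append(e)
    uf = _UnionFind()
    for e in ents:
        uf.find(e.id)
    audit: list[MergeAudit] = []
    for group in groups.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                score, rel = _score_pair(a, b, value_sim_threshold)
                merged = score.product > product_threshold
                audit.append(MergeAudit(
                    a.id, b.id, score.commonness, score.relatedness,
                    score.product, merged, rel.no_shared_attributes))
                if merged:
                    uf.union(a.id, b.id)
    clusters: dict[str, list[str]] = {}
    for e in ents:
        clusters.setdefault(uf.find(e.id), []).append(e.id)
    return [sorted(c) for c in sorted(clusters.values())], audit


def fuse_kb(kb: KnowledgeBase, priority: SourcePriority,
            product_threshold: float = DEFAULT_PRODUCT_THRESHOLD,
            value_sim_threshold: float = DEFAULT_VALUE_SIM_THRESHOLD,
            ) -> tuple[KnowledgeBase, list[MergeAudit]]:
    """Merge duplicate entities in a KB and re-point all facts.

    Each cluster keeps the id and name of its member from the highest-
    priority source; types, sources and attributes are unioned.
    """
    clusters, audit = map_entities(
        kb.entities.values(), product_threshold, value_sim_threshold)
    id_map: dict[str, str] = {}
    merged_kb = KnowledgeBase(schema=kb.schema)
    for cluster in clusters:
        members = [kb.entities[i] for i in cluster]
        canonical = min(
            members,
            key=lambda e: (priority.best_rank(e.sources), e.id),
        )
        new = Entity(
            id=canonical.id,
            name=canonical.name,
            types=close_types(t for m in members for t in m.types),
            sources={s for m in members for s in m.sources},
        )
        for m in members:
            for aname in sorted(m.attributes):
                for v in m.attributes[aname]:
                    new.add_attribute(aname, v)
        merged_kb.add_entity(new)
        for i in cluster:
            id_map[i] = canonical.id
    for f in sorted(kb.facts, key=lambda f: f.key):
        merged_kb.add_fact(Fact(
            subject=id_map[f.subject],
            predicate=f.predicate,
            object=id_map[f.object] if f.object_is_entity else f.object,
            source=f.source,
            object_is_entity=f.object_is_entity,
        ))
    return merged_kb, audit


def merge_count_sweep(entities: Iterable[Entity],
                      thresholds: Sequence[float],
                      value_sim_threshold: float = DEFAULT_VALUE_SIM_THRESHOLD,
                      ) -> list[int]:
    """Number of merged pairs at each product threshold (for the sweep
    utility; merged-pair counts are non-increasing in the threshold)."""
    ents = list(entities)
    counts = []
    for thr in thresholds:
        _, audit = map_entities(ents, thr, value_sim_threshold)
        counts.append(sum(1 for a in audit if a.merged))
    return counts


# ---------------------------------------------------------------------------
# Attribute mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeMappingRule:
    """Maps a source attribute name onto a schema property, optionally
    constrained by the subject's and the value's coarse concept type."""

    source_attribute: str
    target_property: str
    subject_type: ConceptType | None = None
    value_type: ConceptType | None = None

    def matches(self, attr_name: str, subject_type: ConceptType | None,
                value_type: ConceptType | None) -> bool:
        if attr_name != self.source_attribute:
            return False
        if self.subject_type is not None and subject_type != self.subject_type:
            return False
        if self.value_type is not None and value_type != self.value_type:
            return False
        return True

    @property
    def specificity(self) -> int:
        return (self.subject_type is not None) + (self.value_type is not None)


def sort_rules_by_specificity(
        rules: Sequence[AttributeMappingRule]) -> list[AttributeMappingRule]:
    """Stable sort putting typed rules before untyped ones."""
    return sorted(rules, key=lambda r: -r.specificity)


def map_attribute(attr_name: str,
                  subject_type: ConceptType | None,
                  value_type: ConceptType | None,
                  rules: Sequence[AttributeMappingRule]) -> str | None:
    """First matching rule wins; ``None`` means quarantine (the caller keeps
    the raw attribute rather than dropping it silently)."""
    for rule in rules:
        if rule.matches(attr_name, subject_type, value_type):
            return rule.target_property
    return None


def default_attribute_rules() -> list[AttributeMappingRule]:
    """Manual map from healthcare-site property-box attribute names (and
    the generic encyclopedia ``症状`` attribute) onto the schema."""
    C = ConceptType
    rules = [
        # the generic "symptom" attribute between two symptoms
        AttributeMappingRule("症状", "symptom_related_symptom",
                             subject_type=C.SYMPTOM, value_type=C.SYMPTOM),
        AttributeMappingRule("相关疾病", "relevant_disease"),
        AttributeMappingRule("相关科室", "relevant_department"),
        AttributeMappingRule("相关检查", "relevant_examination"),
        AttributeMappingRule("常用药品", "relevant_medicine"),
        AttributeMappingRule("相关症状", "relevant_symptom"),
        AttributeMappingRule("发病部位", "location"),
        AttributeMappingRule("检查部位", "location"),
        AttributeMappingRule("规格", "specification"),
    ]
    return sort_rules_by_specificity(rules)
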