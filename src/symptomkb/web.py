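"""Wrapper-based extraction from healthcare-site detail pages.

Each site's detail pages share one layout, so extraction is driven by a
per-site *wrapper*: XPath locators for the property box (the attribute-value
panel of a detail page), its rows, and the key/value cells, plus a manual
map from the site's attribute names to schema properties.  Wrappers are
configuration (YAML), not code — a ninth site needs a config entry, not a
release.

Two heuristics refine entity subtypes: a symptom whose related department
name contains a TCM marker is a TCM symptom (departments without the marker
vote for the Western subtype; both can co-occur), and medicine descriptions
are scanned for TCM/Western keyword lists.  Synonym pairs are harvested from
detail-page abstracts with lexico-syntactic templates of the form
"[entity1]又称[entity2]".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import lxml.html
import yaml

from . import vocab
from .schema import (
    ConceptType,
    Entity,
    Fact,
    KnowledgeBase,
    mint_entity_id,
)

__all__ = [
    "DetailPage",
    "WrapperConfig",
    "SynonymPattern",
    "parse_property_box",
    "parse_list_page",
    "classify_symptom_subtype",
    "classify_medicine_subtype",
    "extract_synonyms",
    "extract_site",
    "load_wrappers",
]

logger = logging.getLogger(__name__)

_SENTENCE_SPLIT_RE = re.compile(r"[。！？!?\n]")
_SLOT_TRIM = " \t\"'“”‘’《》〈〉【】()（）[]、，,;；:：.。"

#: list-page file name -> planted coarse entity type
LIST_TYPE_BY_STEM = {
    "symptom": ConceptType.SYMPTOM,
    "disease": ConceptType.DISEASE,
    "medicine": ConceptType.MEDICINE,
    "department": ConceptType.DEPARTMENT,
    "examination": ConceptType.EXAMINATION,
}


@dataclass(frozen=True)
class DetailPage:
    site_id: str
    url: str
    html: str


@dataclass
class WrapperConfig:
    """Structural locators and the attribute-name map for one site."""

    site_id: str
    property_box: str          # XPath to the property-box element
    row: str                   # XPath (relative) to one attribute row
    key: str                   # XPath (relative) to the attribute-name cell
    value: str                 # XPath (relative) to the value cell
    attribute_map: dict[str, str] = field(default_factory=dict)
    title: str = "//h1"        # XPath to the entity name
    abstract: str = ""         # XPath to the abstract/description block
    list_item: str = "//ul[@class='entity-list']//a"  # anchors on list pages

    def to_dict(self) -> dict:
        return {
            "property_box": self.property_box,
            "row": self.row,
            "key": self.key,
            "value": self.value,
            "attribute_map": dict(self.attribute_map),
            "title": self.title,
            "abstract": self.abstract,
            "list_item": self.list_item,
        }


def load_wrappers(path: str | Path) -> dict[str, WrapperConfig]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return wrappers_from_dict(doc)


def wrappers_from_dict(doc: Mapping) -> dict[str, WrapperConfig]:
    out = {}
    for site_id, cfg in doc["sites"].items():
        out[site_id] = WrapperConfig(site_id=site_id, **cfg)
    return out


def _norm_space(text: str) -> str:
    return " ".join(text.split())


def parse_property_box(page: DetailPage, wrapper: WrapperConfig,
                       ) -> list[tuple[str, str]]:
    """Extract (schema-property, value) pairs from a detail page.

    Only attributes covered by the wrapper's map are emitted, in order of
    appearance, with whitespace-normalized values.  A page without the
    property box yields an empty list with a warning, not an error — one
    malformed page must not halt a batch.
    """
    doc = lxml.html.fromstring(page.html)
    boxes = doc.xpath(wrapper.property_box)
    if not boxes:
        logger.warning("no property box on %s page %s", page.site_id,
                       page.url)
        return []
    pairs: list[tuple[str, str]] = []
    for box in boxes:
        for row in box.xpath(wrapper.row):
            keys = row.xpath(wrapper.key)
            values = row.xpath(wrapper.value)
            if not keys or not values:
                continue
            key = _norm_space(keys[0].text_content())
            prop = wrapper.attribute_map.get(key)
            if prop is None:
                logger.debug("unmapped attribute %r on %s", key, page.url)
                continue
            pairs.append((prop, _norm_space(values[0].text_content())))
    return pairs


def parse_list_page(html: str, wrapper: WrapperConfig,
                    ) -> list[tuple[str, str]]:
    """(entity name, detail href) pairs from a list page."""
    doc = lxml.html.fromstring(html)
    out = []
    for a in doc.xpath(wrapper.list_item):
        name = _norm_space(a.text_content())
        href = a.get("href", "")
        if name:
            out.append((name, href))
    return out


def page_title(page: DetailPage, wrapper: WrapperConfig) -> str | None:
    doc = lxml.html.fromstring(page.html)
    nodes = doc.xpath(wrapper.title)
    return _norm_space(nodes[0].text_content()) if nodes else None


def page_abstract(page: DetailPage, wrapper: WrapperConfig) -> str:
    if not wrapper.abstract:
        return ""
    doc = lxml.html.fromstring(page.html)
    nodes = doc.xpath(wrapper.abstract)
    return _norm_space(nodes[0].text_content()) if nodes else ""


# ---------------------------------------------------------------------------
# Subtype heuristics
# ---------------------------------------------------------------------------

def classify_symptom_subtype(
        relevant_departments: Iterable[str],
        tcm_markers: Sequence[str] = vocab.TCM_DEPARTMENT_MARKERS,
) -> set[ConceptType]:
    """TCM/Western symptom labels from related-department names.

    A department containing a TCM marker votes TCM; one without votes
    Western; both labels may co-occur.  No departments -> no evidence.
    """
    labels: set[ConceptType] = set()
    for dept in relevant_departments:
        if any(marker in dept for marker in tcm_markers):
            labels.add(ConceptType.TCM_SYMPTOM)
        else:
            labels.add(ConceptType.WESTERN_SYMPTOM)
    return labels


def classify_medicine_subtype(
        description: str,
        tcm_keywords: Sequence[str] = vocab.MEDICINE_TCM_KEYWORDS,
        western_keywords: Sequence[str] = vocab.MEDICINE_WESTERN_KEYWORDS,
) -> set[ConceptType]:
    """TCM/Western medicine labels from description keywords; no keyword
    evidence leaves the entity a plain Medicine."""
    labels: set[ConceptType] = set()
    if any(k in description for k in tcm_keywords):
        labels.add(ConceptType.TCM_MEDICINE)
    if any(k in description for k in western_keywords):
        labels.add(ConceptType.WESTERN_MEDICINE)
    return labels


# ---------------------------------------------------------------------------
# Synonym (sameAs) extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynonymPattern:
    """A two-slot template such as ``[entity1]又称[entity2]``."""

    template: str

    def __post_init__(self) -> None:
        if (self.template.count("[entity1]") != 1
                or self.template.count("[entity2]") != 1):
            raise ValueError("pattern needs exactly one [entity1] and one "
                             "[entity2] slot")

    @property
    def connector(self) -> str:
        head, tail = self.template.split("[entity1]")
        middle = tail.split("[entity2]")[0]
        return middle


def default_patterns() -> list[SynonymPattern]:
    return [SynonymPattern(t) for t in vocab.DEFAULT_SYNONYM_PATTERNS]


def extract_synonyms(abstract: str,
                     patterns: Sequence[SynonymPattern],
                     ) -> list[tuple[str, str]]:
    """Harvest symmetric sameAs pairs from an abstract.

    Each pattern is applied per sentence; the slot fillers are the text
    before and after the first occurrence of the connector, trimmed of
    punctuation.  Self-pairs are suppressed.
    """
    if not patterns:
        raise ValueError("pattern list must be non-empty")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for sentence in _SENTENCE_SPLIT_RE.split(abstract):
        for pattern in patterns:
            conn = pattern.connector
            if conn not in sentence:
                continue
            left, _, right = sentence.partition(conn)
            e1 = left.strip(_SLOT_TRIM)
            e2 = right.strip(_SLOT_TRIM)
            if not e1 or not e2 or e1 == e2:
                continue
            if (e1, e2) not in seen:
                seen.add((e1, e2))
                pairs.append((e1, e2))
    return pairs


# ---------------------------------------------------------------------------
# Site-level extraction pipeline
# ---------------------------------------------------------------------------

def extract_site(pages: Mapping[str, str], site_id: str,
                 wrapper: WrapperConfig,
                 kb: KnowledgeBase | None = None,
                 patterns: Sequence[SynonymPattern] | None = None,
                 ) -> KnowledgeBase:
    """Run extraction for one site into a KB.

    ``pages`` maps relative file names to HTML text; list pages are named
    ``list_<type>.html`` and enumerate detail pages.  Property-box
    attributes arrive pre-mapped to schema properties by the wrapper;
    entity-valued properties produce stub object entities, literal-valued
    ones become attribute values and literal facts.
    """
    kb = kb if kb is not None else KnowledgeBase()
    patterns = list(patterns) if patterns is not None else default_patterns()

    def stub(name: str, ctype: ConceptType) -> Entity:
        return kb.get_or_add(Entity(
            id=mint_entity_id(site_id, name), name=name,
            types={ctype}, sources={site_id}))

    for fname in sorted(pages):
        stem = Path(fname).stem
        if not stem.startswith("list_"):
            continue
        ctype = LIST_TYPE_BY_STEM.get(stem[len("list_"):])
        if ctype is None:
            logger.warning("unknown list page %s on site %s", fname, site_id)
            continue
        for name, href in parse_list_page(pages[fname], wrapper):
            detail_html = pages.get(href)
            if detail_html is None:
                logger.warning("missing detail page %s for %r", href, name)
                continue
            page = DetailPage(site_id, href, detail_html)
            entity = stub(name, ctype)
            abstract = page_abstract(page, wrapper)
            pairs = parse_property_box(page, wrapper)
            dept_values = [v for p, v in pairs if p == "relevant_department"]
            if ctype is ConceptType.SYMPTOM:
                entity.types |= classify_symptom_subtype(dept_values)
            elif ctype is ConceptType.MEDICINE:
                entity.types |= classify_medicine_subtype(abstract)
            for prop, value in pairs:
                spec = kb.schema.get(prop)
                if spec is None:
                    entity.add_attribute(prop, value)  # quarantined raw attr
                    continue
                entity.add_attribute(prop, value)
                if spec.entity_valued:
                    rng = spec.range or frozenset({ConceptType.OTHER})
                    obj = stub(value, next(iter(rng)))
                    kb.add_fact(Fact(entity.id, prop, obj.id, site_id,
                                     object_is_entity=True))
                else:
                    kb.add_fact(Fact(entity.id, prop, value, site_id))
            for e1, e2 in extract_synonyms(abstract, patterns):
                a = stub(e1, ctype) if e1 != entity.name else entity
                b = stub(e2, ctype) if e2 != entity.name else entity
                kb.add_fact(Fact(a.id, "sameAs", b.id, site_id,
                                 object_is_entity=True))
                kb.add_fact(Fact(b.id, "sameAs", a.id, site_id,
                                 object_is_entity=True))
    return kb


def load_site_dir(site_dir: str | Path) -> dict[str, str]:
    """Read a site directory (list_*.html plus detail/*.html) into memory."""
    site_dir = Path(site_dir)
    pages: dict[str, str] = {}
    for path in sorted(site_dir.rglob("*.html")):
        pages[str(path.relative_to(site_dir))] = path.read_text("utf-8")
    return pages
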