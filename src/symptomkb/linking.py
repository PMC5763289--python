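"""Cross-lingual symptom linking to an English concept table.

Chinese symptom names are translated to English phrases by a pluggable
translator (tests and the CLI use a deterministic bilingual lexicon), each
phrase is reduced to a bag of words, and a symptom is linked to every
concept row whose term has *exactly* the same bag — i.e. Jaccard similarity
of 1.  The strict rule makes the normalization consequential, so the same
normalizer (lowercase, strip punctuation, split on whitespace) is applied
to both sides and no stemming is performed by default ("fevers" != "fever").
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .schema import ConceptType, Entity, Fact, KnowledgeBase

__all__ = [
    "ConceptRow",
    "SymptomLink",
    "LexiconTranslator",
    "bag_of_words",
    "jaccard",
    "link_symptoms",
    "verify_links",
    "semantic_type_distribution",
    "load_concepts_tsv",
    "load_lexicon_tsv",
    "links_to_facts",
]

logger = logging.getLogger(__name__)

Translator = Callable[[str], "str | None"]

_PUNCT_RE = re.compile(r"[^\w\s]+", flags=re.UNICODE)


@dataclass(frozen=True)
class ConceptRow:
    """One row of the concept table: a CUI-like id, an English preferred
    term, and a semantic type such as ``Sign or Symptom`` or ``Finding``."""

    cui: str
    term: str
    semantic_type: str


@dataclass(frozen=True)
class SymptomLink:
    entity_id: str
    cui: str
    translation: str
    jaccard: float = 1.0


class LexiconTranslator:
    """Deterministic dictionary translator (Chinese -> English phrase)."""

    def __init__(self, lexicon: Mapping[str, str]):
        self.lexicon = dict(lexicon)

    def __call__(self, text: str) -> str | None:
        return self.lexicon.get(text)


def bag_of_words(phrase: str) -> frozenset[str]:
    """Lowercase, strip punctuation, split on whitespace; set semantics."""
    cleaned = _PUNCT_RE.sub(" ", phrase.lower())
    return frozenset(tok for tok in cleaned.split() if tok)


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    """|a ∩ b| / |a ∪ b|; errors when both sets are empty (0/0)."""
    if not a and not b:
        raise ValueError("Jaccard of two empty bags is undefined")
    return len(a & b) / len(a | b)


def link_symptoms(symptoms: Iterable[Entity], translator: Translator,
                  concepts: Sequence[ConceptRow]) -> list[SymptomLink]:
    """Link each translatable symptom to every concept with the same bag.

    One symptom may link to several concepts sharing a bag; untranslatable
    symptoms are skipped with a log message.
    """
    by_bag: dict[frozenset[str], list[ConceptRow]] = {}
    for row in concepts:
        bag = bag_of_words(row.term)
        if not bag:
            logger.warning("concept %s has an empty term bag; skipped",
                           row.cui)
            continue
        by_bag.setdefault(bag, []).append(row)
    links: list[SymptomLink] = []
    for sym in sorted(symptoms, key=lambda e: e.id):
        phrase = translator(sym.name)
        if phrase is None:
            logger.info("no translation for symptom %r; skipped", sym.name)
            continue
        bag = bag_of_words(phrase)
        if not bag:
            logger.info("empty translation bag for %r; skipped", sym.name)
            continue
        for row in by_bag.get(bag, ()):
            links.append(SymptomLink(sym.id, row.cui, phrase))
    return links


def verify_links(links: Iterable[SymptomLink],
                 concepts: Sequence[ConceptRow]) -> bool:
    """Self-audit: recompute Jaccard for every stored link from scratch."""
    terms = {row.cui: row.term for row in concepts}
    for link in links:
        if link.cui not in terms:
            raise ValueError(f"link references unknown concept {link.cui!r}")
        if jaccard(bag_of_words(link.translation),
                   bag_of_words(terms[link.cui])) != 1.0:
            return False
    return True


def semantic_type_distribution(links: Iterable[SymptomLink],
                               concepts: Sequence[ConceptRow],
                               ) -> dict[str, tuple[int, float]]:
    """Semantic type -> (link count, fraction of all links)."""
    types = {row.cui: row.semantic_type for row in concepts}
    counts: dict[str, int] = {}
    total = 0
    for link in links:
        if link.cui not in types:
            raise ValueError(f"link references unknown concept {link.cui!r}")
        counts[types[link.cui]] = counts.get(types[link.cui], 0) + 1
        total += 1
    return {t: (c, c / total) for t, c in sorted(counts.items())}


def links_to_facts(links: Iterable[SymptomLink],
                   source: str = "terminology_link") -> list[Fact]:
    """Render links as ``exact_match`` facts (CUI literals) for the KB."""
    return [
        Fact(subject=l.entity_id, predicate="exact_match", object=l.cui,
             source=source)
        for l in links
    ]


def add_links_to_kb(kb: KnowledgeBase, links: Iterable[SymptomLink],
                    source: str = "terminology_link") -> int:
    n = 0
    for fact in links_to_facts(links, source):
        kb.add_fact(fact)
        n += 1
    return n


def symptoms_of(kb: KnowledgeBase) -> list[Entity]:
    return kb.entities_of_type(ConceptType.SYMPTOM)


# ---------------------------------------------------------------------------
# TSV I/O (an MRCONSO/MRSTY-like projection and a bilingual lexicon)
# ---------------------------------------------------------------------------

def load_concepts_tsv(path: str | Path) -> list[ConceptRow]:
    """Columns: cui, term, semantic_type (tab-separated, UTF-8, no header)."""
    rows: list[ConceptRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec or rec[0].startswith("#"):
                continue
            cui, term, semtype = rec[0], rec[1], rec[2]
            rows.append(ConceptRow(cui, term, semtype))
    return rows


def load_lexicon_tsv(path: str | Path) -> LexiconTranslator:
    """Columns: chinese, english (tab-separated, UTF-8, no header)."""
    lex: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec or rec[0].startswith("#"):
                continue
            lex[rec[0]] = rec[1]
    return LexiconTranslator(lex)
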