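"""Encyclopedia entity bootstrapping and seven-label classification.

Bootstrapping (single pass): entities extracted from healthcare sites act
as *seeds*; the categories of their encyclopedia pages form the candidate
category set; each category's confidence is the ratio of seeds among its
member pages, split into high/low at a configurable threshold; any page
carrying a low-confidence category is noise and is removed.  Pages without
categories cannot be convicted and are retained.

Classification: a decision tree over 26 features drawn from the five fields
of an encyclopedia entity page (name, abstract, content, full text,
categories) assigns one of seven labels — department, tcm, western
medicine, symptom, disease, examination, other.  Feature inventory: six
name-suffix tests, four abstract cue-word tests, two content cue-word
count thresholds plus the two raw counts, two full-text cue tests, six
category cue tests, and four per-field total hit counts.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.tree import DecisionTreeClassifier

from . import vocab
from .schema import ConceptType
from .web import classify_symptom_subtype

__all__ = [
    "EncyclopediaPage",
    "CategoryConfidence",
    "ENTITY_LABELS",
    "collect_seed_categories",
    "score_categories",
    "category_members",
    "filter_noise_entities",
    "feature_names",
    "featurize_page",
    "feature_matrix",
    "train_entity_classifier",
    "classify_entity",
    "cross_validate_classifier",
    "refine_symptom_subtype",
]

logger = logging.getLogger(__name__)

ENTITY_LABELS: tuple[str, ...] = (
    "department", "tcm", "western_medicine", "symptom", "disease",
    "examination", "other",
)

DEFAULT_CONFIDENCE_THRESHOLD = 0.1

_DEPT_MENTION_RE = re.compile(r"[一-鿿A-Za-z]{1,8}科")


@dataclass
class EncyclopediaPage:
    """Five-field entity page: name, abstract, content, full text and the
    page's category tags.  ``full_text`` defaults to abstract + content but
    may be supplied independently."""

    name: str
    abstract: str = ""
    content: str = ""
    full_text: str | None = None
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("page name must be non-empty")
        self.categories = frozenset(self.categories)
        if self.full_text is None:
            self.full_text = self.abstract + self.content

    def to_json(self) -> dict:
        return {
            "name": self.name, "abstract": self.abstract,
            "content": self.content, "full_text": self.full_text,
            "categories": sorted(self.categories),
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "EncyclopediaPage":
        return cls(
            name=doc["name"], abstract=doc.get("abstract", ""),
            content=doc.get("content", ""),
            full_text=doc.get("full_text"),
            categories=frozenset(doc.get("categories", ())),
        )


def read_pages_jsonl(path: str | Path) -> list[EncyclopediaPage]:
    pages = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                pages.append(EncyclopediaPage.from_json(json.loads(line)))
    return pages


def write_pages_jsonl(pages: Iterable[EncyclopediaPage],
                      path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pages:
            fh.write(json.dumps(p.to_json(), ensure_ascii=False,
                                sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Seed-category bootstrapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryConfidence:
    category: str
    seed_count: int
    entity_count: int

    @property
    def ratio(self) -> float:
        return self.seed_count / self.entity_count

    def label(self, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> str:
        return "high" if self.ratio >= threshold else "low"


def collect_seed_categories(seeds: Iterable[str],
                            pages: Mapping[str, EncyclopediaPage],
                            ) -> set[str]:
    """Union of categories over the seed entities' pages; seeds without a
    page are skipped with a log message."""
    cats: set[str] = set()
    for seed in seeds:
        page = pages.get(seed)
        if page is None:
            logger.info("seed %r has no encyclopedia page; skipped", seed)
            continue
        cats |= page.categories
    return cats


def category_members(pages: Iterable[EncyclopediaPage],
                     ) -> dict[str, set[str]]:
    """Category -> names of member pages."""
    members: dict[str, set[str]] = {}
    for p in pages:
        for c in p.categories:
            members.setdefault(c, set()).add(p.name)
    return members


def score_categories(seeds: Iterable[str],
                     members: Mapping[str, Iterable[str]],
                     ) -> list[CategoryConfidence]:
    """Seed ratio per category.  A category with zero members is an error
    (the ratio would be 0/0)."""
    seed_set = set(seeds)
    out = []
    for cat in sorted(members):
        names = set(members[cat])
        if not names:
            raise ValueError(f"category {cat!r} has no members")
        out.append(CategoryConfidence(cat, len(names & seed_set), len(names)))
    return out


def low_confidence_categories(
        confidences: Iterable[CategoryConfidence],
        threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> set[str]:
    return {c.category for c in confidences if c.label(threshold) == "low"}


def filter_noise_entities(pages: Iterable[EncyclopediaPage],
                          low_confidence: set[str],
                          ) -> list[EncyclopediaPage]:
    """Remove every page carrying a low-confidence category.  Pages with no
    categories are retained (no positive evidence against them)."""
    return [p for p in pages if not (p.categories & low_confidence)]


# ---------------------------------------------------------------------------
# Featurization (26 features over five fields)
# ---------------------------------------------------------------------------

def feature_names(keywords: Mapping[str, Sequence[str]] | None = None,
                  ) -> list[str]:
    kw = keywords or vocab.ENCYCLOPEDIA_KEYWORDS
    names = [f"name_endswith_{w}" for w in kw["name_suffixes"]]
    names += [f"abstract_contains_{w}" for w in kw["abstract_words"]]
    names += ["content_medicine_gt3", "content_disease_gt3",
              "content_medicine_hits", "content_disease_hits"]
    names += [f"fulltext_contains_{w}" for w in kw["fulltext_words"]]
    names += [f"category_contains_{w}" for w in kw["category_words"]]
    names += ["name_hits", "abstract_hits", "fulltext_hits", "category_hits"]
    return names


def featurize_page(page: EncyclopediaPage,
                   keywords: Mapping[str, Sequence[str]] | None = None,
                   ) -> dict[str, float]:
    """The 26-dimensional feature vector as an ordered name -> value dict.

    Name features test string suffixes; abstract/full-text/category features
    test containment; the two content features count distinct cue words
    present and fire above three hits.  Deterministic and invariant to
    category ordering (categories are a set).
    """
    kw = keywords or vocab.ENCYCLOPEDIA_KEYWORDS
    cats = " ".join(sorted(page.categories))
    feats: dict[str, float] = {}
    for w in kw["name_suffixes"]:
        feats[f"name_endswith_{w}"] = float(page.name.endswith(w))
    for w in kw["abstract_words"]:
        feats[f"abstract_contains_{w}"] = float(w in page.abstract)
    med_hits = sum(1 for w in kw["content_medicine_words"]
                   if w in page.content)
    dis_hits = sum(1 for w in kw["content_disease_words"]
                   if w in page.content)
    feats["content_medicine_gt3"] = float(med_hits > 3)
    feats["content_disease_gt3"] = float(dis_hits > 3)
    feats["content_medicine_hits"] = float(med_hits)
    feats["content_disease_hits"] = float(dis_hits)
    for w in kw["fulltext_words"]:
        feats[f"fulltext_contains_{w}"] = float(w in (page.full_text or ""))
    for w in kw["category_words"]:
        feats[f"category_contains_{w}"] = float(
            any(w in c for c in page.categories))
    feats["name_hits"] = float(
        sum(1 for w in kw["name_suffixes"] if w in page.name))
    feats["abstract_hits"] = float(
        sum(1 for w in kw["abstract_words"] if w in page.abstract))
    feats["fulltext_hits"] = float(
        sum(1 for w in kw["fulltext_words"] if w in (page.full_text or "")))
    feats["category_hits"] = float(
        sum(1 for w in kw["category_words"] if w in cats))
    return feats


def feature_matrix(pages: Sequence[EncyclopediaPage],
                   keywords: Mapping[str, Sequence[str]] | None = None,
                   ) -> np.ndarray:
    names = feature_names(keywords)
    X = np.zeros((len(pages), len(names)))
    for i, p in enumerate(pages):
        feats = featurize_page(p, keywords)
        X[i] = [feats[n] for n in names]
    return X


# ---------------------------------------------------------------------------
# Seven-label decision-tree classifier
# ---------------------------------------------------------------------------

def train_entity_classifier(X: np.ndarray, y: Sequence[str],
                            seed: int = 0,
                            max_depth: int | None = None,
                            ) -> DecisionTreeClassifier:
    labels = set(y)
    if len(labels) < 2:
        raise ValueError("training data must contain at least two labels")
    unknown = labels - set(ENTITY_LABELS)
    if unknown:
        raise ValueError(f"unknown entity labels: {sorted(unknown)}")
    model = DecisionTreeClassifier(random_state=seed, max_depth=max_depth)
    model.fit(X, list(y))
    return model


def classify_entity(model: DecisionTreeClassifier, page: EncyclopediaPage,
                    keywords: Mapping[str, Sequence[str]] | None = None,
                    ) -> str:
    X = feature_matrix([page], keywords)
    return str(model.predict(X)[0])


def cross_validate_classifier(pages: Sequence[EncyclopediaPage],
                              labels: Sequence[str],
                              keywords: Mapping[str, Sequence[str]]
                              | None = None,
                              n_folds: int = 10,
                              seed: int = 0) -> dict[str, float]:
    """Ten-fold (by default) stratified cross-validation; reports accuracy
    and macro-averaged F1."""
    X = feature_matrix(pages, keywords)
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(
        DecisionTreeClassifier(random_state=seed), X, y, cv=cv)
    return {
        "accuracy": float(accuracy_score(y, pred)),
        "macro_f1": float(f1_score(y, pred, average="macro")),
    }


def refine_symptom_subtype(
        page: EncyclopediaPage,
        tcm_markers: Sequence[str] = vocab.TCM_DEPARTMENT_MARKERS,
) -> set[ConceptType]:
    """TCM/Western subtype for a page already classified as a symptom.

    Department mentions (…科 tokens) are harvested from the page text and
    fed to the department-marker heuristic; with no evidence the Western
    subtype is the default (TCM labels only ever arise from positive marker
    evidence).
    """
    text = " ".join((page.abstract, page.content, page.full_text or "",
                     " ".join(sorted(page.categories))))
    mentions = _DEPT_MENTION_RE.findall(text)
    labels = classify_symptom_subtype(mentions, tcm_markers)
    if not labels:
        labels = {ConceptType.WESTERN_SYMPTOM}
    return labels
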