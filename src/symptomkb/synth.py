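"""Deterministic synthetic-data generators with planted ground truth.

Every input the pipeline consumes is generated here: two pseudo healthcare
sites (detail pages with property boxes, list pages, wrapper configs), an
encyclopedia page corpus with seed/category structure and planted noise
pages, an EMR corpus with gold symptom spans and planted sentence
duplication, and a bilingual lexicon + concept table for cross-lingual
linking.  All generators are pure functions of (config, seed): re-running
with the same seed reproduces byte-identical artifacts.

Planted structure mirrors how the real inputs behave: duplicated entities
across sites differ by small affix insertions in the name and one perturbed
fact out of three; encyclopedia noise pages are marked by lifestyle
(health-preservation / beauty / psychology) categories that attract no
seeds; EMR sentences are templated clinical phrases around lexicon
symptoms, with verbatim copy-paste duplication inside records.
Fractional rate x count quantities round down (floor), so planted counts
are exact.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

from . import ner, vocab
from .encyclopedia import EncyclopediaPage, write_pages_jsonl
from .fusion import string_similarity
from .linking import ConceptRow, LexiconTranslator
from .ner import EMRecord, LabeledSequence, TokenSequence, pos_tag
from .schema import ConceptType, Entity, mint_entity_id
from .web import WrapperConfig

__all__ = [
    "GeneratorConfig",
    "HealthcareFixture",
    "EncyclopediaFixture",
    "EMRFixture",
    "LinkingFixture",
    "generate_healthcare_site",
    "generate_encyclopedia",
    "generate_emr_corpus",
    "generate_linking_fixture",
    "generate_all",
    "healthcare_seed_labels",
    "ner_recovery_experiment",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    Defaults are the conditions the test suite and the acceptance checks
    run under; rates are in [0, 1] and fractional counts floor.
    """

    seed: int = 7
    # healthcare sites
    sites: tuple[str, str] = ("kangfu", "yixun")
    n_symptoms: int = 80
    n_diseases: int = 50
    n_medicines: int = 40
    n_departments: int = 16
    n_examinations: int = 14
    duplication_rate: float = 0.5
    max_name_edits: int = 2
    edit_count_weights: tuple[float, float, float] = (0.55, 0.35, 0.10)
    missing_box_rate: float = 0.02
    synonym_rate: float = 0.25
    tcm_symptom_rate: float = 0.25
    value_sim_threshold: float = 0.85
    # encyclopedia
    ency_pages_per_label: int = 40
    ency_seeds_per_label: int = 10
    ency_noise_rate: float = 0.2
    ency_feature_noise: float = 0.05
    confidence_threshold: float = 0.1
    # EMR corpus
    n_records: int = 1000
    n_train_records: int = 660
    symptoms_per_record: int = 3
    sentence_duplication_rate: float = 0.3
    label_noise: float = 0.05
    # linking
    n_exact_links: int = 50
    n_near_miss: int = 50
    n_distractor_concepts: int = 10

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "missing_box_rate", "synonym_rate",
                     "tcm_symptom_rate", "ency_noise_rate",
                     "ency_feature_noise", "sentence_duplication_rate",
                     "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _write_json(doc, path: Path) -> None:
    path.write_text(
        json.dumps(doc, ensure_ascii=False, sort_keys=True, indent=1) + "\n",
        encoding="utf-8")


# ===========================================================================
# Healthcare sites
# ===========================================================================

_DESCRIPTORS = ("胀痛", "隐痛", "酸痛", "刺痛", "麻木", "不适", "灼热", "无力")
_DOSE_FORMS = ("片", "胶囊", "颗粒", "口服液")

_ATTR_KEYS = {
    "symptom": ("相关科室", "相关疾病", "发病部位"),
    "disease": ("相关科室", "相关症状", "相关检查"),
    "medicine": ("相关科室", "相关疾病", "规格"),
    "department": ("相关疾病", "相关症状", "相关检查"),
    "examination": ("相关科室", "相关疾病", "检查部位"),
}

ATTRIBUTE_MAP = {
    "相关科室": "relevant_department",
    "相关疾病": "relevant_disease",
    "相关症状": "relevant_symptom",
    "相关检查": "relevant_examination",
    "发病部位": "location",
    "检查部位": "location",
    "规格": "specification",
}

_COARSE = {
    "symptom": ConceptType.SYMPTOM,
    "disease": ConceptType.DISEASE,
    "medicine": ConceptType.MEDICINE,
    "department": ConceptType.DEPARTMENT,
    "examination": ConceptType.EXAMINATION,
}


def _unique_names(rng: random.Random, n: int, make) -> list[str]:
    """Draw names from ``make(rng)`` until n distinct ones accumulate."""
    out: list[str] = []
    seen: set[str] = set()
    guard = 0
    while len(out) < n:
        name = make(rng)
        guard += 1
        if guard > 100 * n:
            name = f"{name}（{guard}）"  # disambiguation suffix, last resort
        if name not in seen:
            seen.add(name)
            out.append(name)
    return out


def _symptom_name(rng: random.Random) -> str:
    # compound clinical phrasings, the style detail pages actually title
    if rng.random() < 0.5:
        return rng.choice(vocab.MODIFIERS) + rng.choice(vocab.SYMPTOMS_WESTERN)
    return (rng.choice(vocab.MODIFIERS) + rng.choice(vocab.BODY_PARTS)
            + rng.choice(_DESCRIPTORS))


def _disease_name(rng: random.Random) -> str:
    if rng.random() < 0.4:
        return rng.choice(vocab.DISEASES)
    return rng.choice(vocab.MODIFIERS) + rng.choice(vocab.DISEASES)


def _medicine_names(rng: random.Random, n: int) -> tuple[list[str], list[str]]:
    """(TCM names, Western names), half/half."""
    n_tcm = n // 2
    tcm = _unique_names(rng, n_tcm, lambda r: (
        r.choice(vocab.MEDICINES_TCM) if r.random() < 0.5
        else r.choice(vocab.MEDICINES_TCM)[:-2] + r.choice(_DOSE_FORMS)))
    west = _unique_names(rng, n - n_tcm, lambda r: (
        r.choice(vocab.MEDICINES_WESTERN) if r.random() < 0.5
        else r.choice(vocab.MEDICINES_WESTERN) + r.choice(_DOSE_FORMS)))
    return tcm, west


def _examination_name(rng: random.Random) -> str:
    if rng.random() < 0.6:
        return rng.choice(vocab.EXAMINATIONS)
    return rng.choice(vocab.BODY_PARTS) + "检查"


@dataclass
class _SiteEntity:
    name: str
    kind: str                      # symptom/disease/medicine/...
    types: list[str]               # ConceptType values incl. subtypes
    attributes: dict[str, str]     # Chinese key -> value, insertion order
    abstract: str
    has_box: bool = True
    synonym: str | None = None


@dataclass
class HealthcareFixture:
    """Generated pseudo-sites: HTML pages, wrapper configs, ground truth."""

    pages: dict[str, dict[str, str]]          # site -> relpath -> html
    wrappers: dict[str, WrapperConfig]
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        for site, files in self.pages.items():
            for rel, html in files.items():
                p = out / site / rel
                p.parent.mkdir(parents=True, exist_ok=True)
                p.write_text(html, encoding="utf-8")
        wrapper_doc = {"sites": {s: w.to_dict()
                                 for s, w in sorted(self.wrappers.items())}}
        import yaml
        (out / "wrappers.yaml").write_text(
            yaml.safe_dump(wrapper_doc, allow_unicode=True, sort_keys=True),
            encoding="utf-8")
        _write_json(self.truth, out / "ground_truth.json")


def _perturb_name(rng: random.Random, name: str, taken: set[str],
                  weights: tuple[float, float, float]) -> tuple[str, int]:
    """Insert 0-2 affix characters (suffix-biased), avoiding collisions.

    The edit budget is capped at (len-1)//3 insertions so that the planted
    pair's name commonness |LCS|/max(len) stays strictly above 3/4: with one
    of three shared facts perturbed the relatedness of a planted pair is
    2/3, and the pair is recoverable at the default product threshold of
    0.5 exactly when commonness exceeds 3/4.  Planted duplicates are meant
    to be duplicates an oracle could confirm; edits beyond this budget
    would plant pairs that are unrecoverable by construction.
    """
    cap = (len(name) - 1) // 3
    for _ in range(50):
        k = min(rng.choices((0, 1, 2), weights=weights)[0], cap)
        new = name
        for _ in range(k):
            pos = len(new) if rng.random() < 0.7 else rng.randrange(1, len(new) + 1)
            new = new[:pos] + rng.choice(vocab.AFFIX_CHARS) + new[pos:]
        if new == name and k == 0:
            if name not in taken:
                return name, 0
            continue
        if new not in taken and new != name:
            return new, k
    # fall back to a guaranteed-fresh suffix
    return name + "症", 1


def _perturb_value(rng: random.Random, key: str, value: str,
                   pools: Mapping[str, list[str]],
                   sim_threshold: float) -> str:
    pool = pools[key]
    for _ in range(50):
        cand = rng.choice(pool)
        if cand != value and string_similarity(cand, value) < sim_threshold:
            return cand
    return value + "（修订）"


def _detail_html_a(e: _SiteEntity) -> str:
    rows = "".join(
        f"<tr><th>{k}</th><td>{v}</td></tr>" for k, v in e.attributes.items())
    box = (f'<div class="property-box"><table>{rows}</table></div>'
           if e.has_box else "")
    return (
        '<html><head><meta charset="utf-8">'
        f"<title>{e.name}</title></head><body>\n"
        f'<h1 class="entity-name">{e.name}</h1>\n'
        f'<div class="abstract"><p>{e.abstract}</p></div>\n'
        f"{box}\n</body></html>\n"
    )


def _detail_html_b(e: _SiteEntity) -> str:
    items = "".join(
        f"<dt>{k}</dt><dd>{v}</dd>" for k, v in e.attributes.items())
    box = f'<dl class="props">{items}</dl>' if e.has_box else ""
    return (
        '<html><head><meta charset="utf-8">'
        f"<title>{e.name}</title></head><body>\n"
        f'<h2 id="title">{e.name}</h2>\n'
        f'<p class="summary">{e.abstract}</p>\n'
        f"{box}\n</body></html>\n"
    )


_SITE_LAYOUTS = (_detail_html_a, _detail_html_b)

_WRAPPER_A = dict(
    property_box="//div[@class='property-box']", row=".//tr",
    key="./th", value="./td",
    title="//h1[@class='entity-name']", abstract="//div[@class='abstract']",
)
_WRAPPER_B = dict(
    property_box="//dl[@class='props']", row="./dt",
    key=".", value="./following-sibling::dd[1]",
    title="//h2[@id='title']", abstract="//p[@class='summary']",
)


def generate_healthcare_site(config: GeneratorConfig) -> HealthcareFixture:
    """Two pseudo healthcare sites with planted duplicates and synonyms."""
    rng = random.Random(config.seed)
    site_a, site_b = config.sites

    symptom_names = _unique_names(rng, config.n_symptoms, _symptom_name)
    disease_names = _unique_names(rng, config.n_diseases, _disease_name)
    med_tcm, med_west = _medicine_names(rng, config.n_medicines)
    dept_pool = list(vocab.DEPARTMENTS + vocab.DEPARTMENTS_TCM)
    department_names = dept_pool[:config.n_departments]
    exam_names = _unique_names(rng, config.n_examinations, _examination_name)

    non_tcm_depts = [d for d in department_names
                     if not any(m in d for m in vocab.TCM_DEPARTMENT_MARKERS)]
    tcm_depts = [d for d in department_names if d not in non_tcm_depts] or \
        list(vocab.DEPARTMENTS_TCM)

    value_pools: dict[str, list[str]] = {
        "相关科室": department_names,
        "相关疾病": disease_names,
        "相关症状": symptom_names,
        "相关检查": exam_names,
        "发病部位": list(vocab.BODY_PARTS),
        "检查部位": list(vocab.BODY_PARTS),
        "规格": [f"0.{d}g×{n}片" for d in (1, 2, 25, 3, 5) for n in (6, 12, 24)],
    }

    def build_entity(name: str, kind: str, tcm_med: bool = False,
                     ) -> _SiteEntity:
        attrs: dict[str, str] = {}
        for key in _ATTR_KEYS[kind]:
            if key == "相关科室" and kind == "symptom":
                is_tcm = rng.random() < config.tcm_symptom_rate
                attrs[key] = rng.choice(tcm_depts if is_tcm else non_tcm_depts)
            else:
                attrs[key] = rng.choice(value_pools[key])
        types = [_COARSE[kind].value]
        if kind == "symptom":
            types.append(
                ConceptType.TCM_SYMPTOM.value
                if any(m in attrs["相关科室"]
                       for m in vocab.TCM_DEPARTMENT_MARKERS)
                else ConceptType.WESTERN_SYMPTOM.value)
        if kind == "medicine":
            types.append(ConceptType.TCM_MEDICINE.value if tcm_med
                         else ConceptType.WESTERN_MEDICINE.value)
        abstract = _abstract_for(rng, name, kind, attrs, tcm_med)
        synonym = None
        if kind == "symptom" and rng.random() < config.synonym_rate:
            synonym = name + rng.choice(vocab.AFFIX_CHARS)
            abstract += f"{name}又称{synonym}。"
        return _SiteEntity(name, kind, types, attrs, abstract,
                           synonym=synonym)

    entities: list[_SiteEntity] = []
    for name in symptom_names:
        entities.append(build_entity(name, "symptom"))
    for name in disease_names:
        entities.append(build_entity(name, "disease"))
    for name in med_tcm:
        entities.append(build_entity(name, "medicine", tcm_med=True))
    for name in med_west:
        entities.append(build_entity(name, "medicine", tcm_med=False))
    for name in department_names:
        entities.append(build_entity(name, "department"))
    for name in exam_names:
        entities.append(build_entity(name, "examination"))

    n_dup = math.floor(config.duplication_rate * len(entities))
    dup_idx = sorted(rng.sample(range(len(entities)), n_dup))
    dup_set = set(dup_idx)

    site_entities: dict[str, list[_SiteEntity]] = {site_a: [], site_b: []}
    duplicate_pairs: list[dict] = []
    all_names = {e.name for e in entities}

    for i, ent in enumerate(entities):
        if i in dup_set:
            site_entities[site_a].append(ent)
            # a twin may keep its own name (identical cross-site listing)
            # but must not collide with any other entity's name
            new_name, k = _perturb_name(
                rng, ent.name, all_names - {ent.name},
                config.edit_count_weights)
            all_names.add(new_name)
            attrs = dict(ent.attributes)
            pert_key = rng.choice(sorted(attrs))
            attrs[pert_key] = _perturb_value(
                rng, pert_key, attrs[pert_key], value_pools,
                config.value_sim_threshold)
            tcm_med = ConceptType.TCM_MEDICINE.value in ent.types
            types = list(ent.types)
            if ent.kind == "symptom":
                # the department attribute may have been perturbed; the
                # twin's subtype follows its own page evidence
                types = [ConceptType.SYMPTOM.value,
                         ConceptType.TCM_SYMPTOM.value
                         if any(m in attrs["相关科室"]
                                for m in vocab.TCM_DEPARTMENT_MARKERS)
                         else ConceptType.WESTERN_SYMPTOM.value]
            twin = _SiteEntity(
                new_name, ent.kind, types, attrs,
                _abstract_for(rng, new_name, ent.kind, attrs, tcm_med))
            site_entities[site_b].append(twin)
            duplicate_pairs.append({
                "site_a": site_a, "name_a": ent.name,
                "site_b": site_b, "name_b": new_name,
                "kind": ent.kind, "edits": k,
            })
        else:
            site = site_a if rng.random() < 0.5 else site_b
            site_entities[site].append(ent)

    # a few pages legitimately lack the property box
    for site in (site_a, site_b):
        ents = site_entities[site]
        candidates = [e for e in ents
                      if not any(e.name in (p["name_a"], p["name_b"])
                                 for p in duplicate_pairs)]
        n_nobox = math.floor(config.missing_box_rate * len(ents))
        for e in rng.sample(candidates, min(n_nobox, len(candidates))):
            e.has_box = False

    pages: dict[str, dict[str, str]] = {}
    wrappers: dict[str, WrapperConfig] = {}
    truth_sites: dict[str, dict] = {}
    synonym_pairs: list[list[str]] = []
    for site, layout, wcfg in zip(
            (site_a, site_b), _SITE_LAYOUTS, (_WRAPPER_A, _WRAPPER_B)):
        site_pages: dict[str, str] = {}
        site_truth: dict[str, dict] = {}
        by_kind: dict[str, list[tuple[str, str]]] = {}
        for e in site_entities[site]:
            rel = f"detail/{mint_entity_id(site, e.name)}.html"
            site_pages[rel] = layout(e)
            by_kind.setdefault(e.kind, []).append((e.name, rel))
            site_truth[e.name] = {
                "kind": e.kind,
                "types": sorted(e.types),
                "attributes": {ATTRIBUTE_MAP[k]: v
                               for k, v in e.attributes.items()}
                if e.has_box else {},
                "has_box": e.has_box,
                "detail": rel,
            }
            if e.synonym:
                synonym_pairs.append([site, e.name, e.synonym])
        for kind, items in sorted(by_kind.items()):
            lis = "".join(f'<li><a href="{rel}">{name}</a></li>'
                          for name, rel in items)
            site_pages[f"list_{kind}.html"] = (
                '<html><head><meta charset="utf-8"></head><body>'
                f'<ul class="entity-list">{lis}</ul></body></html>\n')
        pages[site] = site_pages
        wrappers[site] = WrapperConfig(
            site_id=site, attribute_map=dict(ATTRIBUTE_MAP), **wcfg)
        truth_sites[site] = site_truth

    truth = {
        "sites": truth_sites,
        "duplicate_pairs": duplicate_pairs,
        "synonym_pairs": synonym_pairs,
        "site_priority": [site_a, site_b],
    }
    return HealthcareFixture(pages, wrappers, truth)


def _abstract_for(rng: random.Random, name: str, kind: str,
                  attrs: Mapping[str, str], tcm_med: bool) -> str:
    if kind == "symptom":
        return (f"{name}是临床常见的症状表现，"
                f"多见于{attrs['相关疾病']}患者。")
    if kind == "disease":
        return f"{name}是一种常见疾病，应及早就医。"
    if kind == "medicine":
        cls = "中成药" if tcm_med else "化学药品"
        return f"{name}属于{cls}，用于治疗{attrs['相关疾病']}。"
    if kind == "department":
        return f"{name}负责相关疾病的诊治。"
    return f"{name}是常用的检查项目。"


def healthcare_seed_labels(truth: Mapping) -> dict[str, str]:
    """Entity name -> seven-way classifier label, from site ground truth."""
    labels: dict[str, str] = {}
    for site in sorted(truth["sites"]):
        for name, rec in truth["sites"][site].items():
            kind = rec["kind"]
            if kind == "medicine":
                lab = ("tcm" if ConceptType.TCM_MEDICINE.value in rec["types"]
                       else "western_medicine")
            else:
                lab = kind
            labels.setdefault(name, lab)
    return labels


# ===========================================================================
# Encyclopedia corpus
# ===========================================================================

_LOW_CATEGORIES = ("养生", "美容", "心理")

_LABEL_CATEGORIES = {
    "department": ("科室",),
    "symptom": ("症状", "医学术语"),
    "disease": ("疾病",),
    "tcm": ("中医", "中成药"),
    "western_medicine": ("药品", "药物"),
    "examination": ("检查",),
    "other": (),
}

_LIFESTYLE = ("晨跑锻炼", "足浴保健", "冥想放松", "健康食谱", "经络养生操",
              "面部护理", "心理疏导", "气功入门", "睡前拉伸", "四季进补")

_MED_CONTENT = "本品成分明确，用法与用量见说明书，规格多样，偶见不良反应。"
_DIS_CONTENT = ("病因尚不明确，需结合检查与鉴别诊断，"
                "发病机制复杂，临床表现多样，可对症缓解。")


@dataclass
class EncyclopediaFixture:
    pages: list[EncyclopediaPage]
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pages_jsonl(self.pages, out / "pages.jsonl")
        _write_json(self.truth, out / "ground_truth.json")


def _ency_page(rng: random.Random, name: str, label: str,
               feature_noise: float) -> EncyclopediaPage:
    cats = set(_LABEL_CATEGORIES[label])
    if label == "department":
        abstract = f"{name}是医院的临床科室。"
        content = "负责本专业疾病的诊治工作。"
    elif label == "symptom":
        abstract = f"{name}是患者常见的症状之一。"
        content = "常与多种疾病相关，必要时就诊。"
    elif label == "disease":
        abstract = f"{name}危害较大，应规范诊疗。"
        content = _DIS_CONTENT
    elif label == "tcm":
        abstract = f"{name}是传统中成药。"
        content = _MED_CONTENT
    elif label == "western_medicine":
        abstract = f"{name}为处方化学药品。"
        content = _MED_CONTENT
    elif label == "examination":
        abstract = f"{name}用于辅助诊断。"
        content = "检查前需遵医嘱准备。"
    else:  # other
        abstract = f"{name}是一种健康生活方式。"
        content = "长期坚持有益身心。"
    # field-signal noise: occasionally a page is irregular
    if rng.random() < feature_noise:
        abstract = "详见正文。"
    if rng.random() < feature_noise:
        content = ""
    if cats and rng.random() < feature_noise:
        cats.discard(sorted(cats)[rng.randrange(len(cats))])
    if rng.random() < feature_noise:
        cats.add(rng.choice(vocab.ENCYCLOPEDIA_KEYWORDS["category_words"]))
    return EncyclopediaPage(name=name, abstract=abstract, content=content,
                            categories=frozenset(cats))


def _ency_name(rng: random.Random, label: str, used: set[str]) -> str:
    for _ in range(200):
        if label == "department":
            name = rng.choice(vocab.BODY_PARTS) + "专" + "科"
            name = rng.choice(
                (rng.choice(vocab.DEPARTMENTS), name))
        elif label == "symptom":
            name = _symptom_name(rng)
        elif label == "disease":
            name = _disease_name(rng)
        elif label == "tcm":
            name = rng.choice(vocab.MEDICINES_TCM)[:-2] + rng.choice(_DOSE_FORMS)
        elif label == "western_medicine":
            name = rng.choice(vocab.MEDICINES_WESTERN) + rng.choice(_DOSE_FORMS)
        elif label == "examination":
            name = rng.choice(vocab.BODY_PARTS) + rng.choice(
                ("检查", "复查检查"))
        else:
            name = rng.choice(_LIFESTYLE)
        if name not in used:
            return name
    i = len(used)
    return f"{label}条目（{i}）"


def generate_encyclopedia(config: GeneratorConfig,
                          seeds: Mapping[str, str]) -> EncyclopediaFixture:
    """Encyclopedia corpus with seed/category structure and planted noise.

    ``seeds`` maps healthcare entity names to their seven-way label; up to
    ``ency_seeds_per_label`` of them per label receive pages, so every
    label's categories collect a seed ratio above the confidence threshold
    while the lifestyle categories of noise pages collect none.
    """
    rng = random.Random(config.seed + 1)
    labels = list(_LABEL_CATEGORIES)
    by_label: dict[str, list[str]] = {lab: [] for lab in labels}
    for name in sorted(seeds):
        by_label.setdefault(seeds[name], [])
        by_label[seeds[name]].append(name)

    pages: list[EncyclopediaPage] = []
    gold_labels: dict[str, str] = {}
    seed_names: list[str] = []
    used: set[str] = set()

    for label in labels:
        pool = by_label.get(label, [])
        chosen = pool[:config.ency_seeds_per_label]
        names = [n for n in chosen if n not in used]
        seed_names.extend(names)
        while len(names) < config.ency_pages_per_label:
            names.append(_ency_name(rng, label, used | set(names)))
        for name in names[:config.ency_pages_per_label]:
            used.add(name)
            pages.append(_ency_page(rng, name, label,
                                    config.ency_feature_noise))
            gold_labels[name] = label

    n_clean = len(pages)
    rate = config.ency_noise_rate
    n_noise = math.floor(rate * n_clean / (1.0 - rate)) if rate < 1 else 0
    noise_names: list[str] = []
    for i in range(n_noise):
        name = f"{rng.choice(_LIFESTYLE)}专题（{i}）"
        cats = {rng.choice(_LOW_CATEGORIES)}
        if rng.random() < 0.5:
            cats.add(rng.choice(("症状", "疾病")))  # mixed-category noise
        pages.append(EncyclopediaPage(
            name=name, abstract=f"{name}与健康生活相关。",
            content="内容与医学主题无关。", categories=frozenset(cats)))
        noise_names.append(name)
        gold_labels[name] = "noise"

    truth = {
        "labels": gold_labels,
        "clean": sorted(n for n, l in gold_labels.items() if l != "noise"),
        "noise": sorted(noise_names),
        "seeds_with_pages": sorted(seed_names),
        "low_categories": sorted(_LOW_CATEGORIES),
        "n_noise": n_noise,
    }
    return EncyclopediaFixture(pages, truth)


# ===========================================================================
# EMR corpus
# ===========================================================================

_S = None  # symptom slot marker

_WESTERN_TEMPLATES = (
    ("患者", "自述", _S, "。"),
    ("查体", "见", _S, "，", "伴", _S, "。"),
    ("患者", "出现", _S, "。"),
    ("查体", "见", _S, "。"),
)
_WESTERN_DISTRACTORS = (
    ("生命体征", "平稳", "。"),
    ("神志", "清楚", "。"),
    ("饮食", "正常", "。"),
    ("睡眠", "可", "。"),
)
_TCM_TEMPLATES = (
    ("辨证", "属", _S, "。"),
    ("证", "见", _S, "，", "兼", _S, "。"),
    ("舌脉", "提示", _S, "。"),
)
_TCM_DISTRACTORS = (
    ("舌", "淡红", "。"),
    ("脉", "弦", "。"),
    ("苔", "薄白", "。"),
)

_TARGET_SPEC = {
    "western": (("physical_examination", "antidiastole_western"),
                _WESTERN_TEMPLATES, _WESTERN_DISTRACTORS),
    "tcm": (("disease_analysis", "antidiastole_tcm"),
            _TCM_TEMPLATES, _TCM_DISTRACTORS),
}


def _mention(rng: random.Random, target: str) -> list[str]:
    """A symptom mention as a token list (40% two-token compounds)."""
    if target == "western":
        base = rng.choice(vocab.SYMPTOMS_WESTERN)
        if rng.random() < 0.4:
            return [rng.choice(vocab.MODIFIERS), base]
        return [base]
    base = rng.choice(vocab.SYMPTOMS_TCM)
    if rng.random() < 0.4:
        return [base, "证"]
    return [base]


@dataclass
class EMRFixture:
    """EMR records plus gold token sequences and dedup ground truth."""

    records: list[EMRecord]
    gold: dict[str, dict[str, list[LabeledSequence]]]  # target -> rid -> seqs
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "emr.jsonl", "w", encoding="utf-8") as fh:
            for r in self.records:
                fh.write(json.dumps(r.to_json(), ensure_ascii=False,
                                    sort_keys=True) + "\n")
        for target, per_rec in sorted(self.gold.items()):
            seqs = [ls for rid in (r.record_id for r in self.records)
                    for ls in per_rec[rid]]
            ner.write_conll(seqs, out / f"gold_{target}.conll")
        _write_json(self.truth, out / "ground_truth.json")


def generate_emr_corpus(config: GeneratorConfig,
                        symptom_lexicon: Mapping[str, tuple[str, ...]]
                        | None = None) -> EMRFixture:
    """Templated clinical records with gold BIO spans and planted
    within-record sentence duplication."""
    del symptom_lexicon  # the packaged lexicon is the default vocabulary
    rng = random.Random(config.seed + 2)
    records: list[EMRecord] = []
    gold: dict[str, dict[str, list[LabeledSequence]]] = {
        "western": {}, "tcm": {}}
    dedup_truth: dict[str, dict] = {}

    for ridx in range(config.n_records):
        rid = f"emr{ridx:05d}"
        field_texts: dict[str, str] = {}
        seen_sentences: set[str] = set()
        rec_all_sentences: list[str] = []
        rec_unique: list[str] = []

        for target, (fields, templates, distractors) in _TARGET_SPEC.items():
            field_gold: dict[str, list[LabeledSequence]] = {f: [] for f in fields}
            field_sents: dict[str, list[list[str]]] = {f: [] for f in fields}
            n_sym_sentences = max(1, config.symptoms_per_record - 1)
            plan = []
            for i in range(n_sym_sentences + 1):
                fld = fields[0] if i < n_sym_sentences else fields[1]
                plan.append((fld, "symptom"))
            if rng.random() < 0.7:
                plan.insert(rng.randrange(len(plan)),
                            (fields[rng.randrange(2)], "distractor"))

            for fld, kind in plan:
                tokens: list[str] | None = None
                labels: list[str] = []
                for _ in range(30):  # keep records duplicate-free by design
                    if kind == "distractor":
                        cand = list(rng.choice(distractors))
                        cand_labels = ["O"] * len(cand)
                    else:
                        tpl = rng.choice(templates)
                        cand, cand_labels = [], []
                        for item in tpl:
                            if item is _S:
                                mention = _mention(rng, target)
                                cand.extend(mention)
                                cand_labels.extend(
                                    ["B-SYM"] + ["I-SYM"] * (len(mention) - 1))
                            else:
                                cand.append(item)
                                cand_labels.append("O")
                    if "".join(cand) not in seen_sentences:
                        tokens, labels = cand, cand_labels
                        break
                if tokens is None:
                    continue
                sentence = "".join(tokens)
                seen_sentences.add(sentence)
                field_sents[fld].append(tokens)
                seq = TokenSequence(tokens, pos_tag(tokens))
                field_gold[fld].append(LabeledSequence(seq, labels))
            # gold order matches field concatenation (= dedup output order)
            gold[target][rid] = [ls for f in fields for ls in field_gold[f]]
            rec_unique.extend("".join(ls.seq.tokens)
                              for ls in gold[target][rid])

            # plant verbatim duplicates (copy-paste) inside the record
            all_field_sents = [(f, i) for f in fields
                               for i in range(len(field_sents[f]))]
            n_dup = math.floor(
                config.sentence_duplication_rate * len(all_field_sents))
            for f, i in rng.sample(all_field_sents, n_dup):
                field_sents[f].insert(i + 1, list(field_sents[f][i]))
            for f in fields:
                field_texts[f] = "".join(
                    "".join(toks) for toks in field_sents[f])
                rec_all_sentences.extend(
                    "".join(toks) for toks in field_sents[f])

        records.append(EMRecord(record_id=rid, **field_texts))
        dedup_truth[rid] = {
            "n_sentences": len(rec_all_sentences),
            "n_unique": len(rec_unique),
            "unique": rec_unique,
        }

    truth = {
        "record_ids": [r.record_id for r in records],
        "dedup": dedup_truth,
        "n_train": config.n_train_records,
        "gold_span_counts": {
            t: sum(sum(1 for lab in ls.labels if lab == "B-SYM")
                   for per in gold[t].values() for ls in per)
            for t in gold
        },
    }
    return EMRFixture(records, gold, truth)


def ner_recovery_experiment(fixture: EMRFixture, target: str,
                            n_train: int = 660, seed: int = 0,
                            label_noise: float = 0.05,
                            train_sizes: tuple[int, ...] = (),
                            l2: float = 0.1, max_iter: int = 150) -> dict:
    """Seeded split, noisy-label training, entity-level test evaluation.

    Optionally refits on nested subsets of the training records
    (``train_sizes``) to chart F1 against training volume.
    """
    rids = [r.record_id for r in fixture.records]
    train_ids, test_ids = ner.split_records(rids, n_train, seed)
    test_seqs = [ls for rid in test_ids for ls in fixture.gold[target][rid]]
    gold_spans = [ner.bio_to_spans(ls.labels, ls.seq.tokens)
                  for ls in test_seqs]

    def fit_eval(ids: list[str]) -> ner.NERMetrics:
        train = [ls for rid in ids for ls in fixture.gold[target][rid]]
        if label_noise:
            train = ner.apply_label_noise(train, label_noise, seed)
        model = ner.train_crf(train, target=target, seed=seed, l2=l2,
                              max_iter=max_iter)
        pred = [ner.decode(model, ls.seq) for ls in test_seqs]
        return ner.evaluate_ner(gold_spans, pred)

    metrics = fit_eval(train_ids)
    out = {
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f1": metrics.f1,
        "n_train_records": len(train_ids),
        "n_test_records": len(test_ids),
        "n_gold_spans": metrics.n_gold,
    }
    for n in train_sizes:
        m = fit_eval(train_ids[:n])
        out[f"f1_at_{n}"] = m.f1
    return out


# ===========================================================================
# Cross-lingual linking fixture
# ===========================================================================

_EN_BASES = (
    "fever", "headache", "cough", "nausea", "vomiting", "diarrhea",
    "dizziness", "fatigue", "insomnia", "tinnitus", "constipation",
    "palpitations", "sweating", "chills", "rash", "itching", "jaundice",
    "hiccup", "backache", "anorexia", "dyspnea", "numbness", "emaciation",
    "cyanosis", "edema", "hemoptysis", "photophobia", "polyuria", "dysuria",
    "hoarseness", "sneezing", "lacrimation", "bloating", "heartburn",
    "tremor", "stiffness", "weakness", "cramp", "wheeze", "snoring",
    "pallor", "flushing", "fainting", "malaise", "anxiety", "agitation",
    "drowsiness", "chest", "stomachache", "earache", "toothache", "myalgia",
    "arthralgia", "pruritus", "vertigo", "syncope",
)
_EN_MODIFIERS = ("acute", "chronic", "severe", "mild", "recurrent",
                 "persistent", "nocturnal", "intermittent")
_EXTRA_WORDS = ("syndrome", "disorder")

_SEMANTIC_TYPES = ("Sign or Symptom", "Finding", "Pathologic Function",
                   "Disease or Syndrome")
# cycle pattern: roughly half the links land outside Sign or Symptom/Finding
_SEMTYPE_CYCLE = ("Sign or Symptom", "Finding", "Pathologic Function",
                  "Sign or Symptom", "Disease or Syndrome",
                  "Pathologic Function", "Sign or Symptom", "Finding",
                  "Disease or Syndrome", "Sign or Symptom")


@dataclass
class LinkingFixture:
    lexicon: dict[str, str]
    concepts: list[ConceptRow]
    truth: dict

    def translator(self) -> LexiconTranslator:
        return LexiconTranslator(self.lexicon)

    def symptom_entities(self) -> list[Entity]:
        return [
            Entity(id=mint_entity_id("linkfix", name), name=name,
                   types={ConceptType.SYMPTOM}, sources={"linkfix"})
            for name in sorted(self.lexicon)
        ]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "lexicon.tsv", "w", encoding="utf-8") as fh:
            for zh in sorted(self.lexicon):
                fh.write(f"{zh}\t{self.lexicon[zh]}\n")
        with open(out / "concepts.tsv", "w", encoding="utf-8") as fh:
            for row in self.concepts:
                fh.write(f"{row.cui}\t{row.term}\t{row.semantic_type}\n")
        _write_json(self.truth, out / "ground_truth.json")


def _chinese_symptom_names(rng: random.Random, n: int) -> list[str]:
    base = list(vocab.SYMPTOMS_WESTERN + vocab.SYMPTOMS_TCM)
    names = base[:n]
    if len(names) < n:
        names += _unique_names(
            rng, n - len(names),
            lambda r: r.choice(vocab.MODIFIERS)
            + r.choice(vocab.SYMPTOMS_WESTERN))
        # regenerate on collision with the base block
        names = list(dict.fromkeys(names))
        while len(names) < n:
            cand = (rng.choice(vocab.MODIFIERS)
                    + rng.choice(vocab.BODY_PARTS)
                    + rng.choice(_DESCRIPTORS))
            if cand not in names:
                names.append(cand)
    return names[:n]


def generate_linking_fixture(config: GeneratorConfig) -> LinkingFixture:
    """Bilingual lexicon + concept table with exact matches, near misses
    (one extra or missing word, so Jaccard < 1) and distractor rows."""
    rng = random.Random(config.seed + 3)
    n_total = config.n_exact_links + config.n_near_miss
    combos = [(m, b) for b in _EN_BASES for m in _EN_MODIFIERS]
    chosen = rng.sample(combos, min(n_total, len(combos)))
    zh_names = _chinese_symptom_names(rng, n_total)

    lexicon: dict[str, str] = {}
    concepts: list[ConceptRow] = []
    gold_links: dict[str, list[str]] = {}
    near_miss: dict[str, str] = {}
    cui_counter = 1

    def next_cui() -> str:
        nonlocal cui_counter
        cui = f"C{cui_counter:07d}"
        cui_counter += 1
        return cui

    for i, ((mod, base), zh) in enumerate(zip(chosen, zh_names)):
        phrase = f"{mod} {base}"
        lexicon[zh] = phrase
        if i < config.n_exact_links:
            # bag-equal variants: case change, word-order swap, punctuation
            variant = rng.randrange(3)
            if variant == 0:
                term = f"{mod.capitalize()} {base.capitalize()}"
            elif variant == 1:
                term = f"{base} {mod}"
            else:
                term = f"{base.capitalize()}, {mod}"
            cui = next_cui()
            concepts.append(ConceptRow(
                cui, term, _SEMTYPE_CYCLE[i % len(_SEMTYPE_CYCLE)]))
            gold_links[zh] = [cui]
        else:
            # near miss: one extra word, or the modifier dropped
            if rng.random() < 0.5:
                term = f"{mod} {rng.choice(_EXTRA_WORDS)} {base}"
            else:
                term = base
            cui = next_cui()
            concepts.append(ConceptRow(
                cui, term, _SEMTYPE_CYCLE[i % len(_SEMTYPE_CYCLE)]))
            near_miss[zh] = cui

    unused = [c for c in combos if c not in set(chosen)]
    for mod, base in unused[:config.n_distractor_concepts]:
        concepts.append(ConceptRow(
            next_cui(), f"{mod} {base} {rng.choice(_EXTRA_WORDS)}",
            rng.choice(_SEMANTIC_TYPES)))

    semtype_counts: dict[str, int] = {}
    cui_types = {c.cui: c.semantic_type for c in concepts}
    for cuis in gold_links.values():
        for cui in cuis:
            t = cui_types[cui]
            semtype_counts[t] = semtype_counts.get(t, 0) + 1

    truth = {
        "gold_links": {zh: sorted(cuis) for zh, cuis in gold_links.items()},
        "near_miss_cuis": dict(sorted(near_miss.items())),
        "semantic_type_counts": dict(sorted(semtype_counts.items())),
        "n_exact": config.n_exact_links,
        "n_near_miss": config.n_near_miss,
    }
    return LinkingFixture(lexicon, concepts, truth)


# ===========================================================================
# Orchestration
# ===========================================================================

def generate_all(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Generate every fixture family under ``out_dir``; returns a manifest."""
    out = Path(out_dir)
    hc = generate_healthcare_site(config)
    hc.write(out / "healthcare")
    ency = generate_encyclopedia(config, healthcare_seed_labels(hc.truth))
    ency.write(out / "encyclopedia")
    emr = generate_emr_corpus(config)
    emr.write(out / "emr")
    link = generate_linking_fixture(config)
    link.write(out / "linking")
    manifest = {
        "config": asdict(config),
        "healthcare_sites": sorted(hc.pages),
        "n_encyclopedia_pages": len(ency.pages),
        "n_emr_records": len(emr.records),
        "n_concepts": len(link.concepts),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
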