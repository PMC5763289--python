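"""Shared Chinese medical vocabulary and default keyword configuration.

The word lists below serve two purposes: they are the default keyword
configuration for the rule-based components (subtype heuristics, the
encyclopedia page featurizer, Hearst-style synonym patterns), and they are
the lexical raw material for the synthetic fixture generators.  English
glosses are given in comments where the surface form matters.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Entity name pools (used by the synthetic generators and the segmenter)
# ---------------------------------------------------------------------------

SYMPTOMS_WESTERN: tuple[str, ...] = (
    "头痛", "发热", "咳嗽", "恶心", "呕吐", "腹泻", "眩晕", "乏力", "盗汗",
    "心悸", "气短", "畏寒", "失眠", "耳鸣", "便秘", "腹痛", "胸闷", "咽痛",
    "鼻塞", "流涕", "水肿", "皮疹", "瘙痒", "黄疸", "咯血", "呃逆", "腰痛",
    "关节痛", "食欲不振", "呼吸困难", "视物模糊", "肢体麻木", "多汗", "消瘦",
    "发绀",
)

SYMPTOMS_TCM: tuple[str, ...] = (
    "阴虚", "气滞", "血瘀", "阳亢", "湿热", "气虚", "痰湿", "肝郁", "脾虚",
    "肾虚", "血虚", "阳虚", "心火旺", "肝阳上亢", "气血两虚", "痰热内扰",
    "风寒束表", "湿困脾胃", "肝肾阴虚", "心脾两虚",
)

DISEASES: tuple[str, ...] = (
    "感冒", "肺炎", "胃炎", "高血压", "糖尿病", "支气管炎", "哮喘", "肝炎",
    "肾炎", "贫血", "中耳炎", "咽喉炎", "关节炎", "偏头痛", "胃溃疡",
    "心绞痛", "脑梗死", "肺结核", "扁桃体炎", "胆囊炎",
)

MEDICINES_TCM: tuple[str, ...] = (
    "板蓝根颗粒", "藿香正气水", "六味地黄丸", "感冒清热颗粒", "川贝枇杷膏",
    "云南白药", "复方丹参片", "银翘解毒片", "逍遥丸", "保和丸",
)

MEDICINES_WESTERN: tuple[str, ...] = (
    "阿司匹林", "布洛芬", "对乙酰氨基酚", "阿莫西林", "头孢克肟", "奥美拉唑",
    "氯雷他定", "硝苯地平", "二甲双胍", "辛伐他汀",
)

DEPARTMENTS: tuple[str, ...] = (
    "内科", "外科", "神经内科", "消化内科", "呼吸内科", "心血管内科",
    "皮肤科", "耳鼻喉科", "儿科", "妇科", "骨科", "眼科",
)

DEPARTMENTS_TCM: tuple[str, ...] = (
    "中医内科", "中医外科", "中医骨伤科", "针灸科",
)

EXAMINATIONS: tuple[str, ...] = (
    "血常规", "尿常规", "胸部CT", "腹部B超", "心电图", "胃镜检查",
    "血糖检测", "肝功能检查", "脑电图", "骨密度检查",
)

# Modifiers and body parts used to synthesize compound entity names.
MODIFIERS: tuple[str, ...] = (
    "急性", "慢性", "阵发性", "持续性", "反复", "夜间", "晨起", "间歇性",
)

BODY_PARTS: tuple[str, ...] = (
    "头部", "胸部", "腹部", "腰部", "四肢", "咽部", "关节", "背部",
)

# Characters used as benign affix perturbations of duplicated entity names
# across pseudo-sources (the kind of variation real listing sites show:
# "头痛" vs "头痛症").
AFFIX_CHARS: tuple[str, ...] = ("症", "感", "性", "样", "型")

# ---------------------------------------------------------------------------
# Default keyword configuration for the rule-based classifiers
# ---------------------------------------------------------------------------

#: Substrings of a department name that mark it as a TCM department.  The
#: English forms are included because translated department names occur in
#: bilingual material.
TCM_DEPARTMENT_MARKERS: tuple[str, ...] = ("中医", "TCM", "Traditional Chinese")

#: Keywords whose presence in a medicine description marks it as TCM
#: (Chinese patent / herbal medicine) or as Western medicine
#: (pharmaceuticals, chemicals).
MEDICINE_TCM_KEYWORDS: tuple[str, ...] = (
    "中成药", "中草药", "草药", "Chinese patent medicine", "herbal medicine",
)
MEDICINE_WESTERN_KEYWORDS: tuple[str, ...] = (
    "化学药品", "化学制剂", "抗生素", "pharmaceuticals", "chemicals",
)

#: Per-field keyword lists driving the encyclopedia page featurizer:
#: name suffixes (department/disease/inflammation/tumour/syndrome/
#: examination), abstract cue words, content cue words for medicines and
#: diseases, full-text TCM cues, and category cue words.
ENCYCLOPEDIA_KEYWORDS: dict[str, tuple[str, ...]] = {
    # department, disease, inflammation, tumour, syndrome, examination
    "name_suffixes": ("科", "病", "炎", "瘤", "综合征", "检查"),
    # symptom, syndrome, symptoms of illness, disease name of TCM
    "abstract_words": ("症状", "综合征", "病症", "中医病名"),
    # function, specification, adverse reaction, side effect, component,
    # usage, dosage
    "content_medicine_words": (
        "功能", "规格", "不良反应", "副作用", "成分", "用法", "用量",
    ),
    # cause, examination, antidiastole, diagnosis, mitigation, pathogenesis,
    # clinical manifestation
    "content_disease_words": (
        "病因", "检查", "鉴别", "诊断", "缓解", "发病机制", "临床表现",
    ),
    # Chinese patent medicine, Chinese herbal medicine
    "fulltext_words": ("中成药", "中草药"),
    # medicine, disease, TCM, drug, Chinese patent medicine, symptom
    "category_words": ("药品", "疾病", "中医", "药物", "中成药", "症状"),
}

#: Synonym extraction patterns.  Each template has exactly two entity slots;
#: the connector between the slots is matched literally within one sentence.
DEFAULT_SYNONYM_PATTERNS: tuple[str, ...] = (
    "[entity1]又称[entity2]",
    "[entity1]俗称[entity2]",
    "[entity1]也叫[entity2]",
    "[entity1] is known as [entity2]",
)

# ---------------------------------------------------------------------------
# POS lexicon for the lightweight rule tagger
# ---------------------------------------------------------------------------

_VERBS = ("自述", "出现", "诉", "见", "伴", "提示", "属", "兼", "查体", "辨证")
_FUNCTION = ("无", "明显", "轻度", "较", "稍", "仍")
_NOUNS_EXTRA = ("患者", "舌脉", "生命体征", "神志", "饮食", "睡眠", "证")

PUNCTUATION = "。！？；，、：（）"


def default_pos_lexicon() -> dict[str, str]:
    """Word -> POS-tag mapping covering the packaged vocabulary.

    Tags follow the usual one-letter Chinese tagset: n(oun), v(erb),
    a(djective modifier), d (adverb/function word), w (punctuation).
    """
    lex: dict[str, str] = {}
    for words in (
        SYMPTOMS_WESTERN, SYMPTOMS_TCM, DISEASES, MEDICINES_TCM,
        MEDICINES_WESTERN, DEPARTMENTS, DEPARTMENTS_TCM, EXAMINATIONS,
        BODY_PARTS, _NOUNS_EXTRA,
    ):
        for w in words:
            lex[w] = "n"
    for w in MODIFIERS:
        lex[w] = "a"
    for w in _VERBS:
        lex[w] = "v"
    for w in _FUNCTION:
        lex[w] = "d"
    for ch in PUNCTUATION:
        lex[ch] = "w"
    return lex


def default_segmentation_lexicon() -> frozenset[str]:
    """All multi-character words the maximum-matching segmenter should know."""
    return frozenset(default_pos_lexicon())
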