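"""CRF-based symptom recognition in EMR free text.

Pipeline: select the narrative fields relevant to the target symptom class
(Western medicine: physical examination and the Western differential
diagnosis; TCM: disease analysis and the TCM differential), deduplicate
sentences within each record (EMR text is heavily copy-pasted), segment and
POS-tag the sentences, extract the 37 context-window feature templates per
token (literal and POS uni/bi/trigrams over a ±3 window plus the position
index), and train one linear-chain CRF per symptom class with BIO labels
(B-SYM/I-SYM/O).  Two independent models mirror the separate field
selection for the two symptom classes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, TypeVar

from . import vocab
from .crf import LinearChainCRF

__all__ = [
    "EMRecord",
    "TokenSequence",
    "LabeledSequence",
    "Span",
    "NERModel",
    "select_fields",
    "split_sentences",
    "dedup_sentences",
    "MaxMatchSegmenter",
    "CharSegmenter",
    "pos_tag",
    "extract_crf_features",
    "sequence_features",
    "train_crf",
    "decode",
    "bio_to_spans",
    "spans_to_bio",
    "evaluate_ner",
    "split_records",
    "apply_label_noise",
    "read_conll",
    "write_conll",
]

PAD = "<PAD>"
WINDOW = 3
SENTENCE_TERMINATORS = "。！？；"

TARGET_FIELDS: dict[str, tuple[str, ...]] = {
    "western": ("physical_examination", "antidiastole_western"),
    "tcm": ("disease_analysis", "antidiastole_tcm"),
}

T = TypeVar("T")


@dataclass
class EMRecord:
    """One EMR with the four narrative fields the extractor reads."""

    record_id: str
    physical_examination: str = ""
    antidiastole_western: str = ""
    disease_analysis: str = ""
    antidiastole_tcm: str = ""

    def to_json(self) -> dict:
        return {
            "record_id": self.record_id,
            "physical_examination": self.physical_examination,
            "antidiastole_western": self.antidiastole_western,
            "disease_analysis": self.disease_analysis,
            "antidiastole_tcm": self.antidiastole_tcm,
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "EMRecord":
        return cls(**{k: doc.get(k, "") for k in (
            "record_id", "physical_examination", "antidiastole_western",
            "disease_analysis", "antidiastole_tcm")})


@dataclass
class TokenSequence:
    """A segmented, POS-tagged sentence with its provenance."""

    tokens: list[str]
    pos_tags: list[str]
    origin: tuple[str, str, int] | None = None  # (record_id, field, index)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.pos_tags):
            raise ValueError("tokens and pos_tags must be parallel")
        if any(not t for t in self.tokens):
            raise ValueError("tokens must be non-empty strings")


@dataclass
class LabeledSequence:
    seq: TokenSequence
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.seq.tokens):
            raise ValueError("labels must parallel tokens")
        prev = "O"
        for lab in self.labels:
            if lab not in ("B-SYM", "I-SYM", "O"):
                raise ValueError(f"unknown BIO label {lab!r}")
            if lab == "I-SYM" and prev == "O":
                raise ValueError("I-SYM may not follow O or sequence start")
            prev = lab


@dataclass(frozen=True, order=True)
class Span:
    """Half-open token span [start, stop) with its surface string."""

    start: int
    stop: int
    text: str = field(compare=False, default="")


# ---------------------------------------------------------------------------
# Field selection and sentence handling
# ---------------------------------------------------------------------------

def select_fields(record: EMRecord, target: str) -> list[str]:
    """Texts relevant to the target symptom class; empty fields dropped."""
    if target not in TARGET_FIELDS:
        raise ValueError(f"unknown target {target!r}; expected one of "
                         f"{sorted(TARGET_FIELDS)}")
    return [t for f in TARGET_FIELDS[target]
            if (t := getattr(record, f))]


def split_sentences(text: str,
                    terminators: str = SENTENCE_TERMINATORS) -> list[str]:
    out: list[str] = []
    buf: list[str] = []
    for ch in text:
        buf.append(ch)
        if ch in terminators:
            s = "".join(buf).strip()
            if s:
                out.append(s)
            buf = []
    tail = "".join(buf).strip()
    if tail:
        out.append(tail)
    return out


def dedup_sentences(texts: Iterable[str],
                    terminators: str = SENTENCE_TERMINATORS) -> list[str]:
    """Within-record sentence deduplication, keeping first occurrences.

    EMR narratives repeat sentences verbatim (copy-paste); each distinct
    sentence string of a record is kept once, in original order.
    Idempotent, and never increases the sentence count.
    """
    seen: set[str] = set()
    out: list[str] = []
    for text in texts:
        for sent in split_sentences(text, terminators):
            if sent not in seen:
                seen.add(sent)
                out.append(sent)
    return out


# ---------------------------------------------------------------------------
# Segmentation and POS tagging
# ---------------------------------------------------------------------------

class MaxMatchSegmenter:
    """Greedy forward maximum matching over a word lexicon; characters not
    starting any known word become single-character tokens."""

    mode = "word"

    def __init__(self, lexicon: Iterable[str] | None = None):
        self.lexicon = frozenset(
            lexicon if lexicon is not None
            else vocab.default_segmentation_lexicon())
        self.max_len = max((len(w) for w in self.lexicon), default=1)

    def __call__(self, text: str) -> list[str]:
        tokens: list[str] = []
        i = 0
        while i < len(text):
            for n in range(min(self.max_len, len(text) - i), 1, -1):
                if text[i:i + n] in self.lexicon:
                    tokens.append(text[i:i + n])
                    i += n
                    break
            else:
                tokens.append(text[i])
                i += 1
        return tokens


class CharSegmenter:
    """Character-level fallback (clinical segmenters vary; characters do
    not)."""

    mode = "char"

    def __call__(self, text: str) -> list[str]:
        return list(text)


def pos_tag(tokens: Sequence[str],
            lexicon: Mapping[str, str] | None = None) -> list[str]:
    """Rule/lexicon POS tagging: dictionary lookup, punctuation -> ``w``,
    unknown words -> ``x``."""
    lex = lexicon if lexicon is not None else _default_pos_lexicon()
    tags = []
    for tok in tokens:
        tag = lex.get(tok)
        if tag is None:
            tag = "w" if all(c in vocab.PUNCTUATION for c in tok) else "x"
        tags.append(tag)
    return tags


_POS_CACHE: dict[str, str] | None = None


def _default_pos_lexicon() -> dict[str, str]:
    global _POS_CACHE
    if _POS_CACHE is None:
        _POS_CACHE = vocab.default_pos_lexicon()
    return _POS_CACHE


def make_sequence(sentence: str,
                  segmenter: Callable[[str], list[str]] | None = None,
                  pos_lexicon: Mapping[str, str] | None = None,
                  origin: tuple[str, str, int] | None = None) -> TokenSequence:
    seg = segmenter if segmenter is not None else MaxMatchSegmenter()
    tokens = seg(sentence)
    return TokenSequence(tokens, pos_tag(tokens, pos_lexicon), origin)


def record_sequences(record: EMRecord, target: str,
                     segmenter: Callable[[str], list[str]] | None = None,
                     ) -> list[TokenSequence]:
    """Field selection + dedup + segmentation for one record."""
    sentences = dedup_sentences(select_fields(record, target))
    return [make_sequence(s, segmenter, origin=(record.record_id, target, i))
            for i, s in enumerate(sentences)]


# ---------------------------------------------------------------------------
# Feature templates: 37 per position
# ---------------------------------------------------------------------------

def extract_crf_features(seq: TokenSequence, i: int) -> list[str]:
    """Context-window templates at position ``i``.

    Exactly 37 features: 7 literal unigrams, 6 literal bigrams, 5 literal
    trigrams over the ±3 window; the position index; and the same 18 n-gram
    templates over POS tags.  Off-sequence window slots read a padding
    token, so the count is constant at every position.
    """
    if not 0 <= i < len(seq.tokens):
        raise IndexError(f"position {i} out of range")
    w = WINDOW
    toks = [PAD] * w + list(seq.tokens) + [PAD] * w
    poss = [PAD] * w + list(seq.pos_tags) + [PAD] * w
    j = i + w
    feats: list[str] = []
    for k in range(-w, w + 1):
        feats.append(f"U{k}={toks[j + k]}")
    for k in range(-w, w):
        feats.append(f"B{k}={toks[j + k]}|{toks[j + k + 1]}")
    for k in range(-w, w - 1):
        feats.append(
            f"T{k}={toks[j + k]}|{toks[j + k + 1]}|{toks[j + k + 2]}")
    feats.append(f"IDX={i}")
    for k in range(-w, w + 1):
        feats.append(f"PU{k}={poss[j + k]}")
    for k in range(-w, w):
        feats.append(f"PB{k}={poss[j + k]}|{poss[j + k + 1]}")
    for k in range(-w, w - 1):
        feats.append(
            f"PT{k}={poss[j + k]}|{poss[j + k + 1]}|{poss[j + k + 2]}")
    return feats


def sequence_features(seq: TokenSequence) -> list[list[str]]:
    return [extract_crf_features(seq, i) for i in range(len(seq.tokens))]


# ---------------------------------------------------------------------------
# Training and decoding
# ---------------------------------------------------------------------------

@dataclass
class NERModel:
    crf: LinearChainCRF
    target: str
    segmenter_mode: str = "word"


def train_crf(data: Sequence[LabeledSequence], target: str = "western",
              seed: int = 0, l2: float = 0.1, max_iter: int = 200,
              segmenter_mode: str = "word") -> NERModel:
    """Fit a linear-chain CRF on BIO-labeled sequences.

    Training data must contain at least one positive (B-SYM) label.
    Deterministic given the data order and seed.
    """
    if target not in TARGET_FIELDS:
        raise ValueError(f"unknown target {target!r}")
    if not any("B-SYM" in ls.labels for ls in data):
        raise ValueError("training data contains no symptom spans")
    del seed  # the optimizer is deterministic; kept for interface stability
    X = [sequence_features(ls.seq) for ls in data]
    y = [list(ls.labels) for ls in data]
    crf = LinearChainCRF(l2=l2, max_iter=max_iter).fit(X, y)
    return NERModel(crf=crf, target=target, segmenter_mode=segmenter_mode)


def bio_to_spans(labels: Sequence[str],
                 tokens: Sequence[str] | None = None) -> list[Span]:
    """Spans from BIO labels; an orphan I (after O or at the start) is
    repaired by treating it as B — the least destructive standard repair."""
    spans: list[Span] = []
    start: int | None = None
    for i, lab in enumerate(labels):
        if lab == "B-SYM" or (lab == "I-SYM" and start is None):
            if start is not None:
                spans.append(_mk_span(start, i, tokens))
            start = i
        elif lab == "O":
            if start is not None:
                spans.append(_mk_span(start, i, tokens))
                start = None
    if start is not None:
        spans.append(_mk_span(start, len(labels), tokens))
    return spans


def _mk_span(start: int, stop: int, tokens: Sequence[str] | None) -> Span:
    text = "".join(tokens[start:stop]) if tokens is not None else ""
    return Span(start, stop, text)


def spans_to_bio(spans: Iterable[Span], length: int) -> list[str]:
    labels = ["O"] * length
    for sp in spans:
        labels[sp.start] = "B-SYM"
        for i in range(sp.start + 1, sp.stop):
            labels[i] = "I-SYM"
    return labels


def decode(model: NERModel, seq: TokenSequence) -> list[Span]:
    """Predicted symptom spans for one sentence (sorted, non-overlapping,
    in bounds by construction)."""
    labels = model.crf.predict(sequence_features(seq))
    return bio_to_spans(labels, seq.tokens)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NERMetrics:
    """Entity-level exact-match metrics; ``None`` marks an undefined value
    (zero denominator), deliberately distinct from 0."""

    precision: float | None
    recall: float | None
    f1: float | None
    n_gold: int
    n_predicted: int
    n_correct: int


def evaluate_ner(gold: Sequence[Sequence[Span]],
                 predicted: Sequence[Sequence[Span]]) -> NERMetrics:
    """Exact span-match precision/recall/F1 over parallel sentence lists."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted sentence counts differ")
    n_gold = n_pred = n_correct = 0
    for g, p in zip(gold, predicted):
        gset = {(s.start, s.stop) for s in g}
        pset = {(s.start, s.stop) for s in p}
        n_gold += len(gset)
        n_pred += len(pset)
        n_correct += len(gset & pset)
    precision = n_correct / n_pred if n_pred else None
    recall = n_correct / n_gold if n_gold else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return NERMetrics(precision, recall, f1, n_gold, n_pred, n_correct)


# ---------------------------------------------------------------------------
# Protocol utilities
# ---------------------------------------------------------------------------

def split_records(items: Sequence[T], n_train: int,
                  seed: int) -> tuple[list[T], list[T]]:
    """Seeded-shuffle split (e.g. 660 training records out of 1000)."""
    if not 0 < n_train < len(items):
        raise ValueError("n_train must be within (0, len(items))")
    order = list(items)
    random.Random(seed).shuffle(order)
    return order[:n_train], order[n_train:]


def apply_label_noise(data: Sequence[LabeledSequence], rate: float,
                      seed: int) -> list[LabeledSequence]:
    """Simulate imperfect annotation: each gold span is dropped (labels set
    to O) independently with probability ``rate``."""
    rng = random.Random(seed)
    noisy = []
    for ls in data:
        spans = [sp for sp in bio_to_spans(ls.labels, ls.seq.tokens)
                 if rng.random() >= rate]
        noisy.append(LabeledSequence(
            ls.seq, spans_to_bio(spans, len(ls.labels))))
    return noisy


# ---------------------------------------------------------------------------
# CoNLL-style two-column I/O (token TAB bio-label; blank line = boundary)
# ---------------------------------------------------------------------------

def write_conll(data: Iterable[LabeledSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ls in data:
            for tok, lab in zip(ls.seq.tokens, ls.labels):
                fh.write(f"{tok}\t{lab}\n")
            fh.write("\n")


def read_conll(path: str | Path,
               pos_lexicon: Mapping[str, str] | None = None,
               ) -> list[LabeledSequence]:
    out: list[LabeledSequence] = []
    toks: list[str] = []
    labs: list[str] = []

    def flush() -> None:
        nonlocal toks, labs
        if toks:
            seq = TokenSequence(toks, pos_tag(toks, pos_lexicon))
            out.append(LabeledSequence(seq, labs))
            toks, labs = [], []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                flush()
                continue
            tok, lab = line.split("\t")
            toks.append(tok)
            labs.append(lab)
    flush()
    return out
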