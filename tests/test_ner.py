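"""EMR field selection, dedup, features, CRF training/decoding, metrics."""

import pytest
from hypothesis import given, settings, strategies as st

from symptomkb import ner
from symptomkb.ner import (
    CharSegmenter,
    EMRecord,
    LabeledSequence,
    MaxMatchSegmenter,
    Span,
    TokenSequence,
    bio_to_spans,
    decode,
    dedup_sentences,
    evaluate_ner,
    extract_crf_features,
    pos_tag,
    select_fields,
    spans_to_bio,
    split_records,
    train_crf,
)


def _seq(tokens, labels=None):
    ts = TokenSequence(list(tokens), pos_tag(tokens))
    return ts if labels is None else LabeledSequence(ts, list(labels))


RECORD = EMRecord(
    record_id="r1",
    physical_examination="查体见发热。",
    antidiastole_western="考虑感冒。",
    disease_analysis="证属阴虚。",
    antidiastole_tcm="辨证属气滞。",
)


class TestFieldSelection:
    def test_tcm_selects_analysis_and_tcm_antidiastole(self):
        assert select_fields(RECORD, "tcm") == ["证属阴虚。", "辨证属气滞。"]

    def test_western_selects_exam_and_western_antidiastole(self):
        assert select_fields(RECORD, "western") == ["查体见发热。", "考虑感冒。"]

    def test_empty_fields_dropped(self):
        rec = EMRecord(record_id="r2", physical_examination="查体见发热。")
        assert select_fields(rec, "western") == ["查体见发热。"]
        assert select_fields(rec, "tcm") == []

    def test_unknown_target_errors(self):
        with pytest.raises(ValueError):
            select_fields(RECORD, "both")


class TestDedup:
    def test_keep_first_occurrence(self):
        assert dedup_sentences(["甲。乙。甲。"]) == ["甲。", "乙。"]

    def test_all_unique_unchanged(self):
        assert dedup_sentences(["甲。", "乙。丙。"]) == ["甲。", "乙。", "丙。"]

    def test_idempotent_and_never_grows(self):
        texts = ["甲。乙。", "乙。丙。甲。"]
        once = dedup_sentences(texts)
        assert dedup_sentences(once) == once
        assert len(once) <= sum(len(ner.split_sentences(t)) for t in texts)

    def test_planted_duplicates_removed_exactly(self, emr_fixture):
        for rec in emr_fixture.records:
            truth = emr_fixture.truth["dedup"][rec.record_id]
            got = dedup_sentences(select_fields(rec, "western")) + \
                dedup_sentences(select_fields(rec, "tcm"))
            assert got == truth["unique"]
            assert len(got) == truth["n_unique"] <= truth["n_sentences"]


class TestSegmentation:
    def test_max_match_prefers_longest_word(self):
        seg = MaxMatchSegmenter(["头痛", "发热", "头"])
        assert seg("头痛发热") == ["头痛", "发热"]

    def test_unknown_chars_become_single_tokens(self):
        seg = MaxMatchSegmenter(["发热"])
        assert seg("Z发热?") == ["Z", "发热", "?"]

    def test_char_fallback(self):
        assert CharSegmenter()("头痛") == ["头", "痛"]

    def test_pos_tags_parallel_and_lexical(self):
        tokens = ["患者", "自述", "头痛", "。"]
        tags = pos_tag(tokens)
        assert len(tags) == len(tokens)
        assert tags[1] == "v" and tags[3] == "w"


class TestFeatureTemplates:
    def test_constant_feature_count(self):
        seq = _seq(["患者", "自述", "头痛", "，", "伴", "发热", "。"])
        for i in range(len(seq.tokens)):
            assert len(extract_crf_features(seq, i)) == 37

    def test_single_token_sequence_padded(self):
        feats = extract_crf_features(_seq(["发热"]), 0)
        assert len(feats) == 37
        assert "U-1=<PAD>" in feats and "U1=<PAD>" in feats
        assert "U0=发热" in feats

    def test_start_boundary_padding(self):
        feats = extract_crf_features(_seq(["甲", "乙", "丙", "丁"]), 0)
        for k in (-1, -2, -3):
            assert f"U{k}=<PAD>" in feats

    def test_bigram_concatenates_neighbours(self):
        seq = _seq(["患者", "自述", "头痛", "，", "伴", "发热", "。"])
        feats = extract_crf_features(seq, 3)
        assert "B-1=头痛|，" in feats
        assert "T-1=头痛|，|伴" in feats
        assert "IDX=3" in feats


class TestSpans:
    def test_bio_semantics(self):
        spans = bio_to_spans(["O", "B-SYM", "I-SYM", "O"],
                             ["查体", "阵发性", "头痛", "。"])
        assert spans == [Span(1, 3)]
        assert spans[0].text == "阵发性头痛"

    def test_all_outside(self):
        assert bio_to_spans(["O", "O"]) == []

    def test_orphan_inside_promoted(self):
        assert bio_to_spans(["O", "I-SYM", "I-SYM"]) == [Span(1, 3)]

    def test_round_trip(self):
        labels = ["O", "B-SYM", "I-SYM", "O", "B-SYM"]
        assert spans_to_bio(bio_to_spans(labels), 5) == labels

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["B-SYM", "I-SYM", "O"]), max_size=12))
    def test_spans_always_well_formed(self, labels):
        spans = bio_to_spans(labels)
        for a, b in zip(spans, spans[1:]):
            assert a.stop <= b.start  # sorted, non-overlapping
        for sp in spans:
            assert 0 <= sp.start < sp.stop <= len(labels)


class TestMetrics:
    def test_identity_is_perfect(self):
        gold = [[Span(0, 2)], [Span(1, 2)]]
        m = evaluate_ner(gold, gold)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_empty_prediction_undefined_precision(self):
        m = evaluate_ner([[Span(0, 1)]], [[]])
        assert m.recall == 0.0 and m.precision is None and m.f1 is None

    def test_hand_counted_half(self):
        gold = [[Span(0, 2), Span(5, 6)]]
        pred = [[Span(0, 2), Span(4, 6)]]
        m = evaluate_ner(gold, pred)
        assert m.precision == 0.5 and m.recall == 0.5


class TestCRF:
    def test_memorizable_literals_recalled(self):
        train = [_seq(["查体", "见", s, "。"], ["O", "O", "B-SYM", "O"])
                 for s in ("发热", "头痛", "盗汗", "耳鸣", "水肿")]
        train += [_seq(["生命体征", "平稳", "。"], ["O", "O", "O"])] * 3
        model = train_crf(train, target="western", max_iter=80)
        for s in ("发热", "头痛", "盗汗"):
            seq = _seq(["患者", "自述", s, "，", "明显", "。"])
            assert Span(2, 3) in decode(model, seq)

    def test_resubstitution_ceiling(self, emr_fixture):
        data = [ls for rid in emr_fixture.truth["record_ids"][:30]
                for ls in emr_fixture.gold["western"][rid]]
        model = train_crf(data, target="western", max_iter=120)
        gold = [bio_to_spans(ls.labels, ls.seq.tokens) for ls in data]
        pred = [decode(model, ls.seq) for ls in data]
        m = evaluate_ner(gold, pred)
        assert m.f1 == pytest.approx(1.0, abs=0.01)

    def test_planted_two_span_sentence_decoded(self, emr_fixture):
        data = [ls for rid in emr_fixture.truth["record_ids"]
                for ls in emr_fixture.gold["tcm"][rid]]
        model = train_crf(data[:80], target="tcm", max_iter=120)
        two_span = next(ls for ls in data[:80]
                        if sum(l == "B-SYM" for l in ls.labels) == 2)
        assert decode(model, two_span.seq) == \
            bio_to_spans(two_span.labels, two_span.seq.tokens)

    def test_no_positive_labels_errors(self):
        data = [_seq(["平稳", "。"], ["O", "O"])]
        with pytest.raises(ValueError):
            train_crf(data, target="western")

    def test_training_deterministic(self):
        train = [_seq(["查体", "见", s, "。"], ["O", "O", "B-SYM", "O"])
                 for s in ("发热", "头痛")]
        m1 = train_crf(train, target="western", max_iter=40)
        m2 = train_crf(train, target="western", max_iter=40)
        assert (m1.crf.W_ == m2.crf.W_).all()
        assert (m1.crf.trans_ == m2.crf.trans_).all()


class TestProtocol:
    def test_split_sizes_and_determinism(self):
        items = list(range(1000))
        train, test = split_records(items, 660, seed=5)
        assert len(train) == 660 and len(test) == 340
        assert split_records(items, 660, seed=5) == (train, test)
        assert sorted(train + test) == items

    def test_label_noise_drops_spans(self):
        data = [_seq(["查体", "见", "发热", "。"], ["O", "O", "B-SYM", "O"])
                for _ in range(200)]
        noisy = ner.apply_label_noise(data, 0.5, seed=0)
        kept = sum("B-SYM" in ls.labels for ls in noisy)
        assert 60 < kept < 140  # roughly half survive
        assert ner.apply_label_noise(data, 0.0, seed=0)[0].labels == \
            data[0].labels


def test_conll_round_trip(tmp_path, emr_fixture):
    data = [ls for rid in emr_fixture.truth["record_ids"][:5]
            for ls in emr_fixture.gold["western"][rid]]
    path = tmp_path / "g.conll"
    ner.write_conll(data, path)
    again = ner.read_conll(path)
    assert [(ls.seq.tokens, ls.labels) for ls in again] == \
        [(ls.seq.tokens, ls.labels) for ls in data]


def test_labeled_sequence_rejects_invalid_transitions():
    with pytest.raises(ValueError):
        _seq(["甲", "乙"], ["O", "I-SYM"])
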