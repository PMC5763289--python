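"""Seed-category bootstrapping and the seven-label page classifier."""

import pytest

from symptomkb import synth
from symptomkb.encyclopedia import (
    EncyclopediaPage,
    category_members,
    classify_entity,
    collect_seed_categories,
    cross_validate_classifier,
    feature_matrix,
    feature_names,
    featurize_page,
    filter_noise_entities,
    low_confidence_categories,
    refine_symptom_subtype,
    score_categories,
    train_entity_classifier,
)
from symptomkb.schema import ConceptType


def _page(name, abstract="", content="", cats=(), full_text=None):
    return EncyclopediaPage(name=name, abstract=abstract, content=content,
                            full_text=full_text, categories=frozenset(cats))


class TestSeedCategories:
    def test_union_of_seed_page_categories(self):
        pages = {"a": _page("a", cats={"A", "B"}),
                 "b": _page("b", cats={"B", "C"})}
        assert collect_seed_categories(["a", "b"], pages) == {"A", "B", "C"}

    def test_seeds_without_pages_skipped(self):
        assert collect_seed_categories(["x", "y"], {}) == set()

    def test_planted_seed_categories_recovered(self, ency_fixture,
                                               healthcare_fixture):
        seeds = synth.healthcare_seed_labels(healthcare_fixture.truth)
        by_name = {p.name: p for p in ency_fixture.pages}
        cats = collect_seed_categories(sorted(seeds), by_name)
        # seeds only ever land on clean pages, so no low-confidence
        # category can enter the seed category set
        assert cats
        assert not cats & set(ency_fixture.truth["low_categories"])


class TestCategoryScoring:
    def test_direct_ratio(self):
        members = {"cat": {f"e{i}" for i in range(10)}}
        seeds = [f"e{i}" for i in range(5)]
        (conf,) = score_categories(seeds, members)
        assert conf.ratio == 0.5
        assert conf.label(0.1) == "high"

    def test_saturated_category(self):
        (conf,) = score_categories(["a", "b"], {"cat": {"a", "b"}})
        assert conf.ratio == 1.0 and conf.label() == "high"

    def test_zero_seed_category_low(self):
        members = {"cat": {f"e{i}" for i in range(50)}}
        (conf,) = score_categories(["other"], members)
        assert conf.ratio == 0.0 and conf.label(0.1) == "low"

    def test_empty_category_errors(self):
        with pytest.raises(ValueError):
            score_categories(["a"], {"cat": set()})

    def test_threshold_monotonicity(self, ency_fixture, healthcare_fixture):
        # raising the threshold never grows the high-confidence set
        seeds = synth.healthcare_seed_labels(healthcare_fixture.truth)
        confs = score_categories(sorted(seeds),
                                 category_members(ency_fixture.pages))
        previous = None
        for thr in (0.0, 0.05, 0.1, 0.3, 0.6, 1.0):
            high = {c.category for c in confs if c.label(thr) == "high"}
            if previous is not None:
                assert high <= previous
            previous = high


class TestNoiseFiltering:
    def test_low_category_convicts(self):
        page = _page("x", cats={"high1", "low1"})
        assert filter_noise_entities([page], {"low1"}) == []

    def test_clean_page_retained(self):
        page = _page("x", cats={"high1", "high2"})
        assert filter_noise_entities([page], {"low1"}) == [page]

    def test_uncategorized_page_retained(self):
        page = _page("x")
        assert filter_noise_entities([page], {"low1"}) == [page]

    def test_idempotent(self, ency_fixture):
        low = set(ency_fixture.truth["low_categories"])
        once = filter_noise_entities(ency_fixture.pages, low)
        assert filter_noise_entities(once, low) == once

    def test_planted_noise_removed_exactly(self, ency_fixture,
                                           healthcare_fixture):
        seeds = synth.healthcare_seed_labels(healthcare_fixture.truth)
        confs = score_categories(sorted(seeds),
                                 category_members(ency_fixture.pages))
        low = low_confidence_categories(confs, 0.1)
        retained = filter_noise_entities(ency_fixture.pages, low)
        assert sorted(p.name for p in retained) == \
            ency_fixture.truth["clean"]


class TestFeaturization:
    def test_fixed_dimensionality(self):
        assert len(feature_names()) == 26

    def test_name_suffix_feature(self):
        feats = featurize_page(_page("急性咽喉炎"))
        assert feats["name_endswith_炎"] == 1.0
        assert feats["name_endswith_科"] == 0.0

    def test_content_count_threshold_boundary(self):
        # >3 distinct cue words fire the feature; exactly 3 do not
        four = _page("x", content="功能规格成分用法")
        three = _page("x", content="功能规格成分")
        assert featurize_page(four)["content_medicine_gt3"] == 1.0
        assert featurize_page(four)["content_medicine_hits"] == 4.0
        assert featurize_page(three)["content_medicine_gt3"] == 0.0

    def test_empty_page_all_zero(self):
        feats = featurize_page(_page("x"))
        assert all(v == 0.0 for v in feats.values())

    def test_category_order_invariant(self):
        a = _page("x", cats=("药品", "疾病", "症状"))
        b = _page("x", cats=("症状", "药品", "疾病"))
        assert featurize_page(a) == featurize_page(b)


class TestClassifier:
    def test_separable_features_perfect_cv(self):
        # each label keyed to one exclusive signal
        pages, labels = [], []
        makers = {
            "department": lambda i: _page(f"门诊{i}科"),
            "disease": lambda i: _page(f"病例{i}病", content="病因检查鉴别诊断缓解"),
            "symptom": lambda i: _page(f"表现{i}", abstract="常见症状",
                                       cats={"症状"}),
            "tcm": lambda i: _page(f"丸剂{i}", abstract="中成药",
                                   cats={"中医"}),
        }
        for lab, make in makers.items():
            for i in range(20):
                pages.append(make(i))
                labels.append(lab)
        res = cross_validate_classifier(pages, labels, n_folds=10, seed=0)
        assert res["accuracy"] == 1.0

    def test_single_label_training_errors(self):
        pages = [_page(f"x{i}") for i in range(5)]
        with pytest.raises(ValueError):
            train_entity_classifier(feature_matrix(pages), ["other"] * 5)

    def test_symptom_only_signals_classify_symptom(self):
        train_pages, train_labels = [], []
        for i in range(10):
            train_pages.append(_page(f"表现{i}", abstract="典型症状",
                                     cats={"症状"}))
            train_labels.append("symptom")
            train_pages.append(_page(f"科室{i}科"))
            train_labels.append("department")
        model = train_entity_classifier(
            feature_matrix(train_pages), train_labels, seed=0)
        probe = _page("新表现", abstract="某症状", cats={"症状"})
        assert classify_entity(model, probe) == "symptom"

    def test_synthetic_corpus_macro_f1(self, ency_fixture):
        clean = [p for p in ency_fixture.pages
                 if ency_fixture.truth["labels"][p.name] != "noise"]
        labels = [ency_fixture.truth["labels"][p.name] for p in clean]
        res = cross_validate_classifier(clean, labels, n_folds=10, seed=0)
        assert res["macro_f1"] >= 0.85  # small-corpus unit check


class TestSubtypeRefinement:
    def test_tcm_department_mention(self):
        page = _page("盗汗", content="可就诊中医内科。")
        assert refine_symptom_subtype(page) == {ConceptType.TCM_SYMPTOM}

    def test_western_department_mention(self):
        page = _page("盗汗", content="可就诊神经内科。")
        assert refine_symptom_subtype(page) == {ConceptType.WESTERN_SYMPTOM}

    def test_no_evidence_defaults_western(self):
        page = _page("盗汗", content="无科室信息。")
        assert ConceptType.WESTERN_SYMPTOM in refine_symptom_subtype(
            _page("盗汗"))
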