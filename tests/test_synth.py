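"""Generator determinism, planted-count exactness, ground-truth consistency."""

import json

import pytest

from symptomkb import synth
from symptomkb.fusion import string_similarity
from symptomkb.linking import bag_of_words
from symptomkb.schema import ConceptType


class TestDeterminism:
    def test_healthcare_byte_identical(self, small_config,
                                       healthcare_fixture, tmp_path):
        again = synth.generate_healthcare_site(small_config)
        assert again.pages == healthcare_fixture.pages
        assert again.truth == healthcare_fixture.truth

    def test_encyclopedia_jsonl_byte_identical(self, small_config,
                                               healthcare_fixture, tmp_path):
        seeds = synth.healthcare_seed_labels(healthcare_fixture.truth)
        a = synth.generate_encyclopedia(small_config, seeds)
        b = synth.generate_encyclopedia(small_config, seeds)
        da, db = tmp_path / "a", tmp_path / "b"
        a.write(da)
        b.write(db)
        assert (da / "pages.jsonl").read_bytes() == \
            (db / "pages.jsonl").read_bytes()

    def test_emr_and_linking_reproducible(self, small_config, emr_fixture,
                                          linking_fixture):
        emr2 = synth.generate_emr_corpus(small_config)
        assert [r.to_json() for r in emr2.records] == \
            [r.to_json() for r in emr_fixture.records]
        link2 = synth.generate_linking_fixture(small_config)
        assert link2.lexicon == linking_fixture.lexicon
        assert link2.concepts == linking_fixture.concepts

    def test_different_seed_differs(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=99)
        assert synth.generate_healthcare_site(other).truth != \
            synth.generate_healthcare_site(small_config).truth


class TestPlantedCounts:
    def test_duplicate_pair_count_floor(self, small_config,
                                        healthcare_fixture):
        total = (small_config.n_symptoms + small_config.n_diseases
                 + small_config.n_medicines + small_config.n_departments
                 + small_config.n_examinations)
        expected = int(small_config.duplication_rate * total)
        assert len(healthcare_fixture.truth["duplicate_pairs"]) == expected

    def test_zero_duplication_all_singletons(self):
        import dataclasses
        cfg = dataclasses.replace(
            synth.GeneratorConfig(), n_symptoms=10, n_diseases=6,
            n_medicines=4, n_departments=4, n_examinations=4,
            duplication_rate=0.0)
        fix = synth.generate_healthcare_site(cfg)
        assert fix.truth["duplicate_pairs"] == []

    def test_noise_page_fraction(self, ency_fixture):
        n_noise = len(ency_fixture.truth["noise"])
        total = len(ency_fixture.pages)
        assert n_noise == ency_fixture.truth["n_noise"]
        assert n_noise == int(0.2 * total)  # floor of the configured rate

    def test_emr_split_matches_protocol(self, small_config, emr_fixture):
        assert len(emr_fixture.records) == small_config.n_records
        from symptomkb.ner import split_records
        train, test = split_records(emr_fixture.records,
                                    small_config.n_train_records, seed=3)
        assert len(train) == small_config.n_train_records
        assert len(test) == small_config.n_records - \
            small_config.n_train_records

    def test_full_protocol_sizes(self):
        cfg = synth.GeneratorConfig()
        assert cfg.n_records == 1000 and cfg.n_train_records == 660


class TestGroundTruthConsistency:
    def test_duplicate_pairs_same_coarse_type_and_commonness_bound(
            self, healthcare_fixture):
        truth = healthcare_fixture.truth
        for pair in truth["duplicate_pairs"]:
            rec_a = truth["sites"][pair["site_a"]][pair["name_a"]]
            rec_b = truth["sites"][pair["site_b"]][pair["name_b"]]
            assert rec_a["kind"] == rec_b["kind"]
            # planted edits are insertions: commonness is exactly
            # len_a / (len_a + edits), which the budget keeps above 3/4
            la = len(pair["name_a"])
            sim = string_similarity(pair["name_a"], pair["name_b"])
            assert sim == pytest.approx(la / (la + pair["edits"]))
            assert sim > 0.75

    def test_duplicate_pairs_share_two_of_three_facts(self,
                                                      healthcare_fixture):
        truth = healthcare_fixture.truth
        for pair in truth["duplicate_pairs"]:
            attrs_a = truth["sites"][pair["site_a"]][pair["name_a"]]["attributes"]
            attrs_b = truth["sites"][pair["site_b"]][pair["name_b"]]["attributes"]
            assert set(attrs_a) == set(attrs_b)
            same = sum(attrs_a[k] == attrs_b[k] for k in attrs_a)
            assert same == len(attrs_a) - 1

    def test_gold_spans_index_real_token_ranges(self, emr_fixture):
        for target in ("western", "tcm"):
            for seqs in emr_fixture.gold[target].values():
                for ls in seqs:
                    assert len(ls.labels) == len(ls.seq.tokens)
                    assert all(t for t in ls.seq.tokens)

    def test_gold_links_bag_equal_near_misses_not(self, linking_fixture):
        terms = {c.cui: c.term for c in linking_fixture.concepts}
        for zh, cuis in linking_fixture.truth["gold_links"].items():
            for cui in cuis:
                assert bag_of_words(linking_fixture.lexicon[zh]) == \
                    bag_of_words(terms[cui])
        for zh, cui in linking_fixture.truth["near_miss_cuis"].items():
            assert bag_of_words(linking_fixture.lexicon[zh]) != \
                bag_of_words(terms[cui])

    def test_noise_pages_carry_low_categories(self, ency_fixture):
        by_name = {p.name: p for p in ency_fixture.pages}
        low = set(ency_fixture.truth["low_categories"])
        for name in ency_fixture.truth["noise"]:
            assert by_name[name].categories & low
        for name in ency_fixture.truth["clean"]:
            assert not by_name[name].categories & low


class TestConfigValidation:
    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            synth.GeneratorConfig(duplication_rate=1.5)
        with pytest.raises(ValueError):
            synth.GeneratorConfig(label_noise=-0.1)


def test_write_outputs_are_text(tmp_path, small_config):
    manifest = synth.generate_all(small_config, tmp_path)
    assert (tmp_path / "manifest.json").exists()
    truth = json.loads(
        (tmp_path / "healthcare" / "ground_truth.json").read_text("utf-8"))
    assert truth["duplicate_pairs"]
    # everything the generators emit is small plain text
    for p in tmp_path.rglob("*"):
        if p.is_file():
            assert p.suffix in {".html", ".yaml", ".json", ".jsonl",
                                ".conll", ".tsv"}
            assert p.stat().st_size < 4_000_000
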