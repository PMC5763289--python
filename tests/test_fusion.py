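"""Name similarity, type voting, duplicate mapping, attribute mapping."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from symptomkb.fusion import (
    AttributeMappingRule,
    SourcePriority,
    align_type,
    default_attribute_rules,
    lcs_length,
    map_attribute,
    map_entities,
    relatedness,
    sort_rules_by_specificity,
    string_similarity,
)
from symptomkb.schema import ConceptType, Entity

C = ConceptType


def brute_force_lcs(a: str, b: str) -> int:
    """Exhaustive subsequence enumeration; only viable for len <= 8."""
    subs = {""}
    for ch in a:
        subs |= {s + ch for s in subs}
    best = 0
    for s in sorted(subs, key=len, reverse=True):
        if len(s) <= best:
            break
        it = iter(b)
        if all(ch in it for ch in s):
            best = len(s)
    return best


_ALPHABET = "AB头痛x疒"  # small mixed Latin/CJK alphabet provokes collisions


class TestLCS:
    @pytest.mark.parametrize("a,b,expected", [
        ("ABCDE", "ACE", 3),
        ("中医内科", "中医内科", 4),
        ("AAA", "BBB", 0),
        ("", "ABC", 0),
    ])
    def test_known_values(self, a, b, expected):
        assert lcs_length(a, b) == expected

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(_ALPHABET, max_size=8), st.text(_ALPHABET, max_size=8))
    def test_agrees_with_brute_force(self, a, b):
        assert lcs_length(a, b) == brute_force_lcs(a, b)


class TestStringSimilarity:
    def test_worked_example(self):
        assert string_similarity("ABCDE", "ACE") == pytest.approx(0.6)

    def test_identity_is_one(self):
        assert string_similarity("头晕目眩", "头晕目眩") == 1.0

    def test_empty_versus_nonempty(self):
        assert string_similarity("A", "") == 0.0

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            string_similarity("", "")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(_ALPHABET, min_size=1, max_size=8),
           st.text(_ALPHABET, max_size=8))
    def test_bounds_symmetry_and_identity_condition(self, a, b):
        s = string_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == string_similarity(b, a)
        if b:
            assert s <= min(len(a), len(b)) / max(len(a), len(b))
        assert (s == 1.0) == (a == b)


def _ent(eid, name, types, source="s1", **attrs):
    e = Entity(id=eid, name=name, types=set(types), sources={source})
    for k, v in attrs.items():
        e.add_attribute(k, v)
    return e


class TestRelatedness:
    def test_identical_values_saturate(self):
        a = _ent("a", "头痛", {C.SYMPTOM}, relevant_department="内科",
                 location="头部")
        b = _ent("b", "头疼", {C.SYMPTOM}, relevant_department="内科",
                 location="头部")
        assert relatedness(a, b).value == 1.0

    def test_one_of_two_similar(self):
        a = _ent("a", "头痛", {C.SYMPTOM}, relevant_department="内科",
                 location="头部")
        b = _ent("b", "头疼", {C.SYMPTOM}, relevant_department="内科",
                 location="腰部")
        r = relatedness(a, b)
        assert r.value == 0.5 and r.shared_attributes == 2

    def test_no_shared_attributes_flagged_zero(self):
        a = _ent("a", "头痛", {C.SYMPTOM}, location="头部")
        b = _ent("b", "头疼", {C.SYMPTOM}, relevant_department="内科")
        r = relatedness(a, b)
        assert r.value == 0.0 and r.no_shared_attributes

    def test_type_mismatch_errors(self):
        a = _ent("a", "头痛", {C.SYMPTOM})
        b = _ent("b", "感冒", {C.DISEASE})
        with pytest.raises(ValueError):
            relatedness(a, b)


class TestTypeVoting:
    def test_plurality_wins(self):
        votes = [(C.SYMPTOM, "s1"), (C.SYMPTOM, "s2"), (C.DISEASE, "s3")]
        assert align_type(votes, SourcePriority(("s1", "s2", "s3"))) == \
            C.SYMPTOM

    def test_tie_breaks_by_source_priority(self):
        votes = [(C.SYMPTOM, "s2"), (C.DISEASE, "s1")]
        assert align_type(votes, SourcePriority(("s1", "s2"))) == C.DISEASE

    def test_singleton(self):
        assert align_type([(C.MEDICINE, "s9")],
                          SourcePriority(("s9",))) == C.MEDICINE

    def test_empty_votes_error(self):
        with pytest.raises(ValueError):
            align_type([], SourcePriority(("s1",)))

    def test_duplicate_priority_sources_rejected(self):
        with pytest.raises(ValueError):
            SourcePriority(("s1", "s1"))


class TestEntityMapping:
    def test_perfect_duplicate_merges(self):
        a = _ent("a", "急性头痛", {C.SYMPTOM}, relevant_department="内科")
        b = _ent("b", "急性头痛", {C.SYMPTOM}, relevant_department="内科",
                 source="s2")
        clusters, audit = map_entities([a, b])
        assert clusters == [["a", "b"]]
        assert audit[0].product == 1.0

    def test_same_name_without_shared_attributes_not_merged(self):
        a = _ent("a", "急性头痛", {C.SYMPTOM}, location="头部")
        b = _ent("b", "急性头痛", {C.SYMPTOM}, relevant_department="内科",
                 source="s2")
        clusters, audit = map_entities([a, b])
        assert clusters == [["a"], ["b"]]
        assert audit[0].no_shared_attributes

    def test_never_merges_across_coarse_types(self):
        a = _ent("a", "扁桃体炎", {C.SYMPTOM}, location="咽部")
        b = _ent("b", "扁桃体炎", {C.DISEASE}, location="咽部")
        clusters, _ = map_entities([a, b])
        assert clusters == [["a"], ["b"]]

    def test_order_independence(self):
        ents = [
            _ent("a", "急性头痛", {C.SYMPTOM}, relevant_department="内科"),
            _ent("b", "急性头痛症", {C.SYMPTOM}, relevant_department="内科"),
            _ent("c", "盗汗", {C.SYMPTOM}, relevant_department="中医内科"),
        ]
        reference, _ = map_entities(ents)
        for perm in itertools.permutations(ents):
            clusters, _ = map_entities(list(perm))
            assert clusters == reference


class TestAttributeMapping:
    def test_typed_symptom_rule(self):
        # the generic "symptom" attribute between two symptom entities
        rules = default_attribute_rules()
        assert map_attribute("症状", C.SYMPTOM, C.SYMPTOM, rules) == \
            "symptom_related_symptom"

    def test_direct_manual_entry(self):
        rules = default_attribute_rules()
        assert map_attribute("相关疾病", None, None, rules) == \
            "relevant_disease"

    def test_unknown_attribute_quarantined(self):
        assert map_attribute("奇怪字段", None, None,
                             default_attribute_rules()) is None

    def test_specificity_ordering(self):
        loose = AttributeMappingRule("x", "location")
        tight = AttributeMappingRule("x", "relevant_symptom",
                                     subject_type=C.SYMPTOM)
        ordered = sort_rules_by_specificity([loose, tight])
        assert ordered[0] is tight
        assert map_attribute("x", C.SYMPTOM, None, ordered) == \
            "relevant_symptom"
        assert map_attribute("x", C.DISEASE, None, ordered) == "location"
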