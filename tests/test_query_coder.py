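"""Query-reformulation taxonomy: the five syntactic detectors, the
semantic detector, and the combined classifier."""

import pytest
from hypothesis import given, settings, strategies as st

from searchcode import (
    QueryCode,
    ReformulationType,
    SyntacticSubtype,
    classify_query_reformulation,
    detect_capitalization_change,
    detect_conjunction_change,
    detect_semantic_change,
    detect_spacing_change,
    detect_typographic_change,
    detect_word_order_change,
    is_typographic_variant,
    tokenize,
)
from searchcode.query_coder import CodingError, light_stem

from conftest import kw


class TestTokenize:
    def test_whitespace_split(self):
        assert [t.text for t in tokenize("asthma diagnosis")] == ["asthma", "diagnosis"]

    def test_hyphen_splits_with_grouping_mark(self):
        toks = tokenize("heart-attack")
        assert [t.text for t in toks] == ["heart", "attack"]
        assert toks[0].group is not None and toks[0].group == toks[1].group

    def test_quoted_phrase_is_single_grouped_token(self):
        toks = tokenize('"otitis media" child')
        assert [t.text for t in toks] == ["otitis media", "child"]
        assert toks[0].group is not None and toks[1].group is None

    def test_empty_string(self):
        assert tokenize("") == []


DETECTOR_CASES = [
    (detect_capitalization_change, "IVF", "ivf", True),
    (detect_capitalization_change, "ivf", "ivf", False),
    (detect_capitalization_change, "IVF risk", "ivf danger", False),
    (detect_word_order_change, "asthma diagnosis", "diagnosis asthma", True),
    (detect_word_order_change, "asthma", "asthma", False),
    (detect_word_order_change, "a b b", "b a b", True),
    (detect_conjunction_change, "asthma AND child", "asthma child", True),
    (detect_conjunction_change, "asthma AND child", "asthma OR child", True),
    (detect_conjunction_change, "asthma child", "asthma child", False),
    (detect_spacing_change, "heart-attack", "heart attack", True),
    (detect_spacing_change, '"otitis media" child', "otitis media child", True),
    (detect_spacing_change, "heart attack", "heart attack", False),
    (detect_typographic_change, "apple", "apples", True),
    (detect_typographic_change, "behaviour", "behavior", True),
    (detect_typographic_change, "run", "running", True),
    (detect_typographic_change, "run", "walked", False),
    (detect_semantic_change, "asthma", "asthma child", True),
    (detect_semantic_change, "asthma spacer", "asthma inhaler", True),
    (detect_semantic_change, "Asthma", "asthma", False),
]


@pytest.mark.parametrize("detector,q1,q2,expected", DETECTOR_CASES)
def test_detectors(detector, q1, q2, expected):
    assert detector(q1, q2) is expected


@pytest.mark.parametrize("detector,q1,q2,expected", DETECTOR_CASES)
def test_detectors_are_symmetric(detector, q1, q2, expected):
    assert detector(q2, q1) is expected


class TestVariantRelation:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("apple", "apples", True),
            ("behaviour", "behavior", True),
            ("studies", "study", True),
            ("run", "walked", False),
            ("asthma", "asthma", False),  # identical words are not variants
            ("cat", "car", False),  # too short for the edit-distance branch
        ],
    )
    def test_pairs(self, a, b, expected):
        assert is_typographic_variant(a, b) is expected

    def test_light_stem_inflections(self):
        assert light_stem("running") == light_stem("run")
        assert light_stem("apples") == light_stem("apple")
        assert light_stem("studies") == light_stem("study")


class TestClassifier:
    def test_identical_maps_code_as_no_change(self):
        m = kw("asthma child", drug="nicotine")
        assert classify_query_reformulation(m, m) == QueryCode(ReformulationType.NONE)

    def test_capitalization_only(self):
        c = classify_query_reformulation(kw("IVF"), kw("ivf"))
        assert c.value is ReformulationType.SYNTACTIC_ONLY
        assert c.subtypes == {SyntacticSubtype.CAPITALIZATION}

    def test_combined_case_flip_and_addition(self):
        c = classify_query_reformulation(kw("asthma"), kw("Asthma child"))
        assert c.value is ReformulationType.SYNTACTIC_AND_SEMANTIC
        assert c.subtypes == {SyntacticSubtype.CAPITALIZATION}

    def test_empty_to_nonempty_field_is_semantic_addition(self):
        c = classify_query_reformulation(kw("asthma"), kw("asthma", symptom="wheeze"))
        assert c.value is ReformulationType.SEMANTIC_ONLY

    def test_cross_category_move_codes_as_semantic(self):
        c = classify_query_reformulation(kw("nicotine"), kw("", drug="nicotine"))
        assert c.value is ReformulationType.SEMANTIC_ONLY

    def test_flags_or_across_categories(self):
        c = classify_query_reformulation(
            kw("IVF", drug="nicotine"), kw("ivf", drug="steroid")
        )
        assert c.value is ReformulationType.SYNTACTIC_AND_SEMANTIC
        assert c.subtypes == {SyntacticSubtype.CAPITALIZATION}

    def test_missing_category_raises(self):
        with pytest.raises(CodingError):
            classify_query_reformulation({"disease": "a"}, kw("a"))

    def test_subtype_value_consistency_enforced(self):
        with pytest.raises(ValueError):
            QueryCode(ReformulationType.SEMANTIC_ONLY, frozenset({SyntacticSubtype.SPACING}))


# Each entry applies exactly one named edit; the classifier must fire
# exactly that detector (single-edit recovery).
SINGLE_EDITS = [
    ("asthma spacer", "Asthma spacer", SyntacticSubtype.CAPITALIZATION),
    ("asthma spacer", "spacer asthma", SyntacticSubtype.WORD_ORDER),
    ("asthma spacer", "asthma AND spacer", SyntacticSubtype.CONJUNCTION),
    ("asthma AND spacer", "asthma NOT spacer", SyntacticSubtype.CONJUNCTION),
    ("asthma spacer", "asthma-spacer", SyntacticSubtype.SPACING),
    ("otitis media child", '"otitis media" child', SyntacticSubtype.SPACING),
    ("asthma spacer", "asthmas spacer", SyntacticSubtype.TYPOGRAPHIC),
    ("behaviour disorder", "behavior disorder", SyntacticSubtype.TYPOGRAPHIC),
]


@pytest.mark.parametrize("q1,q2,subtype", SINGLE_EDITS)
def test_single_syntactic_edit_recovered_exactly(q1, q2, subtype):
    c = classify_query_reformulation(kw(q1), kw(q2))
    assert c.value is ReformulationType.SYNTACTIC_ONLY
    assert c.subtypes == {subtype}


@pytest.mark.parametrize("q1,q2,subtype", SINGLE_EDITS)
def test_syntactic_plus_semantic_composes(q1, q2, subtype):
    """Adding a semantic edit in another category on top of any single
    syntactic edit yields the combined code."""
    c = classify_query_reformulation(
        kw(q1, drug="nicotine"), kw(q2, drug="steroid")
    )
    assert c.value is ReformulationType.SYNTACTIC_AND_SEMANTIC
    assert subtype in c.subtypes


_words = st.lists(
    st.sampled_from(["asthma", "spacer", "IVF", "otitis", "child", "AND", "heart-attack"]),
    min_size=0,
    max_size=4,
)


@settings(max_examples=200, derandomize=True)
@given(w1=_words, w2=_words)
def test_no_change_is_symmetric(w1, w2):
    """classify(q1,q2) is 'none' iff classify(q2,q1) is 'none'."""
    m1, m2 = kw(" ".join(w1)), kw(" ".join(w2))
    fwd = classify_query_reformulation(m1, m2).value is ReformulationType.NONE
    rev = classify_query_reformulation(m2, m1).value is ReformulationType.NONE
    assert fwd == rev


@settings(max_examples=100, derandomize=True)
@given(w=_words, drug=st.sampled_from(["", "nicotine", "x-y"]))
def test_identity_codes_as_no_change(w, drug):
    m = kw(" ".join(w), drug=drug)
    assert classify_query_reformulation(m, m) == QueryCode(ReformulationType.NONE)
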