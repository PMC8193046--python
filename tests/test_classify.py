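import math

import pytest
from hypothesis import given, settings, strategies as st

from capa.chem import parse_structure
from capa.classify import (
    CLASS_OF_SUBSET,
    MULTITARGET_CLASSES,
    SUBSET_OF_CLASS,
    ActivityProfile,
    Censored,
    ClassificationError,
    FlagRules,
    assign_class,
    class_distribution,
    flag_hits,
    load_activity_csv,
    parse_measurement,
)
from capa.patterns import SubstructurePattern


# ---------------------------------------------------------------------------
# Class mapping
# ---------------------------------------------------------------------------


def test_subset_mapping_is_a_bijection():
    assert len(CLASS_OF_SUBSET) == 8
    assert sorted(CLASS_OF_SUBSET.values()) == list(range(8))
    for cls, subset in SUBSET_OF_CLASS.items():
        assert CLASS_OF_SUBSET[subset] == cls


@pytest.mark.parametrize(
    "profile,expected_class,expected_subset",
    [
        ((50.0, 50.0, 50.0), 0, set()),
        ((5.0, 50.0, 50.0), 1, {"ABCB1"}),
        ((50.0, 5.0, 50.0), 2, {"ABCC1"}),
        ((50.0, 50.0, 5.0), 3, {"ABCG2"}),
        ((5.0, 5.0, 50.0), 4, {"ABCB1", "ABCC1"}),
        ((5.0, 50.0, 5.0), 5, {"ABCB1", "ABCG2"}),
        ((50.0, 5.0, 5.0), 6, {"ABCC1", "ABCG2"}),
        ((5.0, 5.0, 5.0), 7, {"ABCB1", "ABCC1", "ABCG2"}),
    ],
)
def test_all_eight_classes(profile, expected_class, expected_subset):
    label = assign_class(ActivityProfile(*profile))
    assert label.value == expected_class
    assert label.inhibited == frozenset(expected_subset)
    assert not label.provisional
    assert label.multitarget == (expected_class in MULTITARGET_CLASSES)


def test_threshold_is_strict():
    at_threshold = assign_class(ActivityProfile(10.0, 50.0, 50.0))
    assert at_threshold.value == 0
    below = assign_class(ActivityProfile(9.999, 50.0, 50.0))
    assert below.value == 1


def test_worked_example_dual_inhibitor():
    # the followed-up candidate: ABCB1 4.01, ABCC1 14.8, ABCG2 9.27 uM
    label = assign_class(ActivityProfile(4.01, 14.8, 9.27))
    assert label.inhibited == frozenset({"ABCB1", "ABCG2"})
    assert label.value == 5
    assert label.value != 7


def test_custom_threshold():
    label = assign_class(ActivityProfile(4.01, 14.8, 9.27), threshold=20.0)
    assert label.value == 7


def test_censored_at_or_above_threshold_is_inactive():
    label = assign_class(ActivityProfile(5.0, Censored(10.0), Censored(100.0)))
    assert label.value == 1
    assert not label.provisional


def test_censored_below_threshold_is_data_error():
    with pytest.raises(ClassificationError, match="ABCC1"):
        assign_class(ActivityProfile(5.0, Censored(5.0), 50.0))


def test_missing_measurements_are_provisional():
    label = assign_class(ActivityProfile(5.0, None, None))
    assert label.value == 1
    assert label.provisional


def test_all_missing_is_error():
    with pytest.raises(ClassificationError, match="no measurement"):
        assign_class(ActivityProfile(None, None, None))


@pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
def test_invalid_measurements_rejected(bad):
    with pytest.raises(ValueError):
        ActivityProfile(bad, 50.0, 50.0)


@pytest.mark.parametrize("bad", [0.0, -5.0, math.inf])
def test_invalid_threshold_rejected(bad):
    with pytest.raises(ValueError):
        assign_class(ActivityProfile(5.0, 5.0, 5.0), threshold=bad)


@given(
    st.tuples(
        st.floats(min_value=0.01, max_value=1000.0),
        st.floats(min_value=0.01, max_value=1000.0),
        st.floats(min_value=0.01, max_value=1000.0),
    )
)
@settings(max_examples=100, deadline=None)
def test_class_consistent_with_per_target_threshold(values):
    label = assign_class(ActivityProfile(*values))
    expected = frozenset(
        t for t, v in zip(("ABCB1", "ABCC1", "ABCG2"), values) if v < 10.0
    )
    assert label.inhibited == expected


# ---------------------------------------------------------------------------
# Occurrence table and flag rules
# ---------------------------------------------------------------------------


def _pattern(name, smarts):
    return SubstructurePattern(
        name=name, smarts=smarts, role="clear_positive", provenance="test"
    )


def _records():
    piperazine = "C1CN(CC)CCN1"
    plain = "CCOCC"
    recs = []
    for i in range(4):  # class 7 compounds, all with piperazine
        recs.append(
            (parse_structure(piperazine, f"c7-{i}"), assign_class(ActivityProfile(1, 1, 1)))
        )
    for i in range(6):  # class 0 compounds without it
        recs.append(
            (parse_structure(plain, f"c0-{i}"), assign_class(ActivityProfile(50, 50, 50)))
        )
    return recs


def test_class_distribution_counts():
    patterns = [_pattern("piperazine", "N1CCNCC1"), _pattern("ether", "[CX4][OX2;!R][CX4]")]
    table = class_distribution(_records(), patterns)
    assert table.class_sizes == (6, 0, 0, 0, 0, 0, 0, 4)
    assert table.counts.at["piperazine", 7] == 4
    assert table.counts.at["piperazine", 0] == 0
    assert table.counts.at["ether", 0] == 6
    assert table.fraction("piperazine", 7) == 1.0
    assert table.pooled_fraction("piperazine", range(7)) == 0.0
    assert table.fraction("piperazine", 3) == 0.0  # empty class


def test_flag_hits_positive_and_rejected():
    patterns = [_pattern("piperazine", "N1CCNCC1"), _pattern("ether", "[CX4][OX2;!R][CX4]")]
    table = class_distribution(_records(), patterns)
    flags = flag_hits(table)
    assert flags["piperazine"] == "positive"
    assert flags["ether"] == "rejected"  # absent from class 7, ubiquitous elsewhere


def test_flag_rules_validation():
    with pytest.raises(ValueError):
        FlagRules(positive_min_class7=0.2, reject_max_class7=0.4)
    with pytest.raises(ValueError):
        FlagRules(positive_max_other=1.5)


def test_occurrence_invariant_under_record_reordering():
    patterns = [_pattern("piperazine", "N1CCNCC1")]
    recs = _records()
    a = class_distribution(recs, patterns)
    b = class_distribution(list(reversed(recs)), patterns)
    assert a.class_sizes == b.class_sizes
    assert a.counts.equals(b.counts)


# ---------------------------------------------------------------------------
# Measurement parsing / CSV
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [("", None), ("  ", None), ("na", None), ("4.01", 4.01), ("> 100", Censored(100.0)),
     (">10", Censored(10.0)), (None, None)],
)
def test_parse_measurement(text, expected):
    assert parse_measurement(text) == expected


def test_load_activity_csv(tmp_path):
    path = tmp_path / "act.csv"
    path.write_text(
        "id,abcb1_ic50_um,abcc1_ic50_um,abcg2_ic50_um\n"
        "a,4.01,14.8,9.27\n"
        "b,,>100,2\n"
    )
    rows = dict(load_activity_csv(path))
    assert rows["a"] == ActivityProfile(4.01, 14.8, 9.27)
    assert rows["b"] == ActivityProfile(None, Censored(100.0), 2.0)
    label = assign_class(rows["b"])
    assert label.value == 3 and label.provisional


def test_load_activity_csv_missing_columns(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("id,ic50\nx,1\n")
    with pytest.raises(ValueError):
        load_activity_csv(path)
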