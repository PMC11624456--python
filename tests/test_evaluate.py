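"""Abstract-level TP/FP/FN alignment and metric arithmetic."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from popchar.evaluate import (
    EvalCounts,
    Metrics,
    absolute_agreement,
    align_abstract,
    compute_metrics,
    macro_metrics,
    micro_metrics,
    sum_counts,
)
from popchar.model import Characteristic, GoldAnnotation, StandardizedValue

C = Characteristic
FEMALE = StandardizedValue(C.SEX, "female")
MALE = StandardizedValue(C.SEX, "male")
NOR = StandardizedValue(C.NATIONALITY, "Norwegian")
SWE = StandardizedValue(C.NATIONALITY, "Swedish")
USA = StandardizedValue(C.NATIONALITY, "American")


@pytest.mark.parametrize(
    ("counts", "expected"),
    [
        # published per-characteristic rows (training/development/evaluation)
        ((51, 6, 10), (89.4, 83.6, 86.4)),
        ((57, 1, 10), (98.2, 85.0, 91.1)),
        ((52, 5, 5), (91.2, 91.2, 91.2)),
        ((54, 6, 5), (90.0, 91.5, 90.7)),
        ((54, 0, 4), (100.0, 93.1, 96.4)),
        ((78, 15, 15), (83.8, 83.8, 83.8)),
        ((94, 11, 8), (89.5, 92.1, 90.7)),
        ((36, 3, 3), (92.3, 92.3, 92.3)),
        ((40, 4, 2), (90.9, 95.2, 93.0)),
    ],
)
def test_compute_metrics_reproduces_published_rows(counts, expected):
    tp, fp, fn = counts
    metrics = compute_metrics(EvalCounts(None, tp, fp, fn))
    assert (metrics.precision, metrics.recall, metrics.f1) == expected


def test_zero_denominators_give_zero_with_warning(caplog):
    with caplog.at_level("WARNING"):
        metrics = compute_metrics(EvalCounts(C.SEX, 0, 0, 0))
    assert metrics == Metrics(0.0, 0.0, 0.0)
    assert len(caplog.records) == 2


def test_align_multiple_surfaces_one_value():
    gold = GoldAnnotation("p1", frozenset({FEMALE}))
    counts = align_abstract(gold, {FEMALE})  # "females" and "women" dedupe
    assert (counts[C.SEX].tp, counts[C.SEX].fp, counts[C.SEX].fn) == (1, 0, 0)


def test_align_empty_both_sides():
    counts = align_abstract(GoldAnnotation("p1", frozenset()), frozenset())
    assert all(c.tp == c.fp == c.fn == 0 for c in counts.values())


def test_align_partial_overlap():
    gold = GoldAnnotation("p1", frozenset({NOR, SWE}))
    counts = align_abstract(gold, {NOR, USA})
    nat = counts[C.NATIONALITY]
    assert (nat.tp, nat.fp, nat.fn) == (1, 1, 1)


def test_align_pmid_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        align_abstract(GoldAnnotation("p1", frozenset()), frozenset(), pmid="p2")


def test_micro_single_class_is_identity():
    counts = EvalCounts(C.SEX, 54, 0, 4)
    assert micro_metrics([counts]) == compute_metrics(counts)


def test_micro_pools_counts():
    metrics = micro_metrics(
        [EvalCounts(C.SEX, 1, 0, 0), EvalCounts(C.AGE, 0, 1, 1)]
    )
    assert metrics == Metrics(50.0, 50.0, 50.0)


def test_micro_empty_raises():
    with pytest.raises(ValueError):
        micro_metrics([])


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
        ),
        min_size=1,
        max_size=6,
    )
)
def test_pooled_counts_equal_sum_of_parts(triples):
    counts = [EvalCounts(None, tp, fp, fn) for tp, fp, fn in triples]
    pooled = sum_counts(counts)
    assert pooled.tp == sum(c.tp for c in counts)
    assert pooled.fp == sum(c.fp for c in counts)
    assert pooled.fn == sum(c.fn for c in counts)


def test_micro_precision_between_class_extremes():
    rng = random.Random(17)
    for _ in range(100):
        counts = [
            EvalCounts(None, rng.randint(1, 40), rng.randint(0, 20), rng.randint(0, 20))
            for _ in range(4)
        ]
        precisions = [compute_metrics(c).precision for c in counts]
        micro = micro_metrics(counts).precision
        assert min(precisions) - 0.1 <= micro <= max(precisions) + 0.1


def test_macro_of_published_precisions():
    per_class = [Metrics(p, 0.0, 0.0) for p in (97.6, 100.0, 92.4, 90.9)]
    assert macro_metrics(per_class).precision == 95.2


def test_macro_identity_and_midpoint():
    single = Metrics(88.8, 77.7, 66.6)
    assert macro_metrics([single]) == single
    pair = [Metrics(0.0, 0.0, 0.0), Metrics(100.0, 100.0, 100.0)]
    assert macro_metrics(pair) == Metrics(50.0, 50.0, 50.0)


def test_swapping_gold_and_predicted_swaps_fp_fn():
    rng = random.Random(23)
    pool = [FEMALE, MALE, NOR, SWE, USA, StandardizedValue(C.AGE, "minors")]
    for _ in range(50):
        gold = frozenset(rng.sample(pool, rng.randint(0, len(pool))))
        pred = frozenset(rng.sample(pool, rng.randint(0, len(pool))))
        forward = align_abstract(GoldAnnotation("p", gold), pred)
        backward = align_abstract(GoldAnnotation("p", pred), gold)
        for kind in C:
            assert forward[kind].tp == backward[kind].tp
            assert forward[kind].fp == backward[kind].fn
            assert forward[kind].fn == backward[kind].fp


def _annotations(values_by_pmid):
    return {
        pmid: GoldAnnotation(pmid, frozenset(values))
        for pmid, values in values_by_pmid.items()
    }


def test_absolute_agreement_identical_sets():
    a = _annotations({"p1": {FEMALE}, "p2": {NOR}})
    assert absolute_agreement(a, dict(a)) == 100.0


def test_absolute_agreement_half_differ():
    a = _annotations({f"p{i}": {FEMALE} for i in range(10)})
    b = _annotations(
        {f"p{i}": ({FEMALE} if i < 5 else {FEMALE, MALE}) for i in range(10)}
    )
    assert absolute_agreement(a, b) == 50.0


def test_absolute_agreement_92_of_100():
    a = _annotations({f"p{i}": {NOR} for i in range(100)})
    b = _annotations(
        {f"p{i}": ({NOR} if i < 92 else {SWE}) for i in range(100)}
    )
    assert absolute_agreement(a, b) == 92.0


def test_absolute_agreement_pmid_mismatch_raises():
    a = _annotations({"p1": {FEMALE}})
    b = _annotations({"p2": {FEMALE}})
    with pytest.raises(ValueError):
        absolute_agreement(a, b)
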