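"""Descriptive analytics: coverage, distributions, series, rankings."""

import random

import pytest

from popchar.analytics import (
    AbstractResult,
    age_distribution,
    correlation,
    country_ranking,
    nationality_counts,
    offender_rates,
    sex_series,
    summarize_corpus,
)
from popchar.model import AgeGroup, Characteristic, OffenderCategory, StandardizedValue
from popchar.resources import benchmark_nationality_counts, default_prisoner_table
from popchar.util import rate_per_1000

C = Characteristic


def value(kind, label, attribute=None):
    return StandardizedValue(kind, label, attribute)


def result(pmid, year=2000, *values):
    return AbstractResult(pmid, year, frozenset(values))


def test_summarize_corpus_counts():
    results = [
        result(
            "a", 2000,
            value(C.AGE, "minors"), value(C.SEX, "female"),
            value(C.NATIONALITY, "Norwegian"),
            value(C.OFFENDER_TYPE, "sex"),
        ),
        result("b", 2001),
        result("c", 2002, value(C.SEX, "male")),
        result("d", 2003, value(C.SEX, "female")),
    ]
    summary = summarize_corpus(results)
    assert summary.total == 4
    assert summary.none == (1, 25.0)
    assert summary.all_four == (1, 25.0)
    assert summary.per_characteristic[C.SEX] == (3, 75.0)


def test_summarize_corpus_all_empty_and_permutation_invariance():
    results = [result(f"p{i}", 2000) for i in range(5)]
    summary = summarize_corpus(results)
    assert summary.none[0] == summary.total == 5
    shuffled = list(results)
    random.Random(3).shuffle(shuffled)
    assert summarize_corpus(shuffled).none == summary.none


def test_summarize_corpus_empty_raises():
    with pytest.raises(ValueError):
        summarize_corpus([])


def test_age_distribution_multi_band_abstract():
    results = [
        result("a", 2000, value(C.AGE, "minors"), value(C.AGE, "18-24")),
        result("b", 2000),  # not age-reporting: excluded from denominator
    ]
    table, denominator = age_distribution(results)
    assert denominator == 1
    assert table[AgeGroup.MINOR] == (1, 100.0)
    assert table[AgeGroup.A18_24] == (1, 100.0)
    assert table[AgeGroup.A65_PLUS] == (0, 0.0)


def test_sex_series_denominators_and_omitted_years():
    results = (
        [result(f"f{i}", 1990, value(C.SEX, "female")) for i in range(19)]
        + [result(f"m{i}", 1990, value(C.SEX, "male")) for i in range(33)]
        + [
            result(f"b{i}", 1990, value(C.SEX, "male"), value(C.SEX, "female"))
            for i in range(13)
        ]
        + [result("noyear", None, value(C.SEX, "female"))]
        + [result("nosex", 1991, value(C.AGE, "minors"))]
    )
    series = sex_series(results)
    (point,) = series["female_only"]
    assert (point.year, point.numerator, point.denominator) == (1990, 19, 65)
    assert point.percentage == 29.2
    (male_point,) = series["male_only"]
    assert male_point.percentage == 50.8
    assert [p.year for p in series["both"]] == [1990]  # 1991 omitted


def test_sex_series_both_only_year_gives_zero_female_only():
    results = [
        result("x", 2005, value(C.SEX, "male"), value(C.SEX, "female"))
    ]
    series = sex_series(results)
    assert series["female_only"][0].percentage == 0.0
    assert series["both"][0].percentage == 100.0


def test_offender_rates_multi_category_counts_denominator_once():
    results = [
        result(
            "a", 2000,
            value(C.OFFENDER_TYPE, "sex"),
            value(C.OFFENDER_TYPE, "violent", "assault"),
            value(C.SEX, "male"),
        ),
        result("b", 2000, value(C.OFFENDER_TYPE, "mentally-ill")),
    ]
    breakdown = offender_rates(results)
    assert breakdown.denominator == 2
    assert breakdown.shares[OffenderCategory.SEX] == (1, 50.0)
    assert breakdown.shares[OffenderCategory.VIOLENT] == (1, 50.0)
    assert breakdown.shares[OffenderCategory.MENTALLY_ILL] == (1, 50.0)
    cross = breakdown.sex_crosstab[OffenderCategory.SEX]
    assert cross["male"] == (1, 100.0)
    assert cross["unknown"] == (0, 0.0)
    mentally = breakdown.sex_crosstab[OffenderCategory.MENTALLY_ILL]
    assert mentally["unknown"] == (1, 100.0)


def test_aggregation_counts_match_direct_count_oracle():
    rng = random.Random(29)
    pool = [
        value(C.AGE, "minors"), value(C.AGE, "18-24"),
        value(C.SEX, "male"), value(C.SEX, "female"),
        value(C.NATIONALITY, "Norwegian"),
        value(C.OFFENDER_TYPE, "sex"),
        value(C.OFFENDER_TYPE, "miscellaneous", "prisoner"),
    ]
    results = [
        AbstractResult(
            f"p{i}",
            rng.choice([1995, 2005, None]),
            frozenset(rng.sample(pool, rng.randint(0, len(pool)))),
        )
        for i in range(200)
    ]
    summary = summarize_corpus(results)
    for kind in C:
        direct = sum(1 for r in results if any(v.kind is kind for v in r.values))
        assert summary.per_characteristic[kind][0] == direct
    table, denom = age_distribution(results)
    age_reporting = [r for r in results if any(v.kind is C.AGE for v in r.values)]
    assert denom == len(age_reporting)
    assert table[AgeGroup.MINOR][0] == sum(
        1 for r in age_reporting if value(C.AGE, "minors") in r.values
    )
    counts = nationality_counts(results)
    assert counts["Norwegian"] == sum(
        1 for r in results if value(C.NATIONALITY, "Norwegian") in r.values
    )


# ---------------------------------------------------------------------------
# Country rankings

@pytest.mark.parametrize(
    ("articles", "population", "expected"),
    [
        (138, 3289, 42.0),    # Norway
        (261, 6510, 40.1),    # Sweden
        (135, 3238, 41.7),    # Finland
        (125, 3729, 33.5),    # Denmark
        (730, 30685, 23.8),   # Australia
        (0, 1000, 0.0),
    ],
)
def test_rate_per_1000(articles, population, expected):
    assert rate_per_1000(articles, population) == expected


def test_country_ranking_on_benchmark_counts():
    ranking = country_ranking(
        benchmark_nationality_counts(), default_prisoner_table()
    )
    by_country = {s.country: s for s in ranking}
    norway = by_country["Norway"]
    assert (norway.rate, norway.rate_rank) == (42.0, 1)
    assert by_country["Finland"].rate_rank == 2
    assert by_country["Sweden"].rate_rank == 3
    assert by_country["Denmark"].rate_rank == 4
    assert by_country["Australia"].rate_rank == 5
    assert by_country["United States"].crude_rank == 1
    assert by_country["United States"].rate_rank == 16
    assert by_country["China"].rate_rank == 20
    # Japan and Spain round to the same rate and share a displayed rank
    assert by_country["Japan"].rate == by_country["Spain"].rate == 3.1
    assert by_country["Japan"].rate_rank_display == "13/14"
    assert by_country["Spain"].rate_rank_display == "13/14"


def test_country_ranking_excludes_unknown_demonyms(caplog):
    counts = {"Norwegian": 10, "Klingon": 5}
    with caplog.at_level("WARNING"):
        ranking = country_ranking(counts, default_prisoner_table())
    assert [s.demonym for s in ranking] == ["Norwegian"]
    assert any("Klingon" in r.message for r in caplog.records)


def test_rate_rank_invariant_to_common_scaling():
    counts = benchmark_nationality_counts()
    table = default_prisoner_table()
    base = {s.country: s.rate_rank for s in country_ranking(counts, table)}
    scaled_counts = {k: v * 3 for k, v in counts.items()}
    scaled = {s.country: s.rate_rank for s in country_ranking(scaled_counts, table)}
    assert base == scaled
    # values themselves do change under scaling
    assert any(
        a.rate != b.rate
        for a, b in zip(
            country_ranking(counts, table), country_ranking(scaled_counts, table)
        )
    )


# ---------------------------------------------------------------------------
# Correlation

def test_correlation_perfect_linear():
    x = [1.0, 2.0, 3.0, 4.0]
    assert correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
    assert correlation(x, [-v for v in x]) == pytest.approx(-1.0)


def test_correlation_matches_textbook_formula():
    rng = random.Random(41)
    x = [rng.uniform(0, 100) for _ in range(30)]
    y = [rng.uniform(0, 100) for _ in range(30)]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5
        * sum((b - my) ** 2 for b in y) ** 0.5
    )
    assert correlation(x, y) == pytest.approx(num / den, abs=1e-12)


def test_correlation_degenerate_inputs():
    with pytest.raises(ValueError):
        correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        correlation([1.0, 2.0], [1.0, 2.0])
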