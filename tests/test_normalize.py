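"""Standardization: age binning, sex categories, nationality canonicalization,
offender taxonomy, and abstract-level deduplication."""

import random

import pytest

from popchar.model import (
    AgeGroup,
    Characteristic,
    NUMERIC_AGE_GROUPS,
    OffenderCategory,
    StandardizedValue,
)
from popchar.normalize import (
    age_groups_from_bounds,
    dedupe_abstract,
    prune_contained,
)

C = Characteristic


# ---------------------------------------------------------------------------
# Worked standardization rows (extracted mention -> standardized value)

def test_row_women_is_female(normalizer, mk_mention):
    assert normalizer.normalize_sex(mk_mention(C.SEX, "Women")) == {"female"}


def test_row_boys_and_girls_is_male_and_female(normalizer, mk_mention):
    assert normalizer.normalize_sex(mk_mention(C.SEX, "Boys and girls")) == {
        "male", "female",
    }


def test_row_women_with_bpd_yields_sex_and_offender(engine):
    """A single phrase can carry two characteristics: sex and a mentally
    ill offender type with the disorder as attribute."""
    from popchar.model import AbstractRecord
    from popchar.pipeline import extract_abstract

    lexicons, rules, normalizer = engine
    record = AbstractRecord(
        pmid="1",
        text="Women with borderline personality disorder were interviewed.",
    )
    _, values = extract_abstract(record, rules, normalizer)
    assert StandardizedValue(C.SEX, "female") in values
    assert (
        StandardizedValue(
            C.OFFENDER_TYPE, "mentally-ill", "borderline personality disorder"
        )
        in values
    )


@pytest.mark.parametrize(
    ("surface", "category", "attribute"),
    [
        ("Child molester", "child-crime-related", "child sex abuse"),
        ("Male sex offenders", "sex", None),
        ("Serial rapists", "sex", "rape"),
        ("Psychotic inmates", "mentally-ill", "psychosis"),
        ("Ex-offenders", "miscellaneous", "ex-offender"),
    ],
)
def test_rows_offender_type(normalizer, mk_mention, surface, category, attribute):
    value = normalizer.normalize_offender(mk_mention(C.OFFENDER_TYPE, surface))
    assert (value.label, value.attribute) == (category, attribute)


def test_row_age_18_25_spans_two_bands(normalizer, mk_mention):
    mention = mk_mention(C.AGE, "Age 18-25 years", low=18, high=25)
    assert normalizer.normalize_age(mention) == {
        AgeGroup.A18_24, AgeGroup.A25_34,
    }


@pytest.mark.parametrize(
    ("surface", "expected"),
    [("Iowa", "American"), ("Norway", "Norwegian")],
)
def test_rows_nationality(normalizer, mk_mention, surface, expected):
    assert normalizer.normalize_nationality(mk_mention(C.NATIONALITY, surface)) == expected


# ---------------------------------------------------------------------------
# Age

def test_numeric_wide_range_covers_all_bands(normalizer, mk_mention):
    mention = mk_mention(C.AGE, "17 to 66 years", low=17, high=66)
    assert normalizer.normalize_age(mention) == set(NUMERIC_AGE_GROUPS)


def test_numeric_overlap_matches_enumeration_oracle():
    """Interval overlap against a brute-force oracle over integer years."""
    rng = random.Random(5)
    spans = {g: set(range(g.bounds[0], (g.bounds[1] or 120) + 1))
             for g in NUMERIC_AGE_GROUPS}
    for _ in range(200):
        low = rng.randint(0, 90)
        high = rng.randint(low, 95)
        expected = {g for g, years in spans.items()
                    if years & set(range(low, high + 1))}
        assert age_groups_from_bounds(low, high) == expected


def test_open_ended_bounds():
    assert age_groups_from_bounds(65, None) == {AgeGroup.A65_PLUS}
    assert age_groups_from_bounds(51, None) == {
        AgeGroup.A45_54, AgeGroup.A55_64, AgeGroup.A65_PLUS,
    }


def test_range_inside_one_band_is_singleton():
    assert age_groups_from_bounds(26, 30) == {AgeGroup.A25_34}


@pytest.mark.parametrize(
    ("term", "groups"),
    [
        ("adolescent", {AgeGroup.MINOR, AgeGroup.A18_24}),
        ("juvenile", {AgeGroup.MINOR}),
        ("delinquents", {AgeGroup.MINOR}),
        ("young offenders", {AgeGroup.MINOR, AgeGroup.A18_24}),
        ("adults", {AgeGroup.UNKNOWN_ADULT}),
    ],
)
def test_textual_age_terms(normalizer, mk_mention, term, groups):
    assert normalizer.normalize_age(mk_mention(C.AGE, term)) == groups


def test_unknown_textual_age_raises(normalizer, mk_mention):
    with pytest.raises(ValueError):
        normalizer.normalize_age(mk_mention(C.AGE, "centenarianish"))


def test_unknown_adult_never_coexists_with_numeric_band_from_one_mention(
    normalizer, mk_mention
):
    for surface in ("adults", "adult"):
        groups = normalizer.normalize_age(mk_mention(C.AGE, surface))
        assert groups == {AgeGroup.UNKNOWN_ADULT}


# ---------------------------------------------------------------------------
# Sex / nationality details

def test_unknown_sex_term_raises(normalizer, mk_mention):
    with pytest.raises(ValueError):
        normalizer.normalize_sex(mk_mention(C.SEX, "persons"))


def test_bare_trans_terms_map_to_unspecified_transgender(normalizer, mk_mention):
    assert normalizer.normalize_sex(mk_mention(C.SEX, "trans")) == {"transgender"}
    assert normalizer.normalize_sex(mk_mention(C.SEX, "transgender women")) == {
        "transgender woman",
    }


@pytest.mark.parametrize(
    "surface", ["United Kingdom", "Great Britain", "Britain", "UK"]
)
def test_uk_variants_one_label(normalizer, mk_mention, surface):
    assert normalizer.normalize_nationality(mk_mention(C.NATIONALITY, surface)) == "British"


def test_defunct_nationalities_are_miscellaneous(normalizer, mk_mention):
    for surface in ("Czechoslovakian", "Yugoslavia", "Soviet Union"):
        assert (
            normalizer.normalize_nationality(mk_mention(C.NATIONALITY, surface))
            == "miscellaneous"
        )


def test_nationality_total_over_shipped_geo_lexicons(normalizer, lexicons, mk_mention):
    """Every entry of every geographic lexicon standardizes to a canonical."""
    from popchar.normalize import GEO_PRECEDENCE

    for name in GEO_PRECEDENCE:
        for term in lexicons[name].entries:
            label = normalizer.normalize_nationality(mk_mention(C.NATIONALITY, term))
            assert label and isinstance(label, str)


# ---------------------------------------------------------------------------
# Offender taxonomy

def test_unmapped_offender_surface_falls_back_to_miscellaneous(normalizer, mk_mention):
    value = normalizer.normalize_offender(
        mk_mention(C.OFFENDER_TYPE, "quibble mongers")
    )
    assert value.label == "miscellaneous"
    assert value.attribute == "quibble mongers"


def test_population_terms_standardize_as_miscellaneous(normalizer, mk_mention):
    value = normalizer.normalize_offender(mk_mention(C.OFFENDER_TYPE, "prisoners"))
    assert (value.label, value.attribute) == ("miscellaneous", "prisoner")


def test_offense_category_closure(normalizer, lexicons):
    """Every offense canonical maps to exactly one of the 7 categories."""
    categories = {c.value for c in OffenderCategory}
    for canonical in set(lexicons["offense_terms"].entries.values()):
        category, _ = normalizer.offense_categories[canonical]
        assert category.value in categories


# ---------------------------------------------------------------------------
# Dedup & pruning

def test_dedupe_collapses_equal_values():
    female = StandardizedValue(C.SEX, "female")
    assert dedupe_abstract([female, female]) == {female}
    assert dedupe_abstract([]) == frozenset()
    values = [
        StandardizedValue(C.NATIONALITY, "Norwegian"),
        StandardizedValue(C.NATIONALITY, "American"),
        StandardizedValue(C.NATIONALITY, "Norwegian"),
    ]
    assert dedupe_abstract(values) == set(values)


def test_dedupe_idempotent():
    values = frozenset(
        {StandardizedValue(C.SEX, "female"), StandardizedValue(C.AGE, "minors")}
    )
    assert dedupe_abstract(dedupe_abstract(values)) == dedupe_abstract(values)


def test_prune_drops_strictly_contained_spans(mk_mention):
    from popchar.model import MentionSpan

    outer = MentionSpan(C.OFFENDER_TYPE, "sex offenders", 0, 13, "A")
    inner = MentionSpan(C.OFFENDER_TYPE, "offenders", 4, 13, "B")
    cross = MentionSpan(C.AGE, "offenders", 4, 13, "C")
    kept = prune_contained([outer, inner, cross])
    assert kept == [outer]
    # equal spans of different characteristics both survive
    dual_a = MentionSpan(C.AGE, "juveniles", 0, 9, "A")
    dual_b = MentionSpan(C.OFFENDER_TYPE, "juveniles", 0, 9, "B")
    assert set(prune_contained([dual_a, dual_b])) == {dual_a, dual_b}
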