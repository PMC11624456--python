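"""Descriptive gap analytics over standardized per-abstract results.

Covers characteristic coverage and combinations, age-band and
offender-category distributions (denominators are the characteristic-
reporting abstracts, and one abstract may contribute to several bands or
categories), sex-composition and offender-rate time series, and crude
versus prisoner-population-adjusted country rankings. All percentages are
one decimal, half-up; country rate ranks are computed on unrounded rates
with a shared display rank when the rounded rates tie.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats as _scipy_stats

from .model import AgeGroup, Characteristic, OffenderCategory, StandardizedValue
from .util import ValidationError, pct_half_up, rate_per_1000

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbstractResult:
    """Deduplicated standardized values of one abstract, with its year."""

    pmid: str
    year: Optional[int]
    values: frozenset[StandardizedValue]

    def kinds(self) -> frozenset[Characteristic]:
        return frozenset(v.kind for v in self.values)


@dataclass
class CorpusSummary:
    total: int
    per_characteristic: dict[Characteristic, tuple[int, float]]
    all_four: tuple[int, float]
    none: tuple[int, float]
    combinations: dict[frozenset, int] = field(default_factory=dict)


def summarize_corpus(results: Sequence[AbstractResult]) -> CorpusSummary:
    """Coverage counts: how many abstracts report each characteristic, all
    four, or none at all."""
    if not results:
        raise ValueError("empty corpus")
    total = len(results)
    per: dict[Characteristic, tuple[int, float]] = {}
    kind_sets = [r.kinds() for r in results]
    for kind in Characteristic:
        n = sum(1 for kinds in kind_sets if kind in kinds)
        per[kind] = (n, pct_half_up(n, total))
    all_four = sum(1 for kinds in kind_sets if len(kinds) == 4)
    none = sum(1 for kinds in kind_sets if not kinds)
    combos = Counter(kind_sets)
    return CorpusSummary(
        total,
        per,
        (all_four, pct_half_up(all_four, total)),
        (none, pct_half_up(none, total)),
        dict(combos),
    )


def age_distribution(
    results: Sequence[AbstractResult],
) -> tuple[dict[AgeGroup, tuple[int, float]], int]:
    """Abstract counts and percentages per age band. The denominator is the
    number of age-reporting abstracts; one abstract can include more than
    one age band."""
    reporting = [
        r for r in results if Characteristic.AGE in r.kinds()
    ]
    denominator = len(reporting)
    table: dict[AgeGroup, tuple[int, float]] = {}
    for group in AgeGroup:
        n = sum(
            1
            for r in reporting
            if StandardizedValue(Characteristic.AGE, group.value) in r.values
        )
        pct = pct_half_up(n, denominator) if denominator else 0.0
        table[group] = (n, pct)
    return table, denominator


@dataclass(frozen=True)
class SeriesPoint:
    year: int
    numerator: int
    denominator: int

    @property
    def percentage(self) -> float:
        return pct_half_up(self.numerator, self.denominator)


def _sex_labels(result: AbstractResult) -> set[str]:
    return {
        v.label for v in result.values if v.kind is Characteristic.SEX
    }


def sex_series(
    results: Sequence[AbstractResult],
) -> dict[str, list[SeriesPoint]]:
    """Yearly proportions of female-only, male-only, and both-sex abstracts
    among the sex-reporting abstracts of each year. Female-only means the
    sex value set is exactly {female}; 'both' means it contains male and
    female. Years without sex-reporting abstracts are omitted; undated
    records are excluded with a logged count."""
    by_year: dict[int, list[AbstractResult]] = defaultdict(list)
    undated = 0
    for r in results:
        if Characteristic.SEX not in r.kinds():
            continue
        if r.year is None:
            undated += 1
            continue
        by_year[r.year].append(r)
    if undated:
        logger.info("sex_series: %d sex-reporting abstracts without a year", undated)
    series: dict[str, list[SeriesPoint]] = {
        "female_only": [], "male_only": [], "both": []
    }
    for year in sorted(by_year):
        group = by_year[year]
        denom = len(group)
        fem = sum(1 for r in group if _sex_labels(r) == {"female"})
        male = sum(1 for r in group if _sex_labels(r) == {"male"})
        both = sum(1 for r in group if {"male", "female"} <= _sex_labels(r))
        series["female_only"].append(SeriesPoint(year, fem, denom))
        series["male_only"].append(SeriesPoint(year, male, denom))
        series["both"].append(SeriesPoint(year, both, denom))
    return series


def _offender_categories(result: AbstractResult) -> set[OffenderCategory]:
    return {
        OffenderCategory(v.label)
        for v in result.values
        if v.kind is Characteristic.OFFENDER_TYPE
    }


@dataclass
class OffenderBreakdown:
    """Per-category share of offender-reporting abstracts, cross-tabulated
    by sex (male/female/unknown within each category), plus yearly rates."""

    denominator: int
    shares: dict[OffenderCategory, tuple[int, float]]
    sex_crosstab: dict[OffenderCategory, dict[str, tuple[int, float]]]
    yearly: dict[OffenderCategory, list[SeriesPoint]]


def offender_rates(results: Sequence[AbstractResult]) -> OffenderBreakdown:
    """Category shares use the offender-reporting abstracts as denominator
    (one abstract may carry several categories); yearly series use the
    offender-reporting abstracts of each year."""
    reporting = [
        r for r in results if Characteristic.OFFENDER_TYPE in r.kinds()
    ]
    denominator = len(reporting)
    shares: dict[OffenderCategory, tuple[int, float]] = {}
    crosstab: dict[OffenderCategory, dict[str, tuple[int, float]]] = {}
    for category in OffenderCategory:
        members = [r for r in reporting if category in _offender_categories(r)]
        n = len(members)
        shares[category] = (n, pct_half_up(n, denominator) if denominator else 0.0)
        male = sum(1 for r in members if "male" in _sex_labels(r))
        female = sum(1 for r in members if "female" in _sex_labels(r))
        unknown = sum(
            1 for r in members if not ({"male", "female"} & _sex_labels(r))
        )
        crosstab[category] = {
            label: (count, pct_half_up(count, n) if n else 0.0)
            for label, count in (
                ("male", male), ("female", female), ("unknown", unknown)
            )
        }
    yearly: dict[OffenderCategory, list[SeriesPoint]] = {
        c: [] for c in OffenderCategory
    }
    by_year: dict[int, list[AbstractResult]] = defaultdict(list)
    for r in reporting:
        if r.year is not None:
            by_year[r.year].append(r)
    for year in sorted(by_year):
        group = by_year[year]
        for category in OffenderCategory:
            n = sum(1 for r in group if category in _offender_categories(r))
            yearly[category].append(SeriesPoint(year, n, len(group)))
    return OffenderBreakdown(denominator, shares, crosstab, yearly)


# ---------------------------------------------------------------------------
# Country rankings adjusted by prisoner population


@dataclass(frozen=True)
class CountryStats:
    country: str
    demonym: str
    continent: str
    articles: int
    prisoner_population: int
    crude_rank: int
    rate: float  # articles per 1000 prisoners, one decimal half-up
    rate_rank: int  # competition rank on the unrounded rate
    rate_rank_display: str  # shared range (e.g. "13/14") on rounded ties


@dataclass(frozen=True)
class PrisonerTableRow:
    country: str
    demonym: str
    continent: str
    population: int


def load_prisoner_table(path: str | Path) -> list[PrisonerTableRow]:
    """TSV: country <tab> demonym <tab> continent <tab> average prisoner
    population."""
    rows: list[PrisonerTableRow] = []
    path = Path(path)
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValidationError(f"{path.name}:{lineno}: expected 4 columns")
        rows.append(
            PrisonerTableRow(
                parts[0].strip(), parts[1].strip(), parts[2].strip(),
                int(parts[3].replace(",", "")),
            )
        )
    if not rows:
        raise ValidationError(f"{path.name}: empty prisoner table")
    return rows


def nationality_counts(results: Sequence[AbstractResult]) -> Counter:
    """Articles per canonical demonym (one count per abstract per demonym)."""
    counts: Counter = Counter()
    for r in results:
        for v in r.values:
            if v.kind is Characteristic.NATIONALITY:
                counts[v.label] += 1
    return counts


def country_ranking(
    article_counts: Mapping[str, int],
    prisoner_table: Sequence[PrisonerTableRow],
) -> list[CountryStats]:
    """Crude rank by article count, population-adjusted rank by articles
    per 1000 prisoners. Demonyms missing from the prisoner table are
    excluded with a warning. Returned in crude-rank order."""
    by_demonym = {row.demonym: row for row in prisoner_table}
    entries = []
    for demonym, articles in article_counts.items():
        row = by_demonym.get(demonym)
        if row is None:
            logger.warning(
                "no prisoner population for %r; excluded from ranking", demonym
            )
            continue
        exact = 1000 * articles / row.population
        entries.append((row, articles, exact, rate_per_1000(articles, row.population)))

    # competition ("1224") ranking helper: ties share the smallest rank
    def competition_ranks(keys: list) -> list[int]:
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        ranks = [0] * len(keys)
        for position, idx in enumerate(order):
            if position > 0 and keys[order[position - 1]] == keys[idx]:
                ranks[idx] = ranks[order[position - 1]]
            else:
                ranks[idx] = position + 1
        return ranks

    crude = competition_ranks([-articles for _, articles, _, _ in entries])
    rate_ranks = competition_ranks([-exact for _, _, exact, _ in entries])
    # display rank shares a range when the *rounded* rates tie
    rounded = [rounded_rate for *_, rounded_rate in entries]
    display: list[str] = []
    for i, value in enumerate(rounded):
        group = sorted(rate_ranks[j] for j, v in enumerate(rounded) if v == value)
        if len(group) > 1:
            display.append("/".join(str(r) for r in group))
        else:
            display.append(str(rate_ranks[i]))
    stats = [
        CountryStats(
            row.country, row.demonym, row.continent, articles, row.population,
            crude[i], entries[i][3], rate_ranks[i], display[i],
        )
        for i, (row, articles, _, _) in enumerate(entries)
    ]
    stats.sort(key=lambda s: s.crude_rank)
    return stats


def correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient in [-1, 1]."""
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("zero variance in input series")
    return float(_scipy_stats.pearsonr(list(x), list(y)).statistic)
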