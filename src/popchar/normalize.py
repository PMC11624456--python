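"""Standardization of raw mentions into canonical abstract-level values.

Maps each raw capture to the standard vocabularies: statistical age bands
(numeric bounds map to every band their closed interval overlaps; textual
terms map through the shipped term table), five sex categories, nationality
demonyms (all US subdivisions collapse to "American", defunct nationalities
to "miscellaneous"), and the seven offender categories with an optional
specific attribute (e.g. sex offender / rape). Duplicate standardized
values within an abstract collapse to a set, mirroring abstract-level
evaluation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .lexicons import Lexicon, fold_term
from .model import (
    AgeGroup,
    Characteristic,
    MentionSpan,
    NUMERIC_AGE_GROUPS,
    OffenderCategory,
    StandardizedValue,
)
from .util import ValidationError

logger = logging.getLogger(__name__)

#: Textual age classifications: canonical term-table label -> age bands.
TEXTUAL_AGE_CLASSES: dict[str, frozenset[AgeGroup]] = {
    "minors": frozenset({AgeGroup.MINOR}),
    "minors-and-18-24": frozenset({AgeGroup.MINOR, AgeGroup.A18_24}),
    "unknown-adult": frozenset({AgeGroup.UNKNOWN_ADULT}),
}

#: Precedence when one surface could standardize through several geographic
#: dictionaries: the more specific national identity first.
GEO_PRECEDENCE = (
    "countries",
    "nationalities",
    "us_states",
    "us_counties",
    "us_cities",
    "world_cities",
)


def age_groups_from_bounds(
    low: int, high: Optional[int]
) -> frozenset[AgeGroup]:
    """Every numeric age band whose closed interval overlaps [low, high]
    (high=None is open-ended). Bands are closed integer intervals, so a
    mention of 18-25 overlaps both 18-24 and 25-34."""
    groups = set()
    for group in NUMERIC_AGE_GROUPS:
        lo_g, hi_g = group.bounds
        if hi_g is not None and low > hi_g:
            continue
        if high is not None and high < lo_g:
            continue
        groups.add(group)
    return frozenset(groups)


class Normalizer:
    """Holds the standardization tables and the lexicons they key off.

    ``offense_categories`` maps each offense-lexicon canonical label to an
    (OffenderCategory, attribute) pair; an empty attribute means the
    canonical is itself the category-level term (e.g. ``sex offence``).
    Category closure over the offense lexicon is validated on construction.
    """

    def __init__(
        self,
        lexicons: Mapping[str, Lexicon],
        age_classes: Mapping[str, str],
        offense_categories: Mapping[str, tuple[OffenderCategory, Optional[str]]],
    ) -> None:
        self.lexicons = dict(lexicons)
        self.age_classes = {fold_term(k): v for k, v in age_classes.items()}
        self.offense_categories = dict(offense_categories)
        for label, cls in self.age_classes.items():
            if cls not in TEXTUAL_AGE_CLASSES:
                raise ValidationError(
                    f"age term {label!r}: unknown classification {cls!r}"
                )
        offense = self.lexicons.get("offense_terms")
        if offense is not None:
            missing = sorted(
                set(offense.entries.values()) - set(self.offense_categories)
            )
            if missing:
                raise ValidationError(
                    "offense canonicals without a category mapping: "
                    + ", ".join(missing)
                )

    # -- age ---------------------------------------------------------------

    def normalize_age(self, mention: MentionSpan) -> frozenset[AgeGroup]:
        """Age bands for a mention; numeric bounds via interval overlap,
        textual terms via the term table. Raises ValueError for unknown
        textual terms (callers drop the mention with a warning)."""
        if mention.low is not None:
            return age_groups_from_bounds(mention.low, mention.high)
        key = fold_term(mention.surface)
        cls = self.age_classes.get(key)
        if cls is None:
            # tolerate captures wider than the bare term ("the adolescents")
            for term, candidate in self.age_classes.items():
                if _contains_term(key, term):
                    cls = candidate
                    break
        if cls is None:
            raise ValueError(f"unknown textual age term {mention.surface!r}")
        return TEXTUAL_AGE_CLASSES[cls]

    # -- sex ---------------------------------------------------------------

    def normalize_sex(self, mention: MentionSpan) -> frozenset[str]:
        """Sex category labels; conjoined surfaces ('boys and girls') yield
        multiple categories."""
        lexicon = self.lexicons["sex_terms"]
        parts = [
            p
            for p in _CONJ_SPLIT.split(mention.surface)
            if p and p.strip()
        ]
        categories: set[str] = set()
        for part in parts:
            canonical = lexicon.lookup(part) or lexicon.best_internal_match(part)
            if canonical:
                categories.add(canonical)
        if not categories:
            raise ValueError(f"unknown sex term {mention.surface!r}")
        return frozenset(categories)

    # -- nationality -------------------------------------------------------

    def normalize_nationality(self, mention: MentionSpan) -> str:
        """Canonical demonym for a geographic/nationality surface; total
        over the shipped geo lexicons (every entry has a canonical)."""
        surface = mention.surface
        geo = [
            self.lexicons[name]
            for name in GEO_PRECEDENCE
            if name in self.lexicons
        ]
        for lexicon in geo:
            canonical = lexicon.lookup(surface)
            if canonical:
                return canonical
        best: tuple[int, int, str] | None = None  # (-len, precedence, label)
        for precedence, lexicon in enumerate(geo):
            for match in lexicon.iter_matches(surface):
                key = (-len(match), precedence, match.canonical)
                if best is None or key < best:
                    best = key
        if best is None:
            raise ValueError(f"unknown nationality surface {surface!r}")
        return best[2]

    # -- offender type -----------------------------------------------------

    def normalize_offender(self, mention: MentionSpan) -> StandardizedValue:
        """Two-level offender value: high-level category plus optional
        specific attribute. Unmappable surfaces fall back to miscellaneous
        with the folded surface as attribute."""
        surface = mention.surface
        offense = self.lexicons.get("offense_terms")
        population = self.lexicons.get("population_terms")
        canonical = None
        for lexicon in (offense, population):
            if lexicon is not None:
                canonical = lexicon.lookup(surface)
                if canonical:
                    break
        if canonical is None:
            for lexicon in (offense, population):
                if lexicon is not None:
                    canonical = lexicon.best_internal_match(surface)
                    if canonical:
                        break
        if canonical is None:
            attribute = fold_term(surface)
            return StandardizedValue(
                Characteristic.OFFENDER_TYPE,
                OffenderCategory.MISCELLANEOUS.value,
                attribute,
            )
        category, attribute = self.offense_categories.get(
            canonical, (OffenderCategory.MISCELLANEOUS, canonical)
        )
        return StandardizedValue(
            Characteristic.OFFENDER_TYPE, category.value, attribute or None
        )

    # -- dispatch ----------------------------------------------------------

    def normalize_mention(
        self, mention: MentionSpan
    ) -> frozenset[StandardizedValue]:
        """Standardized value set for one raw mention (age/sex mentions may
        yield several values)."""
        kind = mention.characteristic
        if kind is Characteristic.AGE:
            return frozenset(
                StandardizedValue(kind, group.value)
                for group in self.normalize_age(mention)
            )
        if kind is Characteristic.SEX:
            return frozenset(
                StandardizedValue(kind, label)
                for label in self.normalize_sex(mention)
            )
        if kind is Characteristic.NATIONALITY:
            return frozenset({
                StandardizedValue(kind, self.normalize_nationality(mention))
            })
        return frozenset({self.normalize_offender(mention)})

    def standardize_mentions(
        self, mentions: Sequence[MentionSpan]
    ) -> frozenset[StandardizedValue]:
        """Abstract-level value set: prune strictly contained spans, map
        each surviving mention, drop unknowns with a warning, deduplicate."""
        values: set[StandardizedValue] = set()
        for mention in prune_contained(mentions):
            try:
                values.update(self.normalize_mention(mention))
            except ValueError as exc:
                logger.warning("dropped mention: %s", exc)
        return frozenset(values)


import re as _re

_CONJ_SPLIT = _re.compile(r"\s*(?:\band\b|\bor\b|,|/|&)\s*", _re.IGNORECASE)


def _contains_term(folded_surface: str, folded_term: str) -> bool:
    return _re.search(
        r"(?<!\S)" + _re.escape(folded_term) + r"(?!\S)", folded_surface
    ) is not None


def prune_contained(mentions: Sequence[MentionSpan]) -> list[MentionSpan]:
    """Drop mentions strictly contained inside another mention's span (any
    characteristic); keep equal spans from different rules/characteristics
    (deduplicated per (characteristic, span)). Applied before
    standardization so that 'sex offenders' does not also standardize its
    inner 'offenders'."""
    kept: list[MentionSpan] = []
    seen: set[tuple[Characteristic, int, int]] = set()
    for mention in mentions:
        contained = any(
            (other.start <= mention.start and mention.end <= other.end)
            and (other.end - other.start > mention.end - mention.start)
            for other in mentions
        )
        if contained:
            continue
        key = (mention.characteristic, mention.start, mention.end)
        if key in seen:
            continue
        seen.add(key)
        kept.append(mention)
    return kept


def dedupe_abstract(
    values: Iterable[StandardizedValue],
) -> frozenset[StandardizedValue]:
    """Abstract-level set semantics: duplicate standardized values collapse.
    Idempotent and order-independent."""
    return frozenset(values)


def load_age_classes(path: str | Path) -> dict[str, str]:
    """Read the textual age term table (term <tab> classification)."""
    table: dict[str, str] = {}
    path = Path(path)
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path.name}:{lineno}: expected two columns")
        table[parts[0].strip()] = parts[1].strip()
    if not table:
        raise ValidationError(f"{path.name}: empty age term table")
    return table


def load_offense_categories(
    path: str | Path,
) -> dict[str, tuple[OffenderCategory, Optional[str]]]:
    """Read the offense category table (canonical <tab> category <tab>
    optional attribute)."""
    table: dict[str, tuple[OffenderCategory, Optional[str]]] = {}
    path = Path(path)
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(
                f"{path.name}:{lineno}: expected canonical<TAB>category"
            )
        canonical = parts[0].strip()
        try:
            category = OffenderCategory(parts[1].strip())
        except ValueError as exc:
            raise ValidationError(
                f"{path.name}:{lineno}: unknown category {parts[1]!r}"
            ) from exc
        attribute = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
        if canonical in table:
            raise ValidationError(
                f"{path.name}:{lineno}: duplicate canonical {canonical!r}"
            )
        table[canonical] = (category, attribute)
    if not table:
        raise ValidationError(f"{path.name}: empty category table")
    return table
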