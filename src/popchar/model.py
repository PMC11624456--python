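"""Core domain types shared across the pipeline.

The unit of extraction is the abstract; the unit of evaluation is the
distinct standardized value per characteristic per abstract. Standardized
values are small frozen records with structural equality so that sets of
them behave like the published abstract-level annotation sets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Characteristic(enum.Enum):
    """The four population characteristics extracted from abstracts."""

    AGE = "AGE"
    SEX = "SEX"
    NATIONALITY = "NATIONALITY"
    OFFENDER_TYPE = "OFFENDER_TYPE"

    def __str__(self) -> str:  # used in gold files and result lines
        return self.value


class AgeGroup(enum.Enum):
    """Standard statistical age bands (Australian Bureau of Statistics),
    plus the 'unknown adult' band used for bare mentions of adults."""

    MINOR = "minors"
    A18_24 = "18-24"
    A25_34 = "25-34"
    A35_44 = "35-44"
    A45_54 = "45-54"
    A55_64 = "55-64"
    A65_PLUS = "65+"
    UNKNOWN_ADULT = "unknown-adult"

    @property
    def bounds(self) -> Optional[tuple[int, Optional[int]]]:
        """Closed integer interval in years; None for the open upper bound
        of 65+ and for the non-numeric unknown-adult band."""
        return _AGE_BOUNDS.get(self)


_AGE_BOUNDS: dict[AgeGroup, tuple[int, Optional[int]]] = {
    AgeGroup.MINOR: (0, 17),
    AgeGroup.A18_24: (18, 24),
    AgeGroup.A25_34: (25, 34),
    AgeGroup.A35_44: (35, 44),
    AgeGroup.A45_54: (45, 54),
    AgeGroup.A55_64: (55, 64),
    AgeGroup.A65_PLUS: (65, None),
}

#: Numeric age bands in ascending order (excludes UNKNOWN_ADULT).
NUMERIC_AGE_GROUPS: tuple[AgeGroup, ...] = tuple(_AGE_BOUNDS)


class SexCategory(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    TRANSGENDER = "transgender"
    TRANSGENDER_MAN = "transgender man"
    TRANSGENDER_WOMAN = "transgender woman"


class OffenderCategory(enum.Enum):
    CHILD_CRIME_RELATED = "child-crime-related"
    SEX = "sex"
    VIOLENT = "violent"
    NONVIOLENT = "nonviolent"
    MENTALLY_ILL = "mentally-ill"
    DRUG_RELATED = "drug-related"
    MISCELLANEOUS = "miscellaneous"


@dataclass(frozen=True)
class StandardizedValue:
    """A canonical abstract-level value for one characteristic.

    ``label`` is the canonical payload: an :class:`AgeGroup` value label,
    a :class:`SexCategory` value label, a nationality demonym, or an
    :class:`OffenderCategory` value label. Offender values may carry the
    specific descriptor as ``attribute`` (e.g. category ``sex`` with
    attribute ``rape``); a miscellaneous offender value always does.
    """

    kind: Characteristic
    label: str
    attribute: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is Characteristic.OFFENDER_TYPE:
            if (
                self.label == OffenderCategory.MISCELLANEOUS.value
                and not self.attribute
            ):
                raise ValueError(
                    "miscellaneous offender value requires an attribute"
                )
        elif self.attribute is not None:
            raise ValueError(f"{self.kind} values carry no attribute")

    @property
    def sort_key(self) -> tuple[str, str, str]:
        return (self.kind.value, self.label, self.attribute or "")


@dataclass(frozen=True)
class MentionSpan:
    """A raw in-text hit produced by a rule: 0-based half-open offsets into
    the whitespace-normalized abstract text. Numeric age captures carry
    parsed year bounds (``high`` is None when open-ended)."""

    characteristic: Characteristic
    surface: str
    start: int
    end: int
    rule_id: str
    low: Optional[int] = None
    high: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.low is not None and self.high is not None:
            if not (0 <= self.low <= self.high):
                raise ValueError(
                    f"invalid age bounds ({self.low}, {self.high})"
                )


@dataclass
class AbstractRecord:
    """One publication: identifier, year, and the abstract text that is the
    unit of extraction. Text is whitespace-normalized on construction."""

    pmid: str
    text: str
    year: Optional[int] = None
    title: Optional[str] = None
    language: str = "eng"

    def __post_init__(self) -> None:
        from .util import normalize_ws

        self.pmid = self.pmid.strip()
        self.text = normalize_ws(self.text)
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if not self.text:
            raise ValueError(f"record {self.pmid}: empty abstract text")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"record {self.pmid}: implausible year {self.year}")


@dataclass(frozen=True)
class GoldAnnotation:
    """Reference annotation for one abstract: the set of standardized
    values two annotators agreed on."""

    pmid: str
    values: frozenset[StandardizedValue] = field(default_factory=frozenset)
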