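"""Synthetic abstract generator with known gold annotations.

Emulates the statistical structure the extraction pipeline assumes: each
abstract is a template-composed paragraph that mentions each of the four
characteristics with a configurable inclusion probability, phrased through
the same lexical patterns the shipped rules recognise and filled with
surfaces sampled from the shipped dictionaries. Gold is recorded at the
standardized (abstract) level, so with noise disabled end-to-end
extraction recovers exactly the gold values.

Noise modes emulate the documented error sources: misspelling noise
corrupts the tokens of planted spans (producing false negatives while the
gold stays fixed, since gold reflects intended content), and unseen-pattern
noise plants characteristic statements phrased outside the rule set's
coverage (age and offender type only).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .model import (
    AbstractRecord,
    Characteristic,
    GoldAnnotation,
    MentionSpan,
    OffenderCategory,
    StandardizedValue,
)
from .normalize import Normalizer, age_groups_from_bounds
from .util import ValidationError

_PLACEHOLDER = re.compile(r"\{(\w+)\}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Default inclusion probabilities are the coverage rates observed in the
    reference corpus (age 14.9%, sex 23.7%, nationality 27.6%, offender
    type 13.9%); the year range spans the trend analyses (1990-2023).
    """

    n: int
    p_age: float = 0.149
    p_sex: float = 0.237
    p_nationality: float = 0.276
    p_offender: float = 0.139
    year_range: tuple[int, int] = (1990, 2023)
    misspell_probability: float = 0.0
    unseen_pattern_probability: float = 0.0
    noise_characteristics: Optional[tuple[Characteristic, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        for name in (
            "p_age", "p_sex", "p_nationality", "p_offender",
            "misspell_probability", "unseen_pattern_probability",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name}={value} outside [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValidationError("invalid year range")

    def probability(self, kind: Characteristic) -> float:
        return {
            Characteristic.AGE: self.p_age,
            Characteristic.SEX: self.p_sex,
            Characteristic.NATIONALITY: self.p_nationality,
            Characteristic.OFFENDER_TYPE: self.p_offender,
        }[kind]


@dataclass(frozen=True)
class PlantedSpan:
    characteristic: Characteristic
    start: int
    end: int
    surface: str


@dataclass
class SyntheticAbstract:
    record: AbstractRecord
    gold: GoldAnnotation
    planted: list[PlantedSpan] = field(default_factory=list)


@dataclass(frozen=True)
class Perturbation:
    """One corrupted token; spans refer to the perturbed text."""

    pmid: str
    characteristic: Characteristic
    start: int
    end: int
    original: str
    corrupted: str


# Sampling pools are deliberately restricted to surfaces that belong to a
# single characteristic (e.g. no "girls", which is both a sex term and a
# textual minor-age term), so the recorded gold is exactly the planted
# content.
SEX_SINGLE_POOL = (
    "men", "women", "males", "females",
    "transgender individuals", "transgender men", "transgender women",
)
SEX_PAIR_POOL = (("men", "women"), ("males", "females"), ("women", "men"))
AGE_TEXT_POOL = ("adolescents", "teenagers", "children", "minors")
NATIONALITY_POOL = (
    "Norway", "Sweden", "Finland", "Denmark", "Australia", "Canada",
    "Germany", "France", "Japan", "Brazil", "Netherlands", "Switzerland",
    "Spain", "Italy", "India", "China", "South Africa", "United States",
    "United Kingdom", "New Zealand",
)
OFFENSE_POOL = (
    "sex offenders", "violent offenders", "drug offenders", "serial rapists",
    "child molesters", "psychotic inmates", "shoplifters", "arsonists",
    "stalkers", "burglars", "drug traffickers", "murderers",
    "mentally ill offenders", "nonviolent offenders",
)
POPULATION_POOL = (
    "prisoners", "detainees", "inmates", "parolees", "probationers",
    "convicts", "felons",
)
FILLERS = (
    "This study linked administrative datasets across multiple jurisdictions.",
    "Outcomes were compared against matched community controls.",
    "Logistic regression models were adjusted for relevant covariates.",
    "Attrition over the follow-up period was minimal.",
    "Service contacts were ascertained through routine clinical records.",
)

# Statements whose phrasing lies outside the shipped rule set: planting one
# yields gold with no recoverable span (a controlled false-negative source).
UNSEEN_STATEMENTS: dict[Characteristic, tuple[tuple[str, tuple], ...]] = {
    Characteristic.AGE: (
        (
            "The median participant age fell in the fourth decade of life.",
            (StandardizedValue(Characteristic.AGE, "35-44"),),
        ),
    ),
    Characteristic.OFFENDER_TYPE: (
        (
            "Many participants were subject to restraining orders.",
            (
                StandardizedValue(
                    Characteristic.OFFENDER_TYPE,
                    OffenderCategory.MISCELLANEOUS.value,
                    "restraining order",
                ),
            ),
        ),
    ),
}

_NUMERIC_PHRASES = (
    "aged {low} to {high} years",
    "aged {low}-{high} years",
    "{low} to {high} years old",
    "aged {single}",
)


def load_templates(
    path: str | Path | None = None,
) -> dict[tuple[Characteristic, str], list[str]]:
    """Sentence templates keyed by (characteristic, slot kind)."""
    if path is None:
        from .resources import data_dir

        path = data_dir() / "templates" / "templates.tsv"
    templates: dict[tuple[Characteristic, str], list[str]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind_str, slot_kind, template = line.split("\t")
        templates.setdefault(
            (Characteristic(kind_str), slot_kind), []
        ).append(template)
    if not templates:
        raise ValidationError(f"{path}: no templates")
    return templates


def _fill(template: str, mapping: dict[str, str]) -> tuple[str, list[tuple[str, int, int]]]:
    parts: list[str] = []
    spans: list[tuple[str, int, int]] = []
    cursor = 0
    length = 0
    for m in _PLACEHOLDER.finditer(template):
        parts.append(template[cursor:m.start()])
        length += m.start() - cursor
        value = mapping[m.group(1)]
        spans.append((m.group(1), length, length + len(value)))
        parts.append(value)
        length += len(value)
        cursor = m.end()
    parts.append(template[cursor:])
    return "".join(parts), spans


def _dummy(kind: Characteristic, surface: str) -> MentionSpan:
    return MentionSpan(kind, surface, 0, len(surface), "generator")


class _AbstractBuilder:
    def __init__(self) -> None:
        self.sentences: list[str] = []
        self.planted: list[PlantedSpan] = []
        self.length = 0

    def add(self, sentence: str, spans: Sequence[tuple[Characteristic, int, int, str]] = ()) -> None:
        offset = self.length + (1 if self.sentences else 0)
        for kind, start, end, surface in spans:
            self.planted.append(PlantedSpan(kind, offset + start, offset + end, surface))
        self.sentences.append(sentence)
        self.length = offset + len(sentence)

    def text(self) -> str:
        return " ".join(self.sentences)


def _plant(
    kind: Characteristic,
    rng: random.Random,
    templates,
    normalizer: Normalizer,
    builder: _AbstractBuilder,
) -> set[StandardizedValue]:
    """Append one characteristic sentence; return its gold values."""
    if kind is Characteristic.AGE:
        if rng.random() < 0.5:
            phrase_template = rng.choice(_NUMERIC_PHRASES)
            if "{single}" in phrase_template:
                single = rng.randint(18, 70)
                phrase = phrase_template.format(single=single)
                groups = age_groups_from_bounds(single, single)
            else:
                low = rng.randint(10, 60)
                high = low + rng.randint(1, 15)
                phrase = phrase_template.format(low=low, high=high)
                groups = age_groups_from_bounds(low, high)
            template = rng.choice(templates[(kind, "numeric")])
            sentence, spans = _fill(template, {"term": phrase})
            values = {
                StandardizedValue(kind, group.value) for group in groups
            }
        else:
            term = rng.choice(AGE_TEXT_POOL)
            template = rng.choice(templates[(kind, "textual")])
            sentence, spans = _fill(template, {"term": term})
            values = {
                StandardizedValue(kind, group.value)
                for group in normalizer.normalize_age(_dummy(kind, term))
            }
    elif kind is Characteristic.SEX:
        if rng.random() < 0.25:
            a, b = rng.choice(SEX_PAIR_POOL)
            template = rng.choice(templates[(kind, "both")])
            sentence, spans = _fill(template, {"term": a, "term2": b})
            labels = normalizer.normalize_sex(_dummy(kind, a)) | (
                normalizer.normalize_sex(_dummy(kind, b))
            )
        else:
            term = rng.choice(SEX_SINGLE_POOL)
            template = rng.choice(templates[(kind, "single")])
            sentence, spans = _fill(template, {"term": term})
            labels = normalizer.normalize_sex(_dummy(kind, term))
        values = {StandardizedValue(kind, label) for label in labels}
    elif kind is Characteristic.NATIONALITY:
        term = rng.choice(NATIONALITY_POOL)
        template = rng.choice(templates[(kind, "country")])
        sentence, spans = _fill(template, {"term": term})
        values = {
            StandardizedValue(kind, normalizer.normalize_nationality(_dummy(kind, term)))
        }
    else:
        if rng.random() < 0.65:
            term = rng.choice(OFFENSE_POOL)
            template = rng.choice(templates[(kind, "offense")])
        else:
            term = rng.choice(POPULATION_POOL)
            template = rng.choice(templates[(kind, "population")])
        sentence, spans = _fill(template, {"term": term})
        values = {normalizer.normalize_offender(_dummy(kind, term))}
    placed = [
        (kind, start, end, sentence[start:end]) for _, start, end in spans
    ]
    builder.add(sentence, placed)
    return values


def generate(
    config: GeneratorConfig,
    normalizer: Normalizer | None = None,
    templates=None,
) -> list[SyntheticAbstract]:
    """Generate ``config.n`` abstracts; deterministic under a fixed seed.

    Misspelling / unseen-pattern noise is applied afterwards when the
    respective probabilities are positive (see :func:`inject_noise`).
    """
    if normalizer is None:
        from .resources import default_engine

        _, _, normalizer = default_engine()
    templates = templates or load_templates()
    rng = random.Random(config.seed)
    abstracts: list[SyntheticAbstract] = []
    for index in range(config.n):
        pmid = f"S{index + 1:06d}"
        builder = _AbstractBuilder()
        builder.add(rng.choice(FILLERS))
        gold: set[StandardizedValue] = set()
        for kind in Characteristic:
            if rng.random() >= config.probability(kind):
                continue
            unseen = UNSEEN_STATEMENTS.get(kind)
            if (
                unseen
                and config.unseen_pattern_probability > 0
                and rng.random() < config.unseen_pattern_probability
            ):
                sentence, values = unseen[rng.randrange(len(unseen))]
                builder.add(sentence)
                gold.update(values)
            else:
                gold.update(_plant(kind, rng, templates, normalizer, builder))
        builder.add(rng.choice(FILLERS))
        record = AbstractRecord(
            pmid=pmid,
            text=builder.text(),
            year=rng.randint(*config.year_range),
            title=f"Synthetic justice-health abstract {pmid}",
        )
        abstracts.append(
            SyntheticAbstract(
                record, GoldAnnotation(pmid, frozenset(gold)), builder.planted
            )
        )
    if config.misspell_probability > 0:
        abstracts, _ = inject_noise(abstracts, config)
    return abstracts


_TOKEN = re.compile(r"[A-Za-z]{2,}")


def _misspell(token: str, rng: random.Random) -> str:
    """Swap one adjacent differing letter pair; '' if impossible."""
    positions = [i for i in range(len(token) - 1) if token[i] != token[i + 1]]
    if not positions:
        return ""
    i = rng.choice(positions)
    return token[:i] + token[i + 1] + token[i] + token[i + 2:]


def inject_noise(
    abstracts: Sequence[SyntheticAbstract],
    config: GeneratorConfig,
) -> tuple[list[SyntheticAbstract], list[Perturbation]]:
    """Corrupt planted spans with misspellings at the configured
    probability; gold is unchanged (it reflects intended content) and every
    perturbed token is logged, so expected false negatives are computable.

    A selected span has *all* its alphabetic tokens corrupted: a partially
    misspelled phrase can still satisfy a shorter rule, which would make
    the noise ineffective as a false-negative source.
    """
    targets = config.noise_characteristics or tuple(Characteristic)
    rng = random.Random((config.seed * 2654435761 + 101) % (2**31))
    out: list[SyntheticAbstract] = []
    log: list[Perturbation] = []
    for abstract in abstracts:
        text = abstract.record.text
        changed = False
        for span in abstract.planted:
            if span.characteristic not in targets:
                continue
            if rng.random() >= config.misspell_probability:
                continue
            segment = text[span.start:span.end]
            new_segment = segment
            for m in list(_TOKEN.finditer(segment)):
                corrupted = _misspell(m.group(0), rng)
                if not corrupted:
                    continue
                new_segment = (
                    new_segment[: m.start()] + corrupted + new_segment[m.end():]
                )
                log.append(
                    Perturbation(
                        abstract.record.pmid,
                        span.characteristic,
                        span.start + m.start(),
                        span.start + m.end(),
                        m.group(0),
                        corrupted,
                    )
                )
            if new_segment != segment:
                text = text[: span.start] + new_segment + text[span.end:]
                changed = True
        if changed:
            record = replace(abstract.record, text=text)
            out.append(SyntheticAbstract(record, abstract.gold, abstract.planted))
        else:
            out.append(abstract)
    return out, log


def write_corpus(
    abstracts: Sequence[SyntheticAbstract], directory: str | Path
) -> tuple[Path, Path]:
    """Emit the corpus as MEDLINE flat format plus a TSV gold file — the
    same formats the readers consume, enabling full-loop testing through
    the public interfaces."""
    from .corpus_io import write_gold, write_medline

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    corpus_path = directory / "corpus.medline"
    gold_path = directory / "gold.tsv"
    write_medline([a.record for a in abstracts], corpus_path)
    write_gold([a.gold for a in abstracts], gold_path)
    return corpus_path, gold_path
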