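"""Semifrozen lexical-pattern rules and the numeric-age parser.

A rule is an ordered sequence of elements anchored on frozen syntactic
material: literal token sequences (``LIT:"characteristics of"``), regular
expression anchors (``RX:"(?:in|from)"``), and lexicon slots
(``SLOT:offense_terms!``) filled by dictionary entries. Elements marked
with ``!`` are captures: each capture occurrence yields one raw mention.

The line-oriented DSL (UTF-8, ``#`` comments)::

    ID <TAB> CHARACTERISTIC <TAB> element;element;...

with elements ``LIT:"..."``, ``LIT!:"..."``, ``RX:"..."``, ``RX!:"..."``,
``SLOT:<lexicon>`` and ``SLOT:<lexicon>!`` (``!capture`` also accepted).
Rules match case-insensitively over the whitespace-normalized abstract;
adjacent elements may be separated by whitespace or light punctuation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .lexicons import BOUND_L, BOUND_R, Lexicon, phrase_core
from .model import AbstractRecord, Characteristic, MentionSpan
from .util import ValidationError

logger = logging.getLogger(__name__)

# Separator tolerated between rule elements (never bare word-concatenation:
# element fragments carry their own token-boundary guards).
_ELEMENT_SEP = r"[\s,;:()]*"

_ELEMENT_RE = re.compile(
    r"""(?P<kind>LIT|RX)(?P<cap1>!?):"(?P<body>[^"]*)"
      | SLOT:(?P<slot>[A-Za-z_][A-Za-z0-9_]*)(?P<cap2>!(?:capture)?)?
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class RuleElement:
    kind: str  # "LIT" | "RX" | "SLOT"
    body: str  # literal text, regex body, or lexicon name
    capture: bool = False


@dataclass
class Rule:
    """One compiled lexical pattern."""

    rule_id: str
    characteristic: Characteristic
    elements: Sequence[RuleElement]
    pattern: re.Pattern = field(repr=False)

    @property
    def n_captures(self) -> int:
        return sum(1 for el in self.elements if el.capture)


def _element_fragment(
    element: RuleElement, lexicons: Mapping[str, Lexicon], group: str | None
) -> str:
    if element.kind == "LIT":
        body = BOUND_L + phrase_core(element.body) + BOUND_R
    elif element.kind == "RX":
        body = "(?:" + element.body + ")"
    else:  # SLOT
        body = lexicons[element.body].slot_regex()
    if group is not None:
        return f"(?P<{group}>{body})"
    return body


def parse_rule_line(line: str) -> tuple[str, Characteristic, list[RuleElement]]:
    parts = line.split("\t")
    if len(parts) != 3:
        raise ValidationError(
            "rule line must be 'ID<TAB>CHARACTERISTIC<TAB>elements'"
        )
    rule_id, kind_str, element_str = (p.strip() for p in parts)
    try:
        characteristic = Characteristic(kind_str)
    except ValueError as exc:
        raise ValidationError(
            f"rule {rule_id}: unknown characteristic {kind_str!r}"
        ) from exc
    elements: list[RuleElement] = []
    matched_len = 0
    for m in _ELEMENT_RE.finditer(element_str):
        matched_len += len(m.group(0))
        if m.group("kind"):
            elements.append(
                RuleElement(m.group("kind"), m.group("body"), bool(m.group("cap1")))
            )
        else:
            elements.append(
                RuleElement("SLOT", m.group("slot"), bool(m.group("cap2")))
            )
    residue = re.sub(r"[;\s]", "", element_str)
    consumed = re.sub(r"[;\s]", "", "".join(
        m.group(0) for m in _ELEMENT_RE.finditer(element_str)
    ))
    if not elements or residue != consumed:
        raise ValidationError(f"rule {rule_id}: unparseable elements {element_str!r}")
    return rule_id, characteristic, elements


def compile_rule(
    rule_id: str,
    characteristic: Characteristic,
    elements: Sequence[RuleElement],
    lexicons: Mapping[str, Lexicon],
) -> Rule:
    if not any(el.capture for el in elements):
        raise ValidationError(f"rule {rule_id}: no capture element")
    fragments = []
    cap_index = 0
    for element in elements:
        if element.kind == "SLOT" and element.body not in lexicons:
            raise ValidationError(
                f"rule {rule_id}: slot names unknown lexicon {element.body!r}"
            )
        group = None
        if element.capture:
            group = f"c{cap_index}"
            cap_index += 1
        fragments.append(_element_fragment(element, lexicons, group))
    try:
        pattern = re.compile(_ELEMENT_SEP.join(fragments), re.IGNORECASE)
    except re.error as exc:
        raise ValidationError(f"rule {rule_id}: bad pattern ({exc})") from exc
    return Rule(rule_id, characteristic, tuple(elements), pattern)


def compile_rules(
    path: str | Path, lexicons: Mapping[str, Lexicon]
) -> list[Rule]:
    """Compile a DSL file; duplicate ids are rejected, empty files warn."""
    path = Path(path)
    rules: list[Rule] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rule_id, characteristic, elements = parse_rule_line(line)
            if rule_id in seen:
                raise ValidationError(f"duplicate rule id {rule_id!r}")
            rule = compile_rule(rule_id, characteristic, elements, lexicons)
        except ValidationError as exc:
            raise ValidationError(f"{path.name}:{lineno}: {exc}") from exc
        seen.add(rule_id)
        rules.append(rule)
    if not rules:
        logger.warning("rule file %s contains no rules", path)
    return rules


def rule_counts(rules: Sequence[Rule]) -> dict[Characteristic, int]:
    counts: dict[Characteristic, int] = {c: 0 for c in Characteristic}
    for rule in rules:
        counts[rule.characteristic] += 1
    return counts


# ---------------------------------------------------------------------------
# Numeric age parsing

_RANGE = re.compile(
    r"(\d{1,3})(?:\.\d+)?\s*(?:to|through|and|[-–—])\s*(\d{1,3})(?:\.\d+)?"
)
_PLUS = re.compile(r"(\d{1,3})\s*(?:\+|or\s+older|and\s+older|and\s+over|or\s+above)")
_OLDER = re.compile(r"(?:older\s+than|over|above)\s+(?:the\s+age\s+of\s+)?(\d{1,3})")
_YOUNGER = re.compile(
    r"(?:younger\s+than|under|below)\s+(?:the\s+age\s+of\s+)?(\d{1,3})"
)
_SINGLE = re.compile(r"(\d{1,3})(?:\.\d+)?")


def parse_numeric_age(surface: str) -> tuple[int, int | None]:
    """Parse a numeric age capture into closed year bounds (high=None when
    open-ended).

    Supported forms include ``18 to 24 years``, ``18-24``, ``between 12 and
    14-year-old``, ``aged 30`` (point interval), ``65+``, ``older than 50``
    (-> (51, open)) and ``younger than 18`` (-> (0, 17)).
    """
    text = surface.strip().lower()
    m = _PLUS.search(text)
    if m:
        return int(m.group(1)), None
    m = _RANGE.search(text)
    if m:
        low, high = int(m.group(1)), int(m.group(2))
        if low > high:
            raise ValueError(f"inverted age range in {surface!r}")
        return low, high
    m = _OLDER.search(text)
    if m:
        return int(m.group(1)) + 1, None
    m = _YOUNGER.search(text)
    if m:
        bound = int(m.group(1))
        if bound < 1:
            raise ValueError(f"degenerate upper bound in {surface!r}")
        return 0, bound - 1
    m = _SINGLE.search(text)
    if m:
        value = int(m.group(1))
        return value, value
    raise ValueError(f"no numeric age in {surface!r}")


def apply_rules(
    record: AbstractRecord,
    rules: Sequence[Rule],
    lexicons: Mapping[str, Lexicon] | None = None,
) -> list[MentionSpan]:
    """Run every rule over the record's text and return all captures.

    Duplicates and overlaps across rules are kept (deduplication is the
    standardization step's job). Output order is deterministic: by start
    offset, then rule id. Unparseable numeric age captures are dropped with
    a warning, never raised.
    """
    mentions: list[MentionSpan] = []
    text = record.text
    for rule in rules:
        for m in rule.pattern.finditer(text):
            for group, surface in sorted(m.groupdict().items()):
                if surface is None:
                    continue
                start, end = m.span(group)
                low = high = None
                if rule.characteristic is Characteristic.AGE and re.search(
                    r"\d", surface
                ):
                    try:
                        low, high = parse_numeric_age(surface)
                    except ValueError as exc:
                        logger.warning(
                            "record %s rule %s: %s", record.pmid, rule.rule_id, exc
                        )
                        continue
                mentions.append(
                    MentionSpan(
                        rule.characteristic, surface, start, end, rule.rule_id,
                        low, high,
                    )
                )
    mentions.sort(key=lambda m: (m.start, m.rule_id))
    return mentions
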