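"""End-to-end extraction: rules over abstracts, then standardization."""

from __future__ import annotations

from typing import Mapping, Sequence

from .analytics import AbstractResult
from .lexicons import Lexicon
from .model import AbstractRecord, MentionSpan, StandardizedValue
from .normalize import Normalizer
from .rules import Rule, apply_rules


def extract_abstract(
    record: AbstractRecord,
    rules: Sequence[Rule],
    normalizer: Normalizer,
    lexicons: Mapping[str, Lexicon] | None = None,
) -> tuple[list[MentionSpan], frozenset[StandardizedValue]]:
    """Raw mentions and the deduplicated standardized value set for one
    abstract."""
    mentions = apply_rules(record, rules, lexicons)
    values = normalizer.standardize_mentions(mentions)
    return mentions, values


def extract_corpus(
    records: Sequence[AbstractRecord],
    rules: Sequence[Rule],
    normalizer: Normalizer,
) -> list[AbstractResult]:
    """Standardized results for a corpus, in input order."""
    results = []
    for record in records:
        _, values = extract_abstract(record, rules, normalizer)
        results.append(AbstractResult(record.pmid, record.year, values))
    return results
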