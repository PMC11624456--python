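"""Abstract-level evaluation: TP/FP/FN alignment and P/R/F1 metrics.

The unit of evaluation is the distinct standardized value per
characteristic per abstract: extracting one or both of two surface forms
that standardize to the same value is a single TP. Metrics are percentages
reported at one decimal, truncated — the convention under which the
published per-class precision/recall cells recompute exactly from their
counts (half-up would flip e.g. 98/106 from 92.4 to 92.5). F1 is the
harmonic mean of the truncated precision and recall, truncated again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal
from typing import Iterable, Mapping, Sequence

from .model import Characteristic, GoldAnnotation, StandardizedValue
from .util import floor1, pct_floor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalCounts:
    """Abstract-level confusion counts for one characteristic."""

    characteristic: Characteristic | None
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        kind = self.characteristic if self.characteristic == other.characteristic else None
        return EvalCounts(kind, self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    """Precision, recall and F1 as percentages in [0, 100]."""

    precision: float
    recall: float
    f1: float


def compute_metrics(counts: EvalCounts) -> Metrics:
    """P = 100*TP/(TP+FP), R = 100*TP/(TP+FN), F1 = harmonic mean of the
    reported (truncated) P and R. Zero denominators give 0.0 with a
    warning so batch evaluation stays total."""
    if counts.tp + counts.fp == 0:
        logger.warning("precision denominator zero for %s", counts.characteristic)
        precision = 0.0
    else:
        precision = pct_floor(counts.tp, counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        logger.warning("recall denominator zero for %s", counts.characteristic)
        recall = 0.0
    else:
        recall = pct_floor(counts.tp, counts.tp + counts.fn)
    return Metrics(precision, recall, _f1(precision, recall))


def _f1(precision: float, recall: float) -> float:
    if precision == 0.0 or recall == 0.0:
        return 0.0
    p, r = Decimal(str(precision)), Decimal(str(recall))
    return floor1(2 * p * r / (p + r))


def align_abstract(
    gold: GoldAnnotation,
    predicted: Iterable[StandardizedValue],
    pmid: str | None = None,
) -> dict[Characteristic, EvalCounts]:
    """Per-characteristic set alignment of one abstract: TP = |gold ∩
    predicted|, FP = |predicted \\ gold|, FN = |gold \\ predicted|."""
    predicted = frozenset(predicted)
    if pmid is not None and pmid != gold.pmid:
        raise ValueError(f"pmid mismatch: gold {gold.pmid!r} vs predicted {pmid!r}")
    out: dict[Characteristic, EvalCounts] = {}
    for kind in Characteristic:
        g = {v for v in gold.values if v.kind is kind}
        p = {v for v in predicted if v.kind is kind}
        out[kind] = EvalCounts(kind, len(g & p), len(p - g), len(g - p))
    return out


def sum_counts(counts: Iterable[EvalCounts]) -> EvalCounts:
    counts = list(counts)
    if not counts:
        raise ValueError("no counts to pool")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return total


def micro_metrics(counts: Sequence[EvalCounts]) -> Metrics:
    """Pool TP/FP/FN across characteristics, then compute metrics on the
    pooled counts (weighted by class size)."""
    return compute_metrics(sum_counts(counts))


def macro_metrics(per_class: Sequence[Metrics]) -> Metrics:
    """Unweighted arithmetic mean of per-class percentages, one decimal."""
    if not per_class:
        raise ValueError("no per-class metrics to average")
    n = len(per_class)
    mean = lambda vals: floor1(sum(Decimal(str(v)) for v in vals) / n)
    return Metrics(
        mean(m.precision for m in per_class),
        mean(m.recall for m in per_class),
        mean(m.f1 for m in per_class),
    )


def evaluate_corpus(
    golds: Mapping[str, GoldAnnotation],
    predictions: Mapping[str, frozenset[StandardizedValue]],
) -> dict[Characteristic, EvalCounts]:
    """Pooled per-characteristic counts over a corpus; the pmid universes
    must coincide."""
    missing = sorted(set(golds) ^ set(predictions))
    if missing:
        raise ValueError(f"pmid universes differ: {missing[:10]}")
    totals = {kind: EvalCounts(kind, 0, 0, 0) for kind in Characteristic}
    for pmid, gold in golds.items():
        for kind, counts in align_abstract(gold, predictions[pmid]).items():
            totals[kind] = totals[kind] + counts
    return totals


def absolute_agreement(
    annotator_a: Mapping[str, GoldAnnotation] | Iterable[GoldAnnotation],
    annotator_b: Mapping[str, GoldAnnotation] | Iterable[GoldAnnotation],
) -> float:
    """Percentage of abstracts on which the two annotators produced
    identical value sets across all four characteristics jointly."""
    a = _as_map(annotator_a)
    b = _as_map(annotator_b)
    if set(a) != set(b):
        raise ValueError("annotators cover different pmid sets")
    if not a:
        raise ValueError("no abstracts to compare")
    same = sum(1 for pmid in a if a[pmid].values == b[pmid].values)
    from .util import pct_half_up

    return pct_half_up(same, len(a))


def _as_map(annotations) -> dict[str, GoldAnnotation]:
    if isinstance(annotations, Mapping):
        return dict(annotations)
    return {ann.pmid: ann for ann in annotations}
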