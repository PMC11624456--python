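"""Shared helpers: whitespace normalization and one-decimal rounding conventions.

Two distinct one-decimal conventions coexist in this package because the
published reference tables use two: evaluation metrics (precision/recall/F1)
are truncated (floored) at one decimal, while descriptive percentages and
per-1000 rates round half-up. Both are implemented over exact Decimal
arithmetic so no binary-float artifact can flip a reported digit.
"""

from __future__ import annotations

import re
from decimal import Decimal, ROUND_FLOOR, ROUND_HALF_UP

_WS = re.compile(r"\s+")


class ValidationError(ValueError):
    """Raised when an input file or configuration violates its contract."""


def normalize_ws(text: str) -> str:
    """Collapse runs of whitespace to single spaces and strip the ends."""
    return _WS.sub(" ", text).strip()


_ONE_DP = Decimal("0.1")


def _as_decimal(value) -> Decimal:
    if isinstance(value, Decimal):
        return value
    if isinstance(value, int):
        return Decimal(value)
    return Decimal(str(value))


def half_up1(value) -> float:
    """Round to one decimal, halves away from zero (reporting convention
    for descriptive percentages and rates)."""
    return float(_as_decimal(value).quantize(_ONE_DP, rounding=ROUND_HALF_UP))


def floor1(value) -> float:
    """Truncate to one decimal (reporting convention for P/R/F1 metrics)."""
    return float(_as_decimal(value).quantize(_ONE_DP, rounding=ROUND_FLOOR))


def ratio(numerator, denominator, scale: int = 100) -> Decimal:
    """Exact ``scale * numerator / denominator`` as a Decimal."""
    if denominator == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    return Decimal(scale) * _as_decimal(numerator) / _as_decimal(denominator)


def pct_half_up(numerator, denominator) -> float:
    """Percentage at one decimal, half-up: the convention of the descriptive
    tables (e.g. 3581/5170 -> 69.3)."""
    return half_up1(ratio(numerator, denominator))


def pct_floor(numerator, denominator) -> float:
    """Percentage at one decimal, truncated: the convention the published
    evaluation metrics follow (e.g. 98/106 -> 92.4)."""
    return floor1(ratio(numerator, denominator))


def rate_per_1000(count, population) -> float:
    """Events per 1000 population, one decimal half-up (e.g. 138 articles /
    3289 prisoners -> 42.0)."""
    return half_up1(ratio(count, population, scale=1000))
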