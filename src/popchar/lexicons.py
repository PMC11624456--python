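"""Gazetteer dictionaries and token-boundary dictionary matching.

A lexicon maps surface terms to canonical labels (e.g. ``sex crime`` ->
``sex offence``; ``Iowa`` -> ``American``). Matching is case-insensitive by
default, respects token boundaries (a term never matches inside a longer
word: letters, digits and internal hyphens/apostrophes count as word
material), and treats hyphens and spaces as equivalent inside multi-word
terms, so ``sex-offender`` matches the entry ``sex offender``.

When candidate matches overlap, the longest wins; ties break leftmost and
then by the caller-supplied lexicon precedence order. The returned spans
are mutually non-overlapping and sorted by start offset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .util import ValidationError

logger = logging.getLogger(__name__)

# A match may not butt against word material: preceding/following letters or
# digits, or a hyphen/apostrophe that glues the match to word material
# ("grapevine" must not yield "rape"; "sex-offender" must not yield
# "offender"; "women's" must not yield "women").
BOUND_L = r"(?<!\w)(?<![\w]['’\-])"
BOUND_R = r"(?!\w)(?!['’\-]\w)"

_TOKEN_SPLIT = re.compile(r"[\s\-]+")


def fold_term(term: str) -> str:
    """Case-fold and collapse hyphen/space variation for dictionary keys."""
    return " ".join(_TOKEN_SPLIT.split(term.strip().lower()))


def phrase_core(term: str) -> str:
    """Regex body matching a term with hyphen/space equivalence between
    tokens (no boundary guards)."""
    tokens = [re.escape(tok) for tok in _TOKEN_SPLIT.split(term.strip()) if tok]
    return r"[\s\-]+".join(tokens)


def phrase_regex(term: str) -> str:
    """Boundary-guarded regex for a single term or literal phrase."""
    return BOUND_L + phrase_core(term) + BOUND_R


def _pluralize(term: str) -> str:
    if re.search(r"(?:s|x|z|ch|sh)$", term):
        return term + "es"
    return term + "s"


@dataclass(frozen=True)
class LexMatch:
    """One dictionary hit: ``surface`` equals ``text[start:end]``."""

    lexicon: str
    surface: str
    canonical: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


class Lexicon:
    """An engineered dictionary: folded surface term -> canonical label."""

    def __init__(
        self,
        name: str,
        entries: dict[str, str],
        *,
        case_sensitive: bool = False,
        expand_inflections: bool = False,
    ) -> None:
        if not entries:
            raise ValidationError(f"lexicon {name!r} has no entries")
        self.name = name
        self.case_sensitive = case_sensitive
        self.expand_inflections = expand_inflections
        folded: dict[str, str] = {}
        for term, canonical in entries.items():
            if not canonical or not canonical.strip():
                raise ValidationError(
                    f"lexicon {name!r}: empty canonical for term {term!r}"
                )
            key = fold_term(term) if not case_sensitive else term.strip()
            if not key:
                raise ValidationError(f"lexicon {name!r}: empty surface term")
            if key in folded and folded[key] != canonical:
                raise ValidationError(
                    f"lexicon {name!r}: term {key!r} maps to both "
                    f"{folded[key]!r} and {canonical!r}"
                )
            folded[key] = canonical
        if expand_inflections:
            for term, canonical in list(folded.items()):
                plural = _pluralize(term)
                folded.setdefault(plural, canonical)
        self.entries = folded
        self._pattern = self._compile()

    @classmethod
    def load(
        cls,
        path: str | Path,
        name: str,
        *,
        case_sensitive: bool = False,
        expand_inflections: bool = False,
    ) -> "Lexicon":
        """Read a two-column TSV (term <tab> canonical, ``#`` comments)."""
        entries: dict[str, str] = {}
        seen: dict[str, str] = {}
        path = Path(path)
        for lineno, raw in enumerate(
            path.read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected 'term<TAB>canonical'"
                )
            term, canonical = parts[0].strip(), parts[1].strip()
            key = fold_term(term) if not case_sensitive else term
            if key in seen and seen[key] != canonical:
                raise ValidationError(
                    f"{path.name}:{lineno}: duplicate term {term!r} with "
                    f"conflicting canonical ({seen[key]!r} vs {canonical!r})"
                )
            seen[key] = canonical
            entries[term] = canonical
        return cls(
            name,
            entries,
            case_sensitive=case_sensitive,
            expand_inflections=expand_inflections,
        )

    def _compile(self) -> re.Pattern:
        # Longest alternatives first so the scanner reports, at every start
        # position, the longest entry beginning there.
        alts = sorted(self.entries, key=len, reverse=True)
        body = "|".join(phrase_core(term) for term in alts)
        flags = 0 if self.case_sensitive else re.IGNORECASE
        return re.compile(BOUND_L + "(?:" + body + ")" + BOUND_R, flags)

    @property
    def pattern(self) -> re.Pattern:
        """Compiled alternation over all entries, boundary-guarded."""
        return self._pattern

    def slot_regex(self) -> str:
        """Regex fragment for embedding this lexicon as a rule slot."""
        return self._pattern.pattern

    def lookup(self, surface: str) -> str | None:
        """Canonical label for an exact surface (after folding), or None."""
        return self.entries.get(fold_term(surface))

    def best_internal_match(self, surface: str) -> str | None:
        """Canonical label of the longest entry contained in ``surface``
        (used to standardize captures wider than a single dictionary term,
        e.g. 'Male sex offenders' -> entry 'sex offenders')."""
        best = None
        for match in self.iter_matches(surface):
            if best is None or len(match) > len(best):
                best = match
        return best.canonical if best else None

    def iter_matches(self, text: str) -> Iterator[LexMatch]:
        """All candidate hits, one per start position (the longest entry
        starting there), possibly overlapping."""
        pos = 0
        while True:
            m = self._pattern.search(text, pos)
            if m is None:
                return
            surface = m.group(0)
            canonical = self.entries.get(fold_term(surface))
            if canonical is not None:
                yield LexMatch(self.name, surface, canonical, m.start(), m.end())
            pos = m.start() + 1

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:
        return f"Lexicon({self.name!r}, {len(self)} entries)"


def match_terms(text: str, lexicons: Lexicon | Sequence[Lexicon]) -> list[LexMatch]:
    """Non-overlapping dictionary hits over whitespace-normalized text.

    Overlap resolution: longest span wins, ties break leftmost, remaining
    ties by the order lexicons are given (earlier = higher precedence).
    """
    if isinstance(lexicons, Lexicon):
        lexicons = [lexicons]
    candidates: list[tuple[int, int, int, LexMatch]] = []
    for priority, lexicon in enumerate(lexicons):
        for match in lexicon.iter_matches(text):
            candidates.append((-len(match), match.start, priority, match))
    candidates.sort(key=lambda item: item[:3])
    selected: list[LexMatch] = []
    for _, _, _, match in candidates:
        if all(
            match.end <= kept.start or match.start >= kept.end
            for kept in selected
        ):
            selected.append(match)
    selected.sort(key=lambda m: m.start)
    return selected


def merge_entries(lexicons: Iterable[Lexicon]) -> dict[str, str]:
    """Union of folded entries across lexicons, earlier lexicons winning."""
    merged: dict[str, str] = {}
    for lexicon in lexicons:
        for term, canonical in lexicon.entries.items():
            merged.setdefault(term, canonical)
    return merged
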