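"""Access to the shipped seed lexicons, rules and standardization tables.

The dictionaries and rule files are data, not code: they live under
``popchar/data`` in open TSV formats and users can extend or replace them
(every loader takes an explicit directory). The seed sets contain every
term and pattern the reference tables cite; growing them toward full
production coverage is an append-only data exercise.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ires
from pathlib import Path

from .lexicons import Lexicon
from .normalize import Normalizer, load_age_classes, load_offense_categories
from .rules import Rule, compile_rules
from .analytics import PrisonerTableRow, load_prisoner_table
from .util import ValidationError

#: lexicon name -> (filename, expand plural inflections)
LEXICON_FILES: dict[str, tuple[str, bool]] = {
    "sex_terms": ("sex_terms.tsv", False),
    "age_terms": ("age_terms.tsv", False),
    "offense_terms": ("offense_terms.tsv", True),
    "population_terms": ("population_terms.tsv", True),
    "nationalities": ("nationalities.tsv", True),
    "countries": ("countries.tsv", False),
    "world_cities": ("world_cities.tsv", False),
    "us_states": ("us_states.tsv", False),
    "us_counties": ("us_counties.tsv", False),
    "us_cities": ("us_cities.tsv", False),
}

RULE_FILES = (
    "rules_age.tsv",
    "rules_sex.tsv",
    "rules_nationality.tsv",
    "rules_offender.tsv",
)


def data_dir() -> Path:
    return Path(str(_ires.files("popchar") / "data"))


def load_lexicons(directory: str | Path | None = None) -> dict[str, Lexicon]:
    directory = Path(directory) if directory else data_dir() / "lexicons"
    lexicons: dict[str, Lexicon] = {}
    for name, (filename, expand) in LEXICON_FILES.items():
        path = directory / filename
        if not path.exists():
            raise ValidationError(f"missing lexicon file {path}")
        lexicons[name] = Lexicon.load(path, name, expand_inflections=expand)
    return lexicons


def load_rules(
    lexicons: dict[str, Lexicon], directory: str | Path | None = None
) -> list[Rule]:
    directory = Path(directory) if directory else data_dir() / "rules"
    rules: list[Rule] = []
    for filename in RULE_FILES:
        rules.extend(compile_rules(directory / filename, lexicons))
    return rules


def load_normalizer(
    lexicons: dict[str, Lexicon] | None = None,
    tables_dir: str | Path | None = None,
) -> Normalizer:
    lexicons = lexicons or load_lexicons()
    tables = Path(tables_dir) if tables_dir else data_dir() / "tables"
    age_classes = load_age_classes(
        data_dir() / "lexicons" / "age_terms.tsv"
        if tables_dir is None
        else tables / "age_terms.tsv"
    )
    categories = load_offense_categories(tables / "offense_categories.tsv")
    return Normalizer(lexicons, age_classes, categories)


def default_prisoner_table() -> list[PrisonerTableRow]:
    return load_prisoner_table(data_dir() / "tables" / "prisoner_population.tsv")


def benchmark_evaluation_counts() -> dict[tuple[str, str], tuple[int, int, int]]:
    """Published per-characteristic confusion counts by dataset split:
    (characteristic, split) -> (tp, fp, fn)."""
    table: dict[tuple[str, str], tuple[int, int, int]] = {}
    path = data_dir() / "benchmarks" / "evaluation_counts.tsv"
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind, split, tp, fp, fn = line.split("\t")
        table[(kind, split)] = (int(tp), int(fp), int(fn))
    return table


def benchmark_nationality_counts() -> dict[str, int]:
    """Published benchmark article counts per nationality (top 20)."""
    counts: dict[str, int] = {}
    path = data_dir() / "benchmarks" / "nationality_counts.tsv"
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        demonym, n = line.split("\t")
        counts[demonym] = int(n)
    return counts


def pubmed_query() -> str:
    """The documented literature-search query (configuration value only;
    no live retrieval is performed by this package)."""
    return (data_dir() / "query" / "pubmed_query.txt").read_text(
        encoding="utf-8"
    ).strip()


@lru_cache(maxsize=1)
def default_engine():
    """(lexicons, rules, normalizer) built from the shipped data files."""
    lexicons = load_lexicons()
    rules = load_rules(lexicons)
    normalizer = load_normalizer(lexicons)
    return lexicons, rules, normalizer
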