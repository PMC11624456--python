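"""Descriptive gap analytics: coverage, distributions, country rankings.

Runs the extractor over a synthetic corpus and prints the coverage
summary and age-band distribution, then derives the prisoner-population-
adjusted country ranking from the shipped benchmark inputs (article
counts per nationality and average prisoner populations 2000-2020). The
adjusted ranking is the headline gap analysis: raw article counts favour
large countries, while the per-1000-prisoner rate puts the Nordic
countries on top.
"""

from popchar import (
    Characteristic,
    GeneratorConfig,
    country_ranking,
    default_engine,
    age_distribution,
    extract_corpus,
    generate,
    summarize_corpus,
)
from popchar.resources import benchmark_nationality_counts, default_prisoner_table

_, rules, normalizer = default_engine()
abstracts = generate(GeneratorConfig(n=500, seed=11), normalizer=normalizer)
results = extract_corpus([a.record for a in abstracts], rules, normalizer)

summary = summarize_corpus(results)
print(f"corpus: {summary.total} abstracts")
for kind in Characteristic:
    n, pct = summary.per_characteristic[kind]
    print(f"  reporting {kind.value.lower():14}: {n:4} ({pct}%)")
print(f"  reporting all four     : {summary.all_four[0]:4} ({summary.all_four[1]}%)")
print(f"  reporting none         : {summary.none[0]:4} ({summary.none[1]}%)")

table, denominator = age_distribution(results)
print(f"\nage bands over {denominator} age-reporting abstracts "
      "(one abstract can span several bands):")
for group, (n, pct) in table.items():
    if n:
        print(f"  {group.value:14} {n:4} ({pct}%)")

print("\npopulation-adjusted country ranking (benchmark inputs):")
print(f"{'country':15} {'articles':>8} {'prisoners':>10} "
      f"{'rate/1000':>9} {'rate rank':>9} {'crude rank':>10}")
for stats in sorted(country_ranking(
    benchmark_nationality_counts(), default_prisoner_table()
), key=lambda s: s.rate_rank)[:6]:
    print(f"{stats.country:15} {stats.articles:>8} "
          f"{stats.prisoner_population:>10} {stats.rate:>9} "
          f"{stats.rate_rank_display:>9} {stats.crude_rank:>10}")
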