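# popchar

Rule-based text mining of **population characteristics in justice-health
research abstracts**: who is actually being studied — which ages, sexes,
nationalities and offender groups — across the epidemiological-criminology
literature, and where the gaps are.

Research at the intersection of public health and the justice system is
indexed in bibliographic databases as abstracts, but those abstracts often
under-describe their populations. `popchar` extracts four characteristics
from abstract text — **age**, **sex**, **nationality** and **offender
type** — standardizes them into closed vocabularies, evaluates extraction
quality at the abstract level, and computes the descriptive gap analytics
(coverage rates, time trends, and prisoner-population-adjusted country
rankings). It is a library first (everything is importable), with a thin
`popchar` command-line wrapper for the standard workflow.

## Method

Extraction is deliberately simple and auditable:

* **Gazetteer dictionaries** map surface terms to canonical labels
  (offenses, sex terms, nationalities/countries/cities, US subdivisions,
  generic offender-population terms). Matching is case-insensitive,
  respects token boundaries ("rape" never matches inside "grapevine"),
  treats hyphen and space as equivalent, and resolves overlaps
  longest-first, leftmost, then by dictionary precedence.
* **Semifrozen lexical patterns** combine literal anchors, regex anchors
  and dictionary slots in a line-oriented DSL, e.g.
  `RX:"characteristics\s+of";SLOT:offense_terms!;LIT:"in"` fires on
  *"characteristics of **sex offenders** in"* and captures the slot.
  Numeric age captures ("aged 18 to 24 years", "65+", "younger than 18")
  are parsed into closed year bounds.
* **Standardization** maps captures to: the seven statistical age bands
  (<18, 18-24, 25-34, 35-44, 45-54, 55-64, 65+) plus *unknown adult* —
  a numeric range maps to every band it overlaps; five sex categories
  (male, female, transgender, transgender man/woman); canonical
  nationality demonyms (all US subdivisions → *American*, defunct
  nationalities → *miscellaneous*); and a two-level offender taxonomy —
  six substantive categories (child crime-related, sex, violent,
  nonviolent, mentally ill, drug-related) plus *miscellaneous*, with the
  specific offense kept as an attribute (*serial rapists* → sex offender /
  rape). Duplicate values collapse per abstract.
* **Evaluation** is abstract-level: the unit is the distinct standardized
  value per characteristic per abstract, TP = |gold ∩ predicted|,
  FP = |predicted \ gold|, FN = |gold \ predicted|, with per-class, macro
  and micro precision / recall / F1.
* **Analytics**: coverage and characteristic-combination counts, age-band
  and offender-category distributions (denominator = characteristic-
  reporting abstracts), female-only / male-only time series, and country
  rankings both crude (article count) and adjusted as
  `rate = 1000 · articles / average prisoner population`.

The shipped dictionaries and rules are representative, extensible seed
sets in plain TSV (every worked example term is present); a synthetic
corpus generator with recorded gold makes the whole pipeline testable
end-to-end without any download.

## Worked example

```python
from popchar import AbstractRecord, default_engine, extract_abstract

lexicons, rules, normalizer = default_engine()
record = AbstractRecord(
    pmid="demo1", year=2019,
    text=("This report describes characteristics of sex offenders in Norway. "
          "Participants aged 18 to 24 years were enrolled, and both men and "
          "women completed the survey."),
)
mentions, values = extract_abstract(record, rules, normalizer)
```

prints (via `python examples/01_extract_characteristics.py`):

```
   mention [OFFENDER_TYPE ] 'sex offenders' (rule OFF_01, chars 41-54)
   mention [NATIONALITY   ] 'Norway' (rule NAT_01, chars 58-64)
   mention [AGE           ] 'aged 18 to 24 years' (rule AGE_N01, chars 79-98)
   mention [SEX           ] 'men' (rule SEX_01, chars 123-126)
   mention [SEX           ] 'women' (rule SEX_01, chars 131-136)
   value   [AGE           ] 18-24
   value   [NATIONALITY   ] Norwegian
   value   [OFFENDER_TYPE ] sex
   value   [SEX           ] female
   value   [SEX           ] male
```

The mention lines are raw rule hits (several rules may hit the same span);
the value lines are the deduplicated abstract-level findings: an 18-24 age
band, Norwegian nationality, a sex-offender population, and both sexes.

The other scripts under `examples/` demonstrate abstract-level evaluation
(`02`), the gap analytics and the population-adjusted country ranking
(`03` — Norway, Finland, Sweden and Denmark lead at 42.0, 41.7, 40.1 and
33.5 articles per 1000 prisoners despite low crude ranks), and a
controlled misspelling-noise experiment (`04` — age recall falls to ~83%
at a 20% corruption rate while precision stays at 100%).

## Command line

```
popchar simulate  --n 1000 --seed 1 --out-dir run/      # corpus + gold
popchar extract   --corpus run/corpus.medline --out run/results.jsonl
popchar evaluate  --results run/results.jsonl --gold run/gold.tsv
popchar aggregate --results run/results.jsonl --out-dir run/tables/
```

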