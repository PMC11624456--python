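# Methods

This note documents the model, the numerical conventions, the synthetic
data generator, and the design choices behind `popchar`.

## The extraction model

The extractor is a classical gazetteer + lexical-pattern system. Its
working assumption is that epidemiological abstracts describe their
populations in a semistructured register — "characteristics of X in Y",
"participants aged A to B years", "both men and women" — so a modest set
of frozen syntactic anchors around dictionary slots captures most
population statements without any training data. The trade-offs of that
choice are inherited knowingly:

* **No negation or hedging** — "no female participants were included"
  still yields a female mention. This mirrors the documented
  false-positive behavior of this family of systems and is a known
  limitation, not an oversight.
* **No fuzzy matching** — misspelled text fails to trigger rules and
  surfaces as false negatives (the generator's misspelling noise
  reproduces exactly this failure mode).
* **No inference from context** — "mothers" does not imply female;
  ethnicity terms are not nationality terms. Only dictionary entries and
  explicit patterns fire.

Text is whitespace-normalized before matching; rules run over the whole
abstract with no sentence splitting (the target patterns do not cross
sentence boundaries, and deduplication happens at the abstract level
anyway).

### Matching semantics

Token boundaries treat letters, digits and *internal* hyphens/apostrophes
as word material, so a term never matches inside a longer word
(`grapevine`/`rape`, `sex-offender`/`offender`, `women's`/`women`).
Hyphens and spaces are equivalent inside multi-word terms. At each start
position the longest dictionary entry is the candidate; overlapping
candidates are resolved longest-first, ties leftmost, remaining ties by
dictionary precedence (for geography: countries > nationalities > US
states > US counties > US/world cities — the more specific national
identity wins, consistent with standardizing all US subdivisions to
*American*).

### Mention pruning

All rule captures are kept initially (rules are independent, and
duplicates are expected). Before standardization, a mention strictly
contained inside another mention's span is dropped — "sex offenders"
suppresses its inner "offenders" — while *equal* spans from different
characteristics both survive, so "juveniles" legitimately contributes
both a minor-age value and a miscellaneous-offender value, and "Women
with borderline personality disorder" yields both a sex and an offender
value from two rules firing over overlapping text. Keeping `apply_rules`
itself prune-free preserves the monotonicity property (adding a rule
never removes another rule's mention); pruning is part of the
standardization step.

## Standardization

* **Age.** Numeric captures are parsed to closed integer year bounds
  (`aged 30` → [30, 30]; `older than 50` → [51, ∞); `younger than 18` →
  [0, 17]) and map to every statistical age band their interval overlaps;
  bands are closed intervals, so 18-25 touches both 18-24 and 25-34.
  Textual terms map through a shipped table: generic minor terms → <18;
  adolescent/teen (13-19) and young/youth (15-24) → {minors, 18-24}; bare
  "adults" → *unknown adult*, which never co-occurs with a numeric band
  from the same mention. Bare "juvenile"/"delinquent" classify as minors
  (both table rows that mention them agree on the classification).
* **Sex.** Five categories; conjoined surfaces ("boys and girls") split
  on connectives and map each part. "trans"/"transgender" without a
  man/woman qualifier → the unspecified transgender category.
* **Nationality.** Every geographic dictionary entry carries a canonical
  demonym, so standardization is total; UK variants collapse to one
  label; defunct nationalities (Czechoslovakian, Yugoslavia, Soviet) →
  *miscellaneous*.
* **Offender type.** Two-level: the offense dictionary maps a surface to
  a canonical offense label, and a category table maps each canonical to
  one of the seven categories with an optional specific attribute (the
  attribute is the canonical label, lower-cased singular; an empty
  attribute means the surface was already category-level, e.g. "sex
  offenders"). Category closure over the offense dictionary is validated
  at load time. Generic population terms (prisoners, detainees,
  parolees…) standardize as *miscellaneous* with the singular lemma as
  attribute; any unmappable capture also falls back to *miscellaneous*
  carrying its folded surface. The taxonomy has 6 substantive categories
  plus miscellaneous — 7 in total (the reference description counts "6
  created + 1 additional").

## Evaluation conventions

The unit of evaluation is the distinct standardized value per
characteristic per abstract: detecting one or both of two surface forms
of the same value is a single TP. Precision = 100·TP/(TP+FP), recall =
100·TP/(TP+FN); zero denominators report 0.0 with a warning so batch
evaluation stays total.

**Rounding.** Two one-decimal conventions coexist deliberately, because
the published reference tables use two. Evaluation metrics are
*truncated* at one decimal and F1 is the harmonic mean of the truncated
precision and recall, truncated again — the only convention under which
the published per-class P/R cells recompute exactly from their confusion
counts (e.g. 98/106 → 92.4, where half-up rounding would give 92.5).
Descriptive percentages and per-1000 rates round *half-up* — required by
the published shares (3581/5170 → 69.3; 398/5170 → 7.7) and rates
(138/3289·1000 → 42.0). Both are computed over exact decimal arithmetic.
Two published cells do not recompute under any convention (the age
evaluation row's printed precision/recall, and the micro values, whose
pooling basis is unstated); they are documented rather than reproduced.

Annotator agreement is the absolute agreement rate at the abstract level:
the percentage of abstracts on which two annotation sets are identical
across all four characteristics jointly.

## Country rankings

`rate = 1000 · articles / average prisoner population`, one decimal
half-up. Crude ranks order by article count, rate ranks by the
*unrounded* rate (both competition ranking, ties share the smallest
rank); when two countries' rounded rates tie, the displayed rank is the
shared range (e.g. "13/14"), matching how such ties are conventionally
printed. The shipped benchmark input table carries the published article
counts and prisoner populations; one source inconsistency (a US article
count printed as 2922 in the table but 2992 in the accompanying text,
only the latter consistent with the printed percentage) is preserved
as-printed in the table rather than silently corrected.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes:
each abstract is a template-composed paragraph; each characteristic is
included by an independent Bernoulli draw; surfaces are sampled from the
shipped dictionaries; gold is recorded at the standardized level (the
abstract-level evaluation unit). Default inclusion probabilities are the
coverage rates observed in the reference corpus — age 0.149, sex 0.237,
nationality 0.276, offender type 0.139 — and years are uniform on
1990-2023, the span of the trend analyses. Templates are stored as data
alongside the rules so template/rule drift is caught by a single shared
regression test (planted spans must be recovered exactly).

Sampling pools are restricted to surfaces belonging to a single
characteristic (no "girls", which is both a sex term and a minor-age
term), so the recorded gold is exactly the planted content and noise-free
end-to-end extraction achieves 100% precision and recall by construction
— the pipeline's regression gate, run at n = 1000 with a fixed seed.

Noise modes emulate the two documented error sources. *Misspelling
noise* corrupts, with the configured probability, every alphabetic token
of a planted span (one adjacent-letter transposition per token; partial
corruption could still satisfy a shorter rule and defeat the purpose);
gold is unchanged because it reflects intended content, and each
perturbed token is logged so expected false negatives are computable.
*Unseen-pattern noise* (age and offender type) plants statements phrased
outside the rule set's coverage, yielding gold with no recoverable span.
What these synthetic conditions do **not** show: robustness to real
scientific prose, to phrasings outside the template vocabulary, or to the
dictionary-coverage limits of the seed lexicons — passing tests certify
the machinery, not corpus-scale recall on real abstracts.

## Problem sizes and determinism

The regression and reproduction runs use 1000 synthetic abstracts,
randomized property checks use 50-200 trials, and the oracle-equivalence
checks use 100 random fixtures — sizes at which every check completes in
seconds while binomial fluctuation in inclusion frequencies stays within
±4 standard errors of the configured probabilities. All randomness flows
from a single integer seed (`random.Random`); fixed seed implies
byte-identical corpora and identical downstream numbers.

## Known limitations

* Seed dictionaries and the starter rule set are representative, not the
  full production artifacts; mention counts on a real corpus will grow
  with dictionary coverage. Both are plain TSV and user-extensible (rules
  are organized one file per characteristic).
* Bare dictionary rules for sex/age/population terms are liberal by
  design; precision on real text depends on the documented
  no-negation/no-context limitations.
* Live literature retrieval is out of scope; the search query ships as a
  documented configuration value only.
* Figures are not rendered; the analytics return tables (TSV/JSON), and
  plotting is left to the caller.
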