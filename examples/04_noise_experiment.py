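"""Controlled error analysis: misspelling noise produces false negatives.

Generates the same 1000-abstract corpus twice — once clean, once with a
20% chance of misspelling each planted age phrase — and compares age
precision/recall. Misspellings break the lexical patterns without
changing the gold (the intended content), so recall drops while precision
stays at 100: the characteristic false-negative signature of a rule-based
extractor.
"""

from popchar import (
    Characteristic,
    GeneratorConfig,
    compute_metrics,
    default_engine,
    evaluate_corpus,
    extract_abstract,
    generate,
)

_, rules, normalizer = default_engine()


def run(misspell: float):
    config = GeneratorConfig(
        n=1000, seed=1, misspell_probability=misspell,
        noise_characteristics=(Characteristic.AGE,),
    )
    abstracts = generate(config, normalizer=normalizer)
    totals = evaluate_corpus(
        {a.gold.pmid: a.gold for a in abstracts},
        {
            a.record.pmid: extract_abstract(a.record, rules, normalizer)[1]
            for a in abstracts
        },
    )
    return compute_metrics(totals[Characteristic.AGE])


clean = run(0.0)
noisy = run(0.2)
print(f"age metrics, clean corpus : P={clean.precision} R={clean.recall}")
print(f"age metrics, 20% misspell : P={noisy.precision} R={noisy.recall}")
print()
print("Recall falls roughly in line with the share of corrupted mentions,")
print("while precision is untouched: noise removes matches, it does not")
print("create wrong ones.")
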