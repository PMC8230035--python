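"""Quarter-over-quarter tracking of reporting quality.

Generates two synthetic quarters in which newspapers reduce their use of
criminalizing language (the N1 prevalence drops from its default 0.65 to
0.40) and start publishing more helpline information (P1 rises to 0.30),
then prints the per-criterion percentage-point deltas a monitoring desk
would report to the newsrooms.
"""

import datetime as dt

from mediascorecard import (
    DEFAULT_PREVALENCE,
    GeneratorConfig,
    code_corpus_auto,
    compare_periods,
    default_helpline_registry,
    default_lexicon,
    frequency_table,
    generate_corpus,
    score_all,
    summarize_by_newspaper,
)

lex = default_lexicon()
reg = default_helpline_registry()


def run_quarter(period, prevalence, seed):
    cfg = GeneratorConfig(
        n_articles=400,
        period=period,
        prevalence=prevalence,
        screening_mix={"included": 1.0, **{k: 0.0 for k in (
            "general_commentary", "ideation_only", "bombing_intent",
            "undetermined_cause", "below_half_content", "not_matching_prefilter")}},
        seed=seed,
    )
    corpus, _ = generate_corpus(cfg)
    records = code_corpus_auto(corpus, lex, reg)
    scores = score_all(records)
    return summarize_by_newspaper(scores, corpus), frequency_table(records)


q2 = run_quarter((dt.date(2020, 4, 1), dt.date(2020, 6, 30)), DEFAULT_PREVALENCE, seed=1)
improved = dict(DEFAULT_PREVALENCE, N1=0.40, P1=0.30)
q3 = run_quarter((dt.date(2020, 7, 1), dt.date(2020, 9, 30)), improved, seed=2)

comparison = compare_periods(q2, q3)
deltas = comparison.criterion_deltas
print("largest criterion shifts (percentage points, later minus earlier):")
print(deltas.reindex(deltas["d_percent"].abs().sort_values(ascending=False).index).head(5))
print(
    "\nN1 (criminalizing language) falling ~25 points and P1 (helpline "
    "information) rising ~20 points is exactly the planted improvement; "
    "the other criteria move only by sampling noise."
)
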