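"""Code and score a single article against the 20-criterion scorecard.

Builds one article by hand, runs the automatic lexicon detectors, and
prints each criterion that fired with its evidence, then the article's
(positive, negative) score pair on the two 0-10 scales.
"""

import datetime as dt

from mediascorecard import (
    Article,
    code_article_auto,
    default_helpline_registry,
    default_lexicon,
    get_criterion,
    score_article,
)

article = Article(
    article_id="demo-1",
    newspaper="The Daily Example",
    publication_date=dt.date(2020, 5, 12),
    headline="Trader ends life over mounting debt",
    body=(
        "A 42-year-old trader died by suicide at his home on Tuesday. "
        "Neighbours told reporters that he had committed suicide after "
        "months of financial strain. He had been battling depression, "
        "relatives said. Police officers confirmed the sequence of events. "
        "Those in distress can contact the Sneha Suicide Prevention Centre "
        "on 044-24640050."
    ),
    page_number=4,
)

record = code_article_auto(article, default_lexicon(), default_helpline_registry())

print("criteria present:")
for code, value in record.codes.items():
    if value:
        name = get_criterion(code).name
        spans = "; ".join(f'"{e.text}"' for e in record.evidence.get(code, []))
        print(f"  {code:>3}  {name}  <- {spans}")

score = score_article(record)
print(f"\npositive score {score.positive_score}/10 (higher is better)")
print(f"negative score {score.negative_score}/10 (lower is better)")
print(
    "\nThe article earns positive credit for the helpline (P1, operational "
    "P2), the mental-health link (P3) and official sourcing (P10), but is "
    "penalised for criminalizing language (N1) and an attention-grabbing "
    "headline (N2)."
)
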