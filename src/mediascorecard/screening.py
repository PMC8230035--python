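"""Corpus screening: inclusion/exclusion rules and PRISMA-style counts.

Only articles on specific cases of death by suicide or attempted suicide
are scored. Screening applies, in a fixed order: period and language
checks, a keyword prefilter ("suicide", "kills self", "ends life"),
category exclusions (general commentary, ideation-only pieces, bombings
with intent to kill oneself and others, undetermined cause of death), and
finally a content-relevance rule: an article where less than half of the
content concerns the case is excluded. The first failing rule determines
the exclusion reason, so decisions are reproducible.

The "half the content" judgment is operationalized at sentence
granularity: the fraction of body sentences containing at least one
suicide-case term, computed with a deterministic rule-based sentence
splitter. Exactly one half is included; strictly less is excluded.
Category exclusions are primarily driven by an optional per-article
category tag supplied by a human screener; when no tag is present a
lexicon-cue fallback is applied and flagged as heuristic in the report.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

from .corpus import Article, Corpus
from .lexicon import Lexicon, default_lexicon
from .textmatch import contains_any, split_sentences

EXCLUSION_REASONS = (
    "out_of_period",
    "wrong_language",
    "not_matching_prefilter",
    "general_commentary",
    "ideation_only",
    "bombing_intent",
    "undetermined_cause",
    "below_half_content",
)
ALL_REASONS = ("included",) + EXCLUSION_REASONS

# category tags a human screener may attach to an article; "case_report"
# (or no tag at all) means no category exclusion applies
CATEGORY_TAGS = (
    "case_report",
    "general_commentary",
    "ideation_only",
    "bombing_intent",
    "undetermined_cause",
)

_CATEGORY_CUE_KEYS = (
    ("general_commentary", "commentary_cues"),
    ("ideation_only", "ideation_cues"),
    ("bombing_intent", "bombing_cues"),
    ("undetermined_cause", "undetermined_cues"),
)


@dataclass
class ScreeningConfig:
    keywords: tuple[str, ...] = ("suicide", "kills self", "ends life")
    period: Optional[tuple[_dt.date, _dt.date]] = None
    language: Optional[str] = None
    category_field: str = "screening_category"
    language_field: str = "language"
    lexicon: Lexicon = field(default_factory=default_lexicon)
    use_cue_fallback: bool = True

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword prefilter requires at least one phrase")


@dataclass(frozen=True)
class ScreeningDecision:
    article_id: str
    included: bool
    reason: str
    relevance_fraction: Optional[float] = None
    heuristic: bool = False  # category reason came from cue fallback, not a tag

    def __post_init__(self) -> None:
        if self.reason not in ALL_REASONS:
            raise ValueError(f"unknown screening reason {self.reason!r}")
        if self.included != (self.reason == "included"):
            raise ValueError("included flag must agree with reason")


@dataclass
class ScreeningReport:
    n_scanned: int
    n_identified: int
    n_included: int
    exclusions: dict[str, int]
    sentence_fraction_note: str = (
        "relevance measured as the fraction of body sentences containing a "
        "suicide-case term (rule-based splitter); this is a proxy for the "
        "'at least half the content' judgment"
    )

    def check_conservation(self) -> None:
        post = sum(
            self.exclusions.get(r, 0)
            for r in ("general_commentary", "ideation_only", "bombing_intent",
                      "undetermined_cause", "below_half_content")
        )
        if self.n_identified != self.n_included + post:
            raise AssertionError("screening counts do not conserve")


def keyword_prefilter(article: Article, keywords: tuple[str, ...]) -> bool:
    """True iff any keyword phrase occurs in the headline or body as a
    whole token sequence, case-insensitively."""
    if not keywords:
        raise ValueError("keyword prefilter requires at least one phrase")
    return contains_any(article.headline, keywords) or contains_any(article.body, keywords)


def relevance_fraction(article: Article, case_lexicon: Lexicon | list[str]) -> float:
    """Fraction of body sentences containing at least one suicide-case term.

    Deterministic for a fixed sentence splitter and lexicon; an empty body
    yields 0.
    """
    terms = case_lexicon["case_terms"] if isinstance(case_lexicon, Lexicon) else case_lexicon
    sentences = split_sentences(article.body)
    if not sentences:
        return 0.0
    hits = sum(1 for s in sentences if contains_any(s, terms))
    return hits / len(sentences)


def screen_article(article: Article, config: ScreeningConfig) -> ScreeningDecision:
    """Apply the screening rules in order; first failure decides the reason."""
    aid = article.article_id
    if config.period is not None and not (
        config.period[0] <= article.publication_date <= config.period[1]
    ):
        return ScreeningDecision(aid, False, "out_of_period")
    if config.language is not None:
        lang = article.extra.get(config.language_field)
        if lang is not None and str(lang).lower() != config.language.lower():
            return ScreeningDecision(aid, False, "wrong_language")
    if not keyword_prefilter(article, config.keywords):
        return ScreeningDecision(aid, False, "not_matching_prefilter")

    frac = relevance_fraction(article, config.lexicon)

    tag = article.extra.get(config.category_field)
    if tag is not None and tag != "":
        if tag not in CATEGORY_TAGS:
            raise ValueError(
                f"article {aid}: unknown screening category tag {tag!r}; "
                f"expected one of {CATEGORY_TAGS}"
            )
        if tag != "case_report":
            return ScreeningDecision(aid, False, tag, relevance_fraction=frac)
    elif config.use_cue_fallback:
        for reason, cue_key in _CATEGORY_CUE_KEYS:
            if contains_any(article.body, config.lexicon.get(cue_key)):
                return ScreeningDecision(
                    aid, False, reason, relevance_fraction=frac, heuristic=True
                )

    if frac < 0.5:  # strictly less than half excludes; exactly half is included
        return ScreeningDecision(aid, False, "below_half_content", relevance_fraction=frac)
    return ScreeningDecision(aid, True, "included", relevance_fraction=frac)


def screen_corpus(
    corpus: Corpus, config: Optional[ScreeningConfig] = None
) -> tuple[list[ScreeningDecision], ScreeningReport]:
    """Screen every article; report counts conserve by construction."""
    config = config or ScreeningConfig()
    decisions = [screen_article(a, config) for a in corpus]
    exclusions = {r: 0 for r in EXCLUSION_REASONS}
    n_included = 0
    for d in decisions:
        if d.included:
            n_included += 1
        else:
            exclusions[d.reason] += 1
    n_scanned = len(decisions)
    n_identified = n_scanned - (
        exclusions["out_of_period"]
        + exclusions["wrong_language"]
        + exclusions["not_matching_prefilter"]
    )
    report = ScreeningReport(
        n_scanned=n_scanned,
        n_identified=n_identified,
        n_included=n_included,
        exclusions={r: c for r, c in exclusions.items() if c},
    )
    report.check_conservation()
    return decisions, report


def format_prisma(report: ScreeningReport) -> str:
    """Plain-text PRISMA-style summary of a screening run."""
    lines = [
        "PRISMA-style screening summary",
        f"  records scanned:     {report.n_scanned}",
        f"  records identified:  {report.n_identified}",
    ]
    for reason in EXCLUSION_REASONS:
        if reason in report.exclusions:
            lines.append(f"    excluded, {reason}: {report.exclusions[reason]}")
    lines.append(f"  articles included:   {report.n_included}")
    lines.append(f"  note: {report.sentence_fraction_note}")
    return "\n".join(lines)
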