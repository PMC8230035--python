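"""Rule-based detectors for the 20 scorecard criteria.

Each detector maps an article to a binary code plus evidence spans
(character offsets into the article field that matched). Detection is
deterministic for a fixed lexicon: case-insensitive, token-boundary
anchored phrase matching, with per-criterion sub-rules — e.g. loose mood
qualifiers ("stressed") never count as a mental-health link, a bare
"sources" attribution never counts as official sourcing, and an
intoxicated state at the time of death never counts as a substance-abuse
link. Overlapping matches are merged for evidence reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional

from .corpus import Article
from .criteria import CriterionDefinition, get_criterion
from .lexicon import HelplineRegistry, Lexicon
from .textmatch import (
    Span,
    contains_any,
    find_any,
    find_phrase,
    find_regex,
    merge_spans,
    span_contained,
    split_sentences,
)


class UnsupportedModeError(ValueError):
    """Raised when automatic detection is requested for a manual-only criterion."""


@dataclass(frozen=True)
class Evidence:
    """A matched span supporting a code of 1."""

    field: str  # "headline", "body" or "metadata"
    start: int
    end: int
    text: str


def _ev(field: str, spans: list[Span], text: str) -> list[Evidence]:
    return [Evidence(field, s.start, s.end, s.text) for s in merge_spans(spans, text)]


def _sentence_offsets(body: str) -> list[tuple[int, str]]:
    """Sentences with their character offsets into ``body``."""
    out = []
    pos = 0
    for sent in split_sentences(body):
        start = body.index(sent, pos)
        out.append((start, sent))
        pos = start + len(sent)
    return out


_DIGIT = re.compile(r"\d")
_QUOTE = re.compile(r'["“”]')


# --- positive criteria ------------------------------------------------------


def _p1_helpline(article: Article, lex: Lexicon, registry=None):
    spans = find_any(article.body, lex["helpline_names"])
    spans += find_regex(article.body, lex["helpline_phone_patterns"])
    return (1 if spans else 0), _ev("body", spans, article.body)


def _p2_operational(article: Article, lex: Lexicon, registry: Optional[HelplineRegistry] = None):
    code, evidence = _p1_helpline(article, lex)
    if not code or registry is None:
        return 0, []
    verified = [e for e in evidence if registry.matches(e.text)]
    return (1 if verified else 0), verified


def _accept_over_reject(body: str, lex: Lexicon, accept_key: str, reject_key: str):
    accepts = find_any(body, lex[accept_key])
    rejects = find_any(body, lex[reject_key])
    # a reject-only match never fires; an accept match wins only as a span
    # distinct from (not contained in) any reject match
    winning = [a for a in accepts if not any(span_contained(a, r) for r in rejects)]
    return (1 if winning else 0), winning


def _p3_mental_health(article: Article, lex: Lexicon, registry=None):
    code, spans = _accept_over_reject(
        article.body, lex, "mental_health_accept_terms", "mental_health_reject_terms"
    )
    return code, _ev("body", spans, article.body)


def _p4_substance(article: Article, lex: Lexicon, registry=None):
    code, spans = _accept_over_reject(
        article.body, lex, "substance_struggle_terms", "intoxication_only_terms"
    )
    return code, _ev("body", spans, article.body)


def _p5_expert_comment(article: Article, lex: Lexicon, registry=None):
    spans: list[Span] = []
    for start, sent in _sentence_offsets(article.body):
        roles = find_any(sent, lex["expert_role_terms"])
        if roles and contains_any(sent, lex["attribution_verbs"]):
            spans += [Span(start + s.start, start + s.end, s.text) for s in roles]
    return (1 if spans else 0), _ev("body", spans, article.body)


def _p6_prevention(article: Article, lex: Lexicon, registry=None):
    spans = find_any(article.body, lex["prevention_markers"])
    return (1 if spans else 0), _ev("body", spans, article.body)


def _p7_statistics(article: Article, lex: Lexicon, registry=None):
    spans: list[Span] = []
    for start, sent in _sentence_offsets(article.body):
        marks = find_any(sent, lex["stat_markers"])
        if marks and _DIGIT.search(sent):
            spans += [Span(start + s.start, start + s.end, s.text) for s in marks]
    return (1 if spans else 0), _ev("body", spans, article.body)


def _p8_myths(article: Article, lex: Lexicon, registry=None):
    spans: list[Span] = []
    for start, sent in _sentence_offsets(article.body):
        myths = find_any(sent, lex["myth_markers"])
        if myths and contains_any(sent, lex["refutation_markers"]):
            spans += [Span(start + s.start, start + s.end, s.text) for s in myths]
    return (1 if spans else 0), _ev("body", spans, article.body)


def _p9_hope(article: Article, lex: Lexicon, registry=None):
    spans = find_any(article.body, lex["hope_markers"])
    return (1 if spans else 0), _ev("body", spans, article.body)


def _p10_official(article: Article, lex: Lexicon, registry=None):
    officials = find_any(article.body, lex["official_source_terms"])
    bare = find_any(article.body, lex["bare_source_phrases"])
    winning = [o for o in officials if not any(span_contained(o, b) for b in bare)]
    return (1 if winning else 0), _ev("body", winning, article.body)


# --- negative criteria ------------------------------------------------------


def _n1_criminalizing(article: Article, lex: Lexicon, registry=None):
    ev = []
    for fieldname in ("headline", "body"):
        text = getattr(article, fieldname)
        spans = find_any(text, lex["criminalizing_phrases"])
        ev += _ev(fieldname, spans, text)
    return (1 if ev else 0), ev


def _n2_headline(article: Article, lex: Lexicon, registry=None):
    head = article.headline
    spans = find_phrase(head, "suicide")
    spans += find_any(head, lex["method_terms"])
    cues = find_any(head, lex["reason_cues"])
    stressors = find_any(head, lex["reason_stressors"])
    if cues and stressors:
        spans += cues + stressors
    return (1 if spans else 0), _ev("headline", spans, head)


def _n3_method(article: Article, lex: Lexicon, registry=None):
    ev = []
    for fieldname in ("headline", "body"):
        text = getattr(article, fieldname)
        spans = find_any(text, lex["method_terms"])
        ev += _ev(fieldname, spans, text)
    return (1 if ev else 0), ev


def _n4_method_detail(article: Article, lex: Lexicon, registry=None):
    distinct = [t for t in lex["method_detail_terms"] if contains_any(article.body, [t])]
    if len(distinct) < 2:
        return 0, []
    spans = find_any(article.body, distinct)
    return 1, _ev("body", spans, article.body)


def _n5_site(article: Article, lex: Lexicon, registry=None):
    spans = find_any(article.body, lex["site_terms"])
    return (1 if spans else 0), _ev("body", spans, article.body)


def _n6_single_factor(article: Article, lex: Lexicon, registry=None):
    markers = find_any(article.body, lex["single_factor_markers"])
    if not markers or contains_any(article.body, lex["speculation_markers"]):
        return 0, []
    return 1, _ev("body", markers, article.body)


def _n7_photos(article: Article, lex: Lexicon, registry=None):
    if article.has_photo or article.photo_kinds:
        kinds = ",".join(sorted(article.photo_kinds)) or "unspecified"
        return 1, [Evidence("metadata", 0, 0, f"has_photo={article.has_photo};kinds={kinds}")]
    return 0, []


def _n8_grief(article: Article, lex: Lexicon, registry=None):
    spans = find_any(article.body, lex["grief_terms"])
    return (1 if spans else 0), _ev("body", spans, article.body)


def _n9_note(article: Article, lex: Lexicon, registry=None):
    spans = find_any(article.body, lex["note_terms"])
    if spans and _QUOTE.search(article.body):
        return 1, _ev("body", spans, article.body)
    return 0, []


def _n10_front_page(article: Article, lex: Lexicon, registry=None):
    if article.page_number == 1 or article.continues_from_front_page:
        return 1, [
            Evidence(
                "metadata",
                0,
                0,
                f"page_number={article.page_number};"
                f"continues_from_front_page={article.continues_from_front_page}",
            )
        ]
    return 0, []


_DETECTORS: dict[str, Callable] = {
    "P1": _p1_helpline,
    "P2": _p2_operational,
    "P3": _p3_mental_health,
    "P4": _p4_substance,
    "P5": _p5_expert_comment,
    "P6": _p6_prevention,
    "P7": _p7_statistics,
    "P8": _p8_myths,
    "P9": _p9_hope,
    "P10": _p10_official,
    "N1": _n1_criminalizing,
    "N2": _n2_headline,
    "N3": _n3_method,
    "N4": _n4_method_detail,
    "N5": _n5_site,
    "N6": _n6_single_factor,
    "N7": _n7_photos,
    "N8": _n8_grief,
    "N9": _n9_note,
    "N10": _n10_front_page,
}


def detect_criterion(
    article: Article,
    criterion: CriterionDefinition | str,
    lexicon: Lexicon,
    registry: Optional[HelplineRegistry] = None,
) -> tuple[int, list[Evidence]]:
    """Run one criterion's detector on one article.

    Returns ``(code, evidence)``; evidence is nonempty only when code is 1.
    Raises :class:`UnsupportedModeError` for manual-only criteria.
    """
    if isinstance(criterion, str):
        criterion = get_criterion(criterion)
    if criterion.detection_mode == "manual_only":
        raise UnsupportedModeError(
            f"criterion {criterion.code} is manual-only; no automatic detector"
        )
    code, evidence = _DETECTORS[criterion.code](article, lexicon, registry)
    return code, evidence
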