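"""The 20-item scorecard registry: 10 protective ("positive") and 10
harmful ("negative") reporting practices, each coded 1 (present) or
0 (absent) per article.

Codes P1..P10 follow the positive rubric order (helpline information
first, official sourcing last) and N1..N10 the negative order
(criminalizing language first, front-page placement last). The registry is
fixed: detectors, coding sheets, reconciliation and scoring all key on
these codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Polarity = Literal["positive", "negative"]
DetectionMode = Literal["auto", "hybrid", "manual_only"]

POSITIVE_CODES = tuple(f"P{i}" for i in range(1, 11))
NEGATIVE_CODES = tuple(f"N{i}" for i in range(1, 11))
ALL_CODES = POSITIVE_CODES + NEGATIVE_CODES


@dataclass(frozen=True)
class CriterionDefinition:
    code: str
    polarity: Polarity
    name: str
    scope: frozenset[str]  # subset of {"headline", "body", "metadata"}
    detection_mode: DetectionMode


_BODY = frozenset({"body"})
_HEAD = frozenset({"headline"})
_HB = frozenset({"headline", "body"})
_META = frozenset({"metadata"})

_REGISTRY: tuple[CriterionDefinition, ...] = (
    CriterionDefinition("P1", "positive", "Presence of help-seeking information", _BODY, "auto"),
    CriterionDefinition(
        "P2", "positive", "Help-seeking information is up to date and operational", _BODY, "hybrid"
    ),
    CriterionDefinition("P3", "positive", "Links to poor mental health", _BODY, "auto"),
    CriterionDefinition("P4", "positive", "Links to drug/alcohol abuse", _BODY, "auto"),
    CriterionDefinition(
        "P5",
        "positive",
        "Comments from mental health and suicide prevention experts",
        _BODY,
        "auto",
    ),
    CriterionDefinition(
        "P6", "positive", "Reduces stigma, highlights suicides are preventable", _BODY, "auto"
    ),
    CriterionDefinition(
        "P7",
        "positive",
        "Credible population-level suicide statistics and/or other research findings",
        _BODY,
        "auto",
    ),
    CriterionDefinition("P8", "positive", "Challenges popular myths", _BODY, "auto"),
    CriterionDefinition("P9", "positive", "Links to hopeful stories", _BODY, "auto"),
    CriterionDefinition(
        "P10", "positive", "Verified information and facts from official source", _BODY, "auto"
    ),
    CriterionDefinition("N1", "negative", "Use of criminalizing language", _HB, "auto"),
    CriterionDefinition("N2", "negative", "Attention-grabbing headline", _HEAD, "auto"),
    CriterionDefinition(
        "N3",
        "negative",
        "Method of suicide or attempted suicide is mentioned in the article",
        _HB,
        "auto",
    ),
    CriterionDefinition("N4", "negative", "Describes method in detail", _BODY, "auto"),
    CriterionDefinition("N5", "negative", "Discloses details of the suicide site", _BODY, "auto"),
    CriterionDefinition(
        "N6", "negative", "Reduces reason to a single factor or event", _BODY, "auto"
    ),
    CriterionDefinition(
        "N7", "negative", "Accompanying photos", frozenset({"metadata"}), "auto"
    ),
    CriterionDefinition(
        "N8", "negative", "Contains information on grieving persons", _BODY, "auto"
    ),
    CriterionDefinition("N9", "negative", "Publishes note or text", _BODY, "auto"),
    CriterionDefinition(
        "N10",
        "negative",
        "Article is on the front page of the newspaper",
        frozenset({"metadata"}),
        "auto",
    ),
)


def load_criteria() -> list[CriterionDefinition]:
    """The fixed registry of 20 criteria, ordered P1..P10, N1..N10."""
    return list(_REGISTRY)


def get_criterion(code: str) -> CriterionDefinition:
    for c in _REGISTRY:
        if c.code == code:
            return c
    raise KeyError(f"unknown criterion code {code!r}")


def polarity_of(code: str) -> Polarity:
    if code in POSITIVE_CODES:
        return "positive"
    if code in NEGATIVE_CODES:
        return "negative"
    raise KeyError(f"unknown criterion code {code!r}")
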