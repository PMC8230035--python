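"""Deterministic text primitives shared by screening and criterion detection.

All matching is case-insensitive and token-boundary anchored: a phrase
matches only as a whole token sequence, so "suicide" never matches inside
"suicidal". Sentence splitting is a fixed punctuation rule, not a trained
model, so every downstream decision is reproducible.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Iterable, NamedTuple

# Split after ., ! or ? followed by whitespace. Decimal points ("10.4") and
# digit groupings ("100,000") never match because no whitespace follows.
_SENTENCE_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


class Span(NamedTuple):
    """A half-open character span [start, end) with the matched text."""

    start: int
    end: int
    text: str


def split_sentences(text: str) -> list[str]:
    """Split ``text`` into sentences with a deterministic punctuation rule."""
    return [s for s in _SENTENCE_BOUNDARY.split(text) if s.strip()]


@lru_cache(maxsize=4096)
def phrase_pattern(phrase: str) -> re.Pattern[str]:
    """Compile a token-boundary-anchored, whitespace-flexible phrase pattern."""
    tokens = [re.escape(t) for t in phrase.split()]
    if not tokens:
        raise ValueError("empty phrase")
    return re.compile(r"(?<!\w)" + r"\s+".join(tokens) + r"(?!\w)", re.IGNORECASE)


def find_phrase(text: str, phrase: str) -> list[Span]:
    """All token-anchored occurrences of ``phrase`` in ``text``."""
    return [Span(m.start(), m.end(), m.group(0)) for m in phrase_pattern(phrase).finditer(text)]


def find_any(text: str, phrases: Iterable[str]) -> list[Span]:
    """Occurrences of any of ``phrases``, sorted by position, duplicates kept."""
    spans: list[Span] = []
    for p in phrases:
        spans.extend(find_phrase(text, p))
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


def find_regex(text: str, patterns: Iterable[str]) -> list[Span]:
    """Occurrences of raw regex ``patterns`` (case-insensitive)."""
    spans: list[Span] = []
    for p in patterns:
        for m in re.finditer(p, text, re.IGNORECASE):
            spans.append(Span(m.start(), m.end(), m.group(0)))
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


def contains_any(text: str, phrases: Iterable[str]) -> bool:
    return any(phrase_pattern(p).search(text) for p in phrases)


def merge_spans(spans: Iterable[Span], text: str) -> list[Span]:
    """Merge overlapping or adjacent spans; matched text re-read from ``text``."""
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    merged: list[Span] = []
    for s in ordered:
        if merged and s.start <= merged[-1].end:
            last = merged[-1]
            end = max(last.end, s.end)
            merged[-1] = Span(last.start, end, text[last.start:end])
        else:
            merged.append(Span(s.start, s.end, text[s.start:s.end]))
    return merged


def span_contained(inner: Span, outer: Span) -> bool:
    return outer.start <= inner.start and inner.end <= outer.end
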