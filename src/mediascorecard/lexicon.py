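"""Lexicon and helpline-registry resources.

The lexicon is the versioned vocabulary behind every automatic criterion
detector: term lists and regex patterns keyed by purpose, stored as YAML so
deployments can adapt them (e.g. to regional helplines or local idiom)
without touching code. The helpline registry is the curated list of
operational crisis services used to verify help-seeking information
offline — never a live lookup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Optional

import yaml

# purposes that hold raw regex patterns rather than literal phrases
_PATTERN_KEYS = {"helpline_phone_patterns"}

# (accept, reject) purpose pairs that must stay disjoint
_DISJOINT_PAIRS = [
    ("mental_health_accept_terms", "mental_health_reject_terms"),
    ("substance_struggle_terms", "intoxication_only_terms"),
    ("official_source_terms", "bare_source_phrases"),
    ("single_factor_markers", "speculation_markers"),
]


class LexiconError(ValueError):
    pass


@dataclass
class Lexicon:
    """Named term-lists and pattern-lists keyed by purpose, with a version."""

    lists: dict[str, list[str]]
    version: str

    def __getitem__(self, purpose: str) -> list[str]:
        try:
            return self.lists[purpose]
        except KeyError:
            raise LexiconError(f"lexicon has no list for purpose {purpose!r}") from None

    def get(self, purpose: str) -> list[str]:
        return self.lists.get(purpose, [])

    def validate(self) -> None:
        for purpose, entries in self.lists.items():
            if purpose in _PATTERN_KEYS:
                for pat in entries:
                    try:
                        re.compile(pat)
                    except re.error as exc:
                        raise LexiconError(f"{purpose}: invalid pattern {pat!r}: {exc}")
                continue
            for term in entries:
                if term != term.lower():
                    raise LexiconError(f"{purpose}: entry {term!r} is not lowercase")
        for accept, reject in _DISJOINT_PAIRS:
            overlap = set(self.lists.get(accept, [])) & set(self.lists.get(reject, []))
            if overlap:
                raise LexiconError(f"{accept} and {reject} overlap: {sorted(overlap)}")
        if not self.version:
            raise LexiconError("lexicon version string missing")


@dataclass(frozen=True)
class HelplineEntry:
    name: str
    phone: str


@dataclass
class HelplineRegistry:
    """Local registry of operational crisis-support services."""

    entries: list[HelplineEntry]
    version: str = ""

    def _phone_digits(self) -> set[str]:
        return {re.sub(r"\D", "", e.phone) for e in self.entries}

    def _names(self) -> set[str]:
        return {e.name.lower() for e in self.entries}

    def matches(self, text: str) -> bool:
        """True when ``text`` (a matched helpline mention) names or numbers
        a registered service."""
        low = text.lower().strip()
        if any(name in low or low in name for name in self._names() if low):
            return True
        digits = re.sub(r"\D", "", text)
        return bool(digits) and digits in self._phone_digits()


def _resource_path(name: str) -> Path:
    return Path(str(_ilres.files("mediascorecard.resources") / name))


def load_lexicon(path: Optional[str | Path] = None) -> Lexicon:
    """Load a lexicon YAML; default is the packaged lexicon."""
    path = Path(path) if path is not None else _resource_path("lexicon.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "version" not in doc:
        raise LexiconError(f"{path}: lexicon file must be a mapping with a 'version' key")
    version = str(doc.pop("version"))
    lists: dict[str, list[str]] = {}
    for purpose, entries in doc.items():
        if entries is None:
            entries = []
        if not isinstance(entries, list):
            raise LexiconError(f"{path}: purpose {purpose!r} must map to a list")
        lists[purpose] = [str(e) for e in entries]
    lex = Lexicon(lists=lists, version=version)
    lex.validate()
    return lex


def load_helpline_registry(path: Optional[str | Path] = None) -> HelplineRegistry:
    """Load a helpline registry YAML; default is the packaged synthetic one."""
    path = Path(path) if path is not None else _resource_path("helplines.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = [
        HelplineEntry(name=str(e["name"]), phone=str(e.get("phone", "")))
        for e in doc.get("entries", [])
    ]
    return HelplineRegistry(entries=entries, version=str(doc.get("version", "")))


def default_lexicon() -> Lexicon:
    return load_lexicon()


def default_helpline_registry() -> HelplineRegistry:
    return load_helpline_registry()
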