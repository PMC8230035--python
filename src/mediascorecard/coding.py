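"""Coding records, automatic coding, manual-sheet ingestion, dual-coder
reconciliation and inter-rater agreement.

A :class:`CodingRecord` is one coder's 20 binary codes for one article —
the coder may be a human (identified by a coder id on a spreadsheet) or
the automatic detector pipeline (coder id ``"auto"``, with evidence
spans). Two independent records for the same article are merged by
:func:`reconcile`; agreement across many pairs is summarised per
criterion by :func:`interrater_agreement` with percent agreement and
Cohen's kappa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .corpus import Article
from .criteria import ALL_CODES, NEGATIVE_CODES, POSITIVE_CODES, load_criteria
from .detectors import Evidence, detect_criterion
from .lexicon import HelplineRegistry, Lexicon


class CodingValidationError(ValueError):
    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class CodingRecord:
    article_id: str
    coder_id: str
    codes: dict[str, int]
    evidence: dict[str, list[Evidence]] = field(default_factory=dict)
    coded_at: Optional[str] = None
    notes: str = ""

    def validate(self) -> list[str]:
        problems = []
        missing = [c for c in ALL_CODES if c not in self.codes]
        if missing:
            problems.append(f"codes missing for {', '.join(missing)}")
        bad = {c: v for c, v in self.codes.items() if v not in (0, 1)}
        if bad:
            problems.append(f"non-binary codes: {bad}")
        if self.codes.get("P2", 0) > self.codes.get("P1", 0):
            problems.append("P2=1 requires P1=1 (operational helpline implies helpline present)")
        for c, ev in self.evidence.items():
            if ev and self.codes.get(c) != 1:
                problems.append(f"evidence recorded for {c} but code is not 1")
        return problems

    def positive_sum(self) -> int:
        return sum(self.codes[c] for c in POSITIVE_CODES)

    def negative_sum(self) -> int:
        return sum(self.codes[c] for c in NEGATIVE_CODES)


Resolution = Literal["A", "B", "consensus_value", "unresolved"]


@dataclass(frozen=True)
class Discrepancy:
    criterion: str
    code_a: int
    code_b: int
    resolution: Resolution


@dataclass
class ReconciledCoding:
    article_id: str
    final_codes: dict[str, int]  # unresolved criteria are absent
    discrepancies: list[Discrepancy]
    resolved_by: str = ""

    @property
    def unresolved(self) -> list[str]:
        return [d.criterion for d in self.discrepancies if d.resolution == "unresolved"]


# ---------------------------------------------------------------------------


def code_article_auto(
    article: Article,
    lexicon: Lexicon,
    registry: Optional[HelplineRegistry] = None,
    criteria=None,
) -> CodingRecord:
    """Automatically code one article against all 20 criteria.

    Manual-only criteria (none in the default registry) are coded 0 and
    flagged ``needs_manual`` in the notes. The helpline coupling P2 <= P1
    holds by construction.
    """
    criteria = criteria if criteria is not None else load_criteria()
    codes: dict[str, int] = {}
    evidence: dict[str, list[Evidence]] = {}
    needs_manual: list[str] = []
    for crit in criteria:
        if crit.detection_mode == "manual_only":
            codes[crit.code] = 0
            needs_manual.append(crit.code)
            continue
        code, ev = detect_criterion(article, crit, lexicon, registry)
        codes[crit.code] = code
        if code and ev:
            evidence[crit.code] = ev
    if codes.get("P2", 0) > codes.get("P1", 0):  # defensive; detectors enforce it
        codes["P2"] = codes["P1"]
        evidence.pop("P2", None)
    notes = f"needs_manual: {','.join(needs_manual)}" if needs_manual else ""
    rec = CodingRecord(article.article_id, "auto", codes, evidence, notes=notes)
    problems = rec.validate()
    if problems:
        raise CodingValidationError([f"article {article.article_id}: {p}" for p in problems])
    return rec


def code_corpus_auto(
    corpus, lexicon: Lexicon, registry: Optional[HelplineRegistry] = None
) -> list[CodingRecord]:
    criteria = load_criteria()
    return [code_article_auto(a, lexicon, registry, criteria) for a in corpus]


# ---------------------------------------------------------------------------
# manual coding sheets (CSV: article_id, coder_id, P1..P10, N1..N10, notes)


def ingest_manual_codes(path: str | Path) -> list[CodingRecord]:
    """Read a manual coding sheet; reject non-binary cells and P1/P2
    inconsistencies with cell-level diagnostics."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    errors: list[str] = []
    unknown = [
        c
        for c in df.columns
        if c not in ("article_id", "coder_id", "notes", "screening_category") + tuple(ALL_CODES)
    ]
    if unknown:
        errors.append(f"unknown column(s): {', '.join(unknown)}")
    missing_cols = [c for c in ("article_id",) + tuple(ALL_CODES) if c not in df.columns]
    if missing_cols:
        errors.append(f"missing column(s): {', '.join(missing_cols)}")
    if errors:
        raise CodingValidationError(errors)

    records: list[CodingRecord] = []
    for idx, row in df.iterrows():
        where = f"{path.name} row {idx + 2}"
        if not row["article_id"]:
            errors.append(f"{where}: missing article_id")
            continue
        codes: dict[str, int] = {}
        row_ok = True
        for c in ALL_CODES:
            cell = str(row[c]).strip()
            if cell not in ("0", "1"):
                errors.append(f"{where}, column {c}: value {cell!r} is not 0 or 1")
                row_ok = False
            else:
                codes[c] = int(cell)
        if row_ok and codes["P2"] > codes["P1"]:
            errors.append(
                f"{where}: P2=1 with P1=0 is inconsistent "
                "(operational helpline implies helpline present)"
            )
            row_ok = False
        if row_ok:
            records.append(
                CodingRecord(
                    article_id=str(row["article_id"]),
                    coder_id=str(row.get("coder_id", "") or "unknown"),
                    codes=codes,
                    notes=str(row.get("notes", "")),
                )
            )
    if errors:
        raise CodingValidationError(errors)
    return records


def write_coding_records(records: Iterable[CodingRecord], path: str | Path) -> None:
    """Write coding records as JSONL."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            obj = {
                "article_id": r.article_id,
                "coder_id": r.coder_id,
                "codes": {c: r.codes[c] for c in ALL_CODES},
                "evidence": {
                    c: [[e.field, e.start, e.end, e.text] for e in ev]
                    for c, ev in r.evidence.items()
                },
                "notes": r.notes,
            }
            if r.coded_at:
                obj["coded_at"] = r.coded_at
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def read_coding_records(path: str | Path) -> list[CodingRecord]:
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                CodingRecord(
                    article_id=obj["article_id"],
                    coder_id=obj["coder_id"],
                    codes={c: int(v) for c, v in obj["codes"].items()},
                    evidence={
                        c: [Evidence(f, s, e, t) for f, s, e, t in ev]
                        for c, ev in obj.get("evidence", {}).items()
                    },
                    coded_at=obj.get("coded_at"),
                    notes=obj.get("notes", ""),
                )
            )
    return records


# ---------------------------------------------------------------------------
# reconciliation

Strategy = Literal["flag", "prefer_A", "prefer_B", "conservative"]


def reconcile(
    rec_a: CodingRecord,
    rec_b: CodingRecord,
    strategy: Strategy = "flag",
    resolved_by: str = "",
) -> ReconciledCoding:
    """Merge two coders' records for the same article.

    Agreeing criteria are copied to the final codes. Disagreements are
    resolved per strategy: ``flag`` leaves them unresolved for a human
    consensus pass; ``prefer_A``/``prefer_B`` take one coder's reading;
    ``conservative`` takes the stricter reading — absent (0) for positive
    criteria, present (1) for negative criteria.
    """
    if rec_a.article_id != rec_b.article_id:
        raise ValueError(
            f"cannot reconcile codings of different articles "
            f"({rec_a.article_id!r} vs {rec_b.article_id!r})"
        )
    if strategy not in ("flag", "prefer_A", "prefer_B", "conservative"):
        raise ValueError(f"unknown reconciliation strategy {strategy!r}")
    final: dict[str, int] = {}
    discrepancies: list[Discrepancy] = []
    for c in ALL_CODES:
        a, b = rec_a.codes[c], rec_b.codes[c]
        if a == b:
            final[c] = a
            continue
        if strategy == "flag":
            discrepancies.append(Discrepancy(c, a, b, "unresolved"))
        elif strategy == "prefer_A":
            final[c] = a
            discrepancies.append(Discrepancy(c, a, b, "A"))
        elif strategy == "prefer_B":
            final[c] = b
            discrepancies.append(Discrepancy(c, a, b, "B"))
        else:  # conservative: stricter reading
            final[c] = 0 if c.startswith("P") else 1
            discrepancies.append(Discrepancy(c, a, b, "consensus_value"))
    # defensive: valid inputs cannot break the helpline coupling, but
    # restore P2 <= P1 if a strategy ever resolved them inconsistently
    if "P1" in final and "P2" in final and final["P2"] > final["P1"]:
        final["P2"] = final["P1"]
    return ReconciledCoding(rec_a.article_id, final, discrepancies, resolved_by=resolved_by)


def resolve_discrepancy(
    rc: ReconciledCoding, criterion: str, value: int, resolved_by: str = ""
) -> ReconciledCoding:
    """Enter a human consensus value for a flagged discrepancy."""
    if value not in (0, 1):
        raise ValueError("consensus value must be 0 or 1")
    new_disc = []
    found = False
    for d in rc.discrepancies:
        if d.criterion == criterion and d.resolution == "unresolved":
            new_disc.append(Discrepancy(d.criterion, d.code_a, d.code_b, "consensus_value"))
            found = True
        else:
            new_disc.append(d)
    if not found:
        raise KeyError(f"no unresolved discrepancy for criterion {criterion!r}")
    final = dict(rc.final_codes)
    final[criterion] = value
    return ReconciledCoding(rc.article_id, final, new_disc, resolved_by or rc.resolved_by)


# ---------------------------------------------------------------------------
# inter-rater agreement


def interrater_agreement(
    pairs: Sequence[tuple[CodingRecord, CodingRecord]]
) -> pd.DataFrame:
    """Per-criterion percent agreement and Cohen's kappa over coder pairs.

    Kappa is undefined (reported as NA) when expected chance agreement is 1,
    i.e. both coders' marginals are degenerate on the same value.
    """
    if not pairs:
        raise ValueError("interrater_agreement requires at least one pair of codings")
    rows = []
    n = len(pairs)
    for c in ALL_CODES:
        xs = [a.codes[c] for a, _ in pairs]
        ys = [b.codes[c] for _, b in pairs]
        agree = sum(x == y for x, y in zip(xs, ys)) / n
        p_yes_a = sum(xs) / n
        p_yes_b = sum(ys) / n
        p_chance = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
        if p_chance == 1.0:
            kappa = float("nan")
        else:
            kappa = float(cohen_kappa_score(xs, ys, labels=[0, 1]))
        rows.append({"criterion": c, "n": n, "percent_agreement": agree, "kappa": kappa})
    return pd.DataFrame(rows).set_index("criterion")
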