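"""Article scores, newspaper summaries, criterion frequency tables and
period-over-period comparisons.

Every criterion carries equal weight: an article's positive score is the
sum of its ten positive codes and its negative score the sum of its ten
negative codes, each on a 0-10 scale (positive: 10 best; negative: 10
worst). Newspaper summaries report the arithmetic mean and sample (n-1)
standard deviation of article scores per newspaper plus a pooled
all-newspapers row computed over all articles (article-weighted, not an
unweighted mean of newspaper means). Frequency tables report, per
criterion, the count and percentage of articles coded 1, with percentages
rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import pandas as pd

from .coding import CodingRecord, ReconciledCoding
from .corpus import Corpus
from .criteria import ALL_CODES, NEGATIVE_CODES, POSITIVE_CODES, get_criterion

POOLED_LABEL = "All newspapers"


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ArticleScore:
    article_id: str
    positive_score: int
    negative_score: int

    def __post_init__(self) -> None:
        for s in (self.positive_score, self.negative_score):
            if not (0 <= s <= 10):
                raise ValueError(f"score {s} outside the 0-10 scale")


@dataclass(frozen=True)
class NewspaperSummary:
    newspaper: str
    n_articles: int
    positive_mean: float
    positive_sd: Optional[float]  # absent when n_articles < 2
    negative_mean: float
    negative_sd: Optional[float]


@dataclass(frozen=True)
class FrequencyRow:
    code: str
    name: str
    count: int
    percent: float  # 100 * count / total, rounded half-up to 2 decimals


@dataclass
class FrequencyTable:
    rows: list[FrequencyRow]  # ordered by descending count within polarity
    total_articles: int

    def row(self, code: str) -> FrequencyRow:
        for r in self.rows:
            if r.code == code:
                return r
        raise KeyError(code)

    def percents(self) -> dict[str, float]:
        return {r.code: r.percent for r in self.rows}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "criterion": r.code,
                    "name": r.name,
                    "count": r.count,
                    "percent": r.percent,
                }
                for r in self.rows
            ]
        )


def round_percent(count: int, total: int) -> float:
    """Percentage of ``count``/``total`` rounded half-up to two decimals."""
    if total <= 0:
        raise ScoringError("total must be positive")
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _codes_of(
    coding: Union[CodingRecord, ReconciledCoding], permissive: bool
) -> dict[str, int]:
    if isinstance(coding, ReconciledCoding):
        unresolved = coding.unresolved
        if unresolved and not permissive:
            raise ScoringError(
                f"article {coding.article_id}: unresolved discrepancies on "
                f"{', '.join(unresolved)}; resolve them or score permissively"
            )
        codes = dict(coding.final_codes)
        # permissive scoring fills unresolved criteria with the stricter
        # (conservative) reading
        for c in unresolved:
            codes[c] = 0 if c.startswith("P") else 1
        return codes
    return coding.codes


def score_article(
    coding: Union[CodingRecord, ReconciledCoding], permissive: bool = False
) -> ArticleScore:
    """Sum the binary codes into the (positive, negative) score pair."""
    codes = _codes_of(coding, permissive)
    missing = [c for c in ALL_CODES if c not in codes]
    if missing:
        raise ScoringError(
            f"article {coding.article_id}: codes missing for {', '.join(missing)}"
        )
    return ArticleScore(
        article_id=coding.article_id,
        positive_score=sum(codes[c] for c in POSITIVE_CODES),
        negative_score=sum(codes[c] for c in NEGATIVE_CODES),
    )


def score_all(
    codings: Sequence[Union[CodingRecord, ReconciledCoding]], permissive: bool = False
) -> list[ArticleScore]:
    return [score_article(c, permissive) for c in codings]


def summarize_by_newspaper(
    scores: Sequence[ArticleScore], articles: Corpus
) -> list[NewspaperSummary]:
    """Mean and sample SD of scores grouped by newspaper, plus a pooled
    article-weighted row over all articles."""
    papers = {a.article_id: a.newspaper for a in articles}
    unknown = [s.article_id for s in scores if s.article_id not in papers]
    if unknown:
        raise ScoringError(f"score(s) reference unknown article(s): {', '.join(unknown)}")
    df = pd.DataFrame(
        {
            "newspaper": [papers[s.article_id] for s in scores],
            "positive": [s.positive_score for s in scores],
            "negative": [s.negative_score for s in scores],
        }
    )
    out: list[NewspaperSummary] = []

    def _summary(label: str, sub: pd.DataFrame) -> NewspaperSummary:
        n = len(sub)
        return NewspaperSummary(
            newspaper=label,
            n_articles=n,
            positive_mean=float(sub["positive"].mean()),
            positive_sd=float(sub["positive"].std(ddof=1)) if n >= 2 else None,
            negative_mean=float(sub["negative"].mean()),
            negative_sd=float(sub["negative"].std(ddof=1)) if n >= 2 else None,
        )

    for paper, sub in df.groupby("newspaper", sort=True):
        out.append(_summary(str(paper), sub))
    if len(df):
        out.append(_summary(POOLED_LABEL, df))
    return out


def summaries_to_dataframe(summaries: Sequence[NewspaperSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "newspaper": s.newspaper,
                "n_articles": s.n_articles,
                "positive_mean": s.positive_mean,
                "positive_sd": s.positive_sd,
                "negative_mean": s.negative_mean,
                "negative_sd": s.negative_sd,
            }
            for s in summaries
        ]
    )


def frequency_table(
    codings: Sequence[Union[CodingRecord, ReconciledCoding]],
    total: Optional[int] = None,
    permissive: bool = False,
) -> FrequencyTable:
    """Per-criterion counts and percentages over ``total`` articles.

    Rows are ordered by descending count within each polarity (positive
    block first); ties break on criterion code order.
    """
    if not codings:
        raise ScoringError("frequency_table requires at least one coding")
    total = total if total is not None else len(codings)
    if total < len(codings):
        raise ScoringError("total cannot be smaller than the number of codings")
    counts = {c: 0 for c in ALL_CODES}
    for coding in codings:
        codes = _codes_of(coding, permissive)
        for c in ALL_CODES:
            counts[c] += codes[c]
    rows: list[FrequencyRow] = []
    for block in (POSITIVE_CODES, NEGATIVE_CODES):
        ordered = sorted(block, key=lambda c: (-counts[c], block.index(c)))
        for c in ordered:
            rows.append(
                FrequencyRow(
                    code=c,
                    name=get_criterion(c).name,
                    count=counts[c],
                    percent=round_percent(counts[c], total),
                )
            )
    return FrequencyTable(rows=rows, total_articles=total)


@dataclass
class PeriodComparison:
    newspaper_deltas: pd.DataFrame  # index newspaper; d_positive_mean, d_negative_mean
    criterion_deltas: pd.DataFrame  # index criterion; d_percent (percentage points)
    only_in_a: list[str]
    only_in_b: list[str]


def compare_periods(
    a: tuple[Sequence[NewspaperSummary], FrequencyTable],
    b: tuple[Sequence[NewspaperSummary], FrequencyTable],
) -> PeriodComparison:
    """Signed deltas (B minus A) in per-newspaper means and per-criterion
    proportions between two scoring periods; newspapers present in only
    one period are flagged rather than differenced."""
    sum_a, freq_a = a
    sum_b, freq_b = b
    codes_a = {r.code for r in freq_a.rows}
    codes_b = {r.code for r in freq_b.rows}
    if codes_a != codes_b:
        raise ScoringError("criterion registries differ between the two periods")
    map_a = {s.newspaper: s for s in sum_a}
    map_b = {s.newspaper: s for s in sum_b}
    shared = sorted(set(map_a) & set(map_b))
    news = pd.DataFrame(
        {
            "d_positive_mean": [map_b[p].positive_mean - map_a[p].positive_mean for p in shared],
            "d_negative_mean": [map_b[p].negative_mean - map_a[p].negative_mean for p in shared],
        },
        index=pd.Index(shared, name="newspaper"),
    )
    pa = freq_a.percents()
    pb = freq_b.percents()
    crit = pd.DataFrame(
        {"d_percent": [pb[c] - pa[c] for c in ALL_CODES]},
        index=pd.Index(ALL_CODES, name="criterion"),
    )
    return PeriodComparison(
        newspaper_deltas=news,
        criterion_deltas=crit,
        only_in_a=sorted(set(map_a) - set(map_b)),
        only_in_b=sorted(set(map_b) - set(map_a)),
    )
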