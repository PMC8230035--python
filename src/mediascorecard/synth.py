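"""Synthetic corpus generator with per-article ground truth.

Generates newspaper-article records whose criterion presences and
screening categories are known by construction, so the screening rules,
the automatic detectors and the aggregation arithmetic can all be tested
end to end without any real news data. Criterion truths are independent
Bernoulli draws at configurable prevalences (defaults: the observed
per-criterion proportions in the study regime this package models, with
the operational-helpline code P2 drawn conditionally on P1). Bodies are
composed from templates that use only lexicon-listed trigger phrases for
present criteria and curated near-miss distractors (loose mood
qualifiers, bare "sources", intoxication-only mentions, speculation
cues) for absent ones, so detector recovery is decidable.

The generator emulates planted screening categories too: commentary,
ideation-only, bombing and undetermined-cause articles carry a screener
category tag and a cue sentence; below-half articles are padded with
off-topic sentences until less than half of the body concerns the case;
articles planted as not matching the keyword prefilter are rendered with
trigger-free text and all-zero truth codes (text containing any criterion
trigger would necessarily contain the word "suicide" and pass the
prefilter).
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .corpus import Article, Corpus, PHOTO_KINDS
from .criteria import ALL_CODES
from .lexicon import Lexicon, default_lexicon
from .screening import relevance_fraction

DEFAULT_PREVALENCE: dict[str, float] = {
    # positive criteria; P2 is P(operational | helpline present)
    "P1": 0.1055,
    "P2": 1.0,
    "P3": 0.2170,
    "P4": 0.0463,
    "P5": 0.0099,
    "P6": 0.0030,
    "P7": 0.0046,
    "P8": 0.0015,
    "P9": 0.0000,
    "P10": 0.8225,
    # negative criteria
    "N1": 0.6517,
    "N2": 0.7527,
    "N3": 0.8649,
    "N4": 0.1472,
    "N5": 0.1705,
    "N6": 0.4105,
    "N7": 0.1123,
    "N8": 0.0956,
    "N9": 0.0463,
    "N10": 0.0599,
}

# share of identified articles surviving screening in the regime modelled
# (~1318/2326); the per-reason split of exclusions is this package's choice
DEFAULT_SCREENING_MIX: dict[str, float] = {
    "included": 0.57,
    "general_commentary": 0.12,
    "ideation_only": 0.06,
    "bombing_intent": 0.02,
    "undetermined_cause": 0.09,
    "below_half_content": 0.07,
    "not_matching_prefilter": 0.07,
}

DEFAULT_NEWSPAPERS: tuple[tuple[str, float], ...] = tuple(
    (name, 1 / 9)
    for name in (
        "The Times of India",
        "Hindustan Times",
        "The New Indian Express",
        "The Telegraph",
        "The Hindu",
        "The Indian Express",
        "Mirror",
        "The Tribune",
        "The Economic Times",
    )
)

_TAGGED_CATEGORIES = (
    "general_commentary",
    "ideation_only",
    "bombing_intent",
    "undetermined_cause",
)


@dataclass
class GeneratorConfig:
    n_articles: int
    newspapers: tuple[tuple[str, float], ...] = DEFAULT_NEWSPAPERS
    period: tuple[_dt.date, _dt.date] = (_dt.date(2020, 4, 1), _dt.date(2020, 6, 30))
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    screening_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCREENING_MIX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 0:
            raise ValueError("n_articles must be >= 0")
        for code in ALL_CODES:
            p = self.prevalence.get(code)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence[{code}] must be a probability, got {p!r}")
        if abs(sum(w for _, w in self.newspapers) - 1.0) > 1e-6:
            raise ValueError("newspaper weights must sum to 1")
        if abs(sum(self.screening_mix.values()) - 1.0) > 1e-6:
            raise ValueError("screening_mix probabilities must sum to 1")
        bad = set(self.screening_mix) - set(DEFAULT_SCREENING_MIX)
        if bad:
            raise ValueError(f"unknown screening categories: {sorted(bad)}")

    def marginal_prevalence(self, code: str) -> float:
        """Unconditional presence probability (P2 folded through P1)."""
        if code == "P2":
            return self.prevalence["P1"] * self.prevalence["P2"]
        return self.prevalence[code]


@dataclass(frozen=True)
class TruthRecord:
    article_id: str
    true_codes: dict[str, int]
    screening_category: str


# ---------------------------------------------------------------------------
# templates


@dataclass
class Templates:
    """Sentence forms per criterion, plus distractors and scaffolding text.

    ``positive[code]`` sentences each contain a lexicon trigger for that
    criterion and nothing that trips any other detector; ``distractor[code]``
    sentences are near misses that must NOT fire the detector.
    """

    positive: dict[str, list[str]]
    distractor: dict[str, list[str]]
    base_sentences: list[str]
    case_fillers: list[str]
    neutral_fillers: list[str]
    headlines_suicide: list[str]
    headlines_reason: list[str]
    headlines_neutral: list[str]
    category_cues: dict[str, str]
    nonmatching_headline: str
    nonmatching_body: list[str]

    def check_coverage(self) -> None:
        # N2 renders through headlines, N7/N10 through metadata, P2 through
        # the choice of P1 helpline sentence (registered vs unregistered)
        missing = [
            c
            for c in ALL_CODES
            if c not in ("P2", "N2", "N7", "N10") and not self.positive.get(c)
        ]
        if missing:
            raise ValueError(f"templates lack positive sentence forms for {missing}")


def default_templates() -> Templates:
    return Templates(
        positive={
            "P1": [  # registered helpline (verifies against the shipped registry)
                "Those in distress can contact the Sneha Suicide Prevention Centre on 044-24640050.",
                "Readers seeking support can reach the iCALL Helpline on 022-25521111.",
            ],
            "P2": [],  # P2 rides on which P1 sentence is used; see render_article
            "P3": [
                "He had been battling depression for months, relatives said.",
                "She had appeared anxious and distraught in recent weeks.",
            ],
            "P4": [
                "He had struggled with alcohol addiction for several years.",
                "Relatives described a long battle with drug addiction.",
            ],
            "P5": [
                '"Timely support can save lives," said a senior psychiatrist.',
                "A mental health professional told this paper that early support matters.",
            ],
            "P6": [
                "Experts emphasised that suicides are preventable and that seeking help early makes a difference.",
            ],
            "P7": [
                "According to the National Crime Records Bureau, the national suicide rate stood at 10.4 per 100,000 in 2019.",
            ],
            "P8": [
                "It is a myth that talking about suicide encourages it, and the evidence shows this is not true.",
            ],
            "P9": [
                "The report also carried the account of a young woman who overcame suicidal thoughts and now mentors students.",
            ],
            "P10": [
                "Police officers confirmed the sequence of events.",
                "Hospital authorities stated that he was declared dead on arrival.",
            ],
            "N1": [
                "Neighbours told reporters that the man had committed suicide at his residence.",
            ],
            "N3": [
                "He was found hanging at his home, the report stated.",
            ],
            "N4": [
                "A nylon rope tied to the ceiling fan was recovered from the room.",
            ],
            "N5": [
                "The spot, a railway bridge on the eastern edge of the city, remains open to the public.",
            ],
            "N6": [
                "Relatives attributed the suicide to mounting debt.",
            ],
            "N8": [
                "His grieving family said they had noticed nothing amiss.",
            ],
            "N9": [
                'A suicide note recovered from the room read, "I alone am responsible for my decision."',
            ],
        },
        distractor={
            "P1": ["Friends said help had seemed out of reach."],
            "P3": ["He had seemed stressed and unhappy in recent weeks."],
            "P4": ["He was reportedly drunk at the time of the incident."],
            "P5": ["A neighbour said the family had kept mostly to themselves."],
            "P7": ["No broader figures were cited in the report."],
            "P10": ["According to sources, the family had recently moved to the city."],
            "N4": ["A nylon rope was found at the spot."],
            "N6": [
                "Some felt it was driven to suicide by debt, but the reason may be more complex."
            ],
        },
        base_sentences=[
            "A 34-year-old resident of the city died by suicide on Tuesday.",
            "The suicide has left the locality in shock.",
            "He had attempted suicide once earlier, the family said.",
        ],
        case_fillers=[
            "The suicide was reported in the city pages the following day.",
            "Residents said the suicide had come as a complete surprise.",
            "It was the second suicide reported from the area this year.",
            "Word of the suicide spread quickly through the neighbourhood.",
        ],
        neutral_fillers=[
            "The municipal council met the same week to discuss road repairs.",
            "Monsoon showers are expected over the coming days.",
            "The local market reopened after the weekend break.",
            "Traffic on the ring road remained heavy through the evening.",
            "A new bus route connecting the suburbs was announced.",
        ],
        headlines_suicide=[
            "City man dies by suicide at home",
            "Second suicide reported from the locality this month",
        ],
        headlines_reason=[
            "Student ends life after exam setback",
            "Trader ends life over mounting debt",
        ],
        headlines_neutral=[
            "Helpline numbers see more calls this summer",
            "Family seeks answers from city officials",
            "Quiet street comes to terms with a loss",
        ],
        category_cues={
            "general_commentary": "This piece is an editorial commentary on how the press covers suicide.",
            "ideation_only": "The feature examined suicidal ideation among college students rather than any single death.",
            "bombing_intent": "The attacker, described as a suicide bomber, blew himself up near the checkpoint.",
            "undetermined_cause": "Investigators said the death could be a suicide or a homicide, and inquiries continue.",
        },
        nonmatching_headline="Man found dead at his residence",
        nonmatching_body=[
            "A 45-year-old resident was found dead at his home on Tuesday.",
            "An investigation is under way.",
            "Neighbours described him as a quiet man.",
        ],
    )


# ---------------------------------------------------------------------------
# sampling and rendering


def sample_truth(
    config: GeneratorConfig, rng: random.Random, article_id: str = "syn-00000"
) -> TruthRecord:
    """Draw one ground-truth record: category from the screening mix,
    criterion codes as independent Bernoullis (P2 conditional on P1)."""
    u = rng.random()
    cum = 0.0
    category = "included"
    for cat, p in config.screening_mix.items():
        cum += p
        if u < cum:
            category = cat
            break
    codes: dict[str, int] = {}
    for code in ALL_CODES:
        if code == "P2":
            continue
        codes[code] = 1 if rng.random() < config.prevalence[code] else 0
    codes["P2"] = 1 if codes["P1"] and rng.random() < config.prevalence["P2"] else 0
    return TruthRecord(article_id=article_id, true_codes=codes, screening_category=category)


_DISTRACTOR_RATE = 0.3  # chance of planting a near-miss when a criterion is absent
_MAX_FILLERS = 120


def render_article(
    truth: TruthRecord,
    templates: Optional[Templates] = None,
    lexicon: Optional[Lexicon] = None,
    rng: Optional[random.Random] = None,
    newspaper: str = "The Daily Synthetic",
    publication_date: Optional[_dt.date] = None,
) -> Article:
    """Compose an article whose detector-visible content matches ``truth``.

    For every body-scope criterion a lexicon-matching sentence appears iff
    the true code is 1; absent criteria may instead receive a near-miss
    distractor. Page and photo metadata follow the N10/N7 truths, the
    headline follows N2.
    """
    templates = templates or default_templates()
    templates.check_coverage()
    lexicon = lexicon or default_lexicon()
    rng = rng or random.Random(0)
    pub = publication_date or _dt.date(2020, 5, 15)
    t = truth.true_codes
    cat = truth.screening_category

    if cat == "not_matching_prefilter":
        if any(t.values()):
            raise ValueError(
                "not_matching_prefilter articles must carry all-zero truth codes"
            )
        return Article(
            article_id=truth.article_id,
            newspaper=newspaper,
            publication_date=pub,
            headline=templates.nonmatching_headline,
            body=" ".join(templates.nonmatching_body),
            page_number=rng.randint(2, 20),
            has_photo=False,
        )

    sentences: list[str] = []
    if cat in _TAGGED_CATEGORIES:
        sentences.append(templates.category_cues[cat])
    sentences.extend(templates.base_sentences)

    crit_sentences: list[str] = []
    for code in ALL_CODES:
        if code in ("N2", "N7", "N10", "P2"):
            continue
        if code == "P1":
            if t["P1"]:
                if t.get("P2"):
                    crit_sentences.append(rng.choice(templates.positive["P1"]))
                else:
                    crit_sentences.append(
                        "Those in distress can call the Harmony Care helpline on 1800-000-2210."
                    )
            elif templates.distractor.get("P1") and rng.random() < _DISTRACTOR_RATE:
                crit_sentences.append(rng.choice(templates.distractor["P1"]))
            continue
        if t[code]:
            crit_sentences.append(rng.choice(templates.positive[code]))
        elif templates.distractor.get(code) and rng.random() < _DISTRACTOR_RATE:
            crit_sentences.append(rng.choice(templates.distractor[code]))
    rng.shuffle(crit_sentences)
    sentences.extend(crit_sentences)

    if t["N2"]:
        pool = templates.headlines_suicide + (
            templates.headlines_reason if not _reason_conflicts(templates) else []
        )
        headline = rng.choice(pool)
    else:
        headline = rng.choice(templates.headlines_neutral)

    page = 1 if t["N10"] else rng.randint(2, 20)
    has_photo = bool(t["N7"])
    kinds = frozenset(rng.sample(sorted(PHOTO_KINDS), rng.randint(1, 2))) if has_photo else frozenset()

    extra = {}
    if cat in _TAGGED_CATEGORIES:
        extra["screening_category"] = cat

    def _assemble() -> Article:
        return Article(
            article_id=truth.article_id,
            newspaper=newspaper,
            publication_date=pub,
            headline=headline,
            body=" ".join(sentences),
            page_number=page,
            continues_from_front_page=False,
            has_photo=has_photo,
            photo_kinds=kinds,
            extra=dict(extra),
        )

    # tune the sentence-level case-relevance fraction to the planted category
    filler_i = 0
    if cat == "below_half_content":
        while relevance_fraction(_assemble(), lexicon) >= 0.5 and filler_i < _MAX_FILLERS:
            sentences.append(
                templates.neutral_fillers[filler_i % len(templates.neutral_fillers)]
            )
            filler_i += 1
    else:
        while relevance_fraction(_assemble(), lexicon) < 0.5 and filler_i < _MAX_FILLERS:
            sentences.append(
                templates.case_fillers[filler_i % len(templates.case_fillers)]
            )
            filler_i += 1
    return _assemble()


def _reason_conflicts(templates: Templates) -> bool:
    # reason-form headlines are always safe with the default lexicon; hook
    # kept so custom templates can disable them wholesale
    return False


def generate_corpus(
    config: GeneratorConfig,
    templates: Optional[Templates] = None,
    lexicon: Optional[Lexicon] = None,
) -> tuple[Corpus, list[TruthRecord]]:
    """Generate a corpus plus aligned ground truth; byte-deterministic for
    a fixed config (including the seed)."""
    templates = templates or default_templates()
    lexicon = lexicon or default_lexicon()
    rng = random.Random(config.seed)
    names = [n for n, _ in config.newspapers]
    weights = [w for _, w in config.newspapers]
    n_days = (config.period[1] - config.period[0]).days
    articles: list[Article] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_articles):
        aid = f"syn-{i:05d}"
        truth = sample_truth(config, rng, article_id=aid)
        if truth.screening_category == "not_matching_prefilter":
            truth = replace(truth, true_codes={c: 0 for c in ALL_CODES})
        paper = rng.choices(names, weights=weights, k=1)[0]
        date = config.period[0] + _dt.timedelta(days=rng.randint(0, n_days))
        articles.append(
            render_article(
                truth,
                templates,
                lexicon,
                rng,
                newspaper=paper,
                publication_date=date,
            )
        )
        truths.append(truth)
    return (
        Corpus(articles, source_label=f"synthetic(seed={config.seed})", period=config.period),
        truths,
    )


def truth_to_sheet(truths: list[TruthRecord], path) -> None:
    """Write ground truth as a manual-coding-sheet CSV (coder_id="truth")."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["article_id", "coder_id", *ALL_CODES, "notes", "screening_category"])
        for t in truths:
            writer.writerow(
                [t.article_id, "truth", *[t.true_codes[c] for c in ALL_CODES], "", t.screening_category]
            )
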