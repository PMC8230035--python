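# mediascorecard

A scorecard for rating how responsibly newspapers report on suicide.

Media coverage of suicide is a population-level risk factor: sensational,
method-detailing, criminalizing reporting is associated with imitative
("Werther effect") suicides, while coverage that carries helpline
information, expert voices and recovery stories can promote help-seeking
(the "Papageno effect"). WHO and national press-council guidelines codify
these practices, but newsrooms rarely receive measurable feedback on
adherence. This package implements a 20-item scorecard for that purpose:
public-health surveillance teams can screen a news corpus down to
specific suicide case reports, code each article against 10 protective
and 10 harmful binary criteria, reconcile dual-coder judgments, and
report per-newspaper scores and per-criterion frequencies quarter over
quarter.

## The instrument

Each article receives 20 binary codes \(x_{P1},\dots,x_{P10},
x_{N1},\dots,x_{N10} \in \{0,1\}\) — 1 if the practice is present, 0 if
absent — with equal weight:

- **positive score** \(S^+ = \sum_{i=1}^{10} x_{Pi}\): helpline
  information present (P1) and operational (P2), mental-health linkage
  (P3), substance-abuse linkage (P4), expert comment (P5),
  prevention/stigma-reduction messaging (P6), population statistics (P7),
  myth challenged (P8), hopeful story (P9), official sourcing (P10).
  10 is best, 0 worst.
- **negative score** \(S^- = \sum_{j=1}^{10} x_{Nj}\): criminalizing
  language (N1), attention-grabbing headline (N2), method mentioned (N3),
  method detailed (N4), site disclosed (N5), cause reduced to a single
  factor (N6), photographs (N7), grieving persons (N8), suicide note
  published (N9), front-page placement (N10). 0 is best, 10 worst.

A newspaper's rating over a period is the mean (SD) of its articles'
scores on each scale; the pooled row is article-weighted. Criterion
frequency tables report, per criterion, the count and percentage of
articles coded 1 (half-up rounding at two decimals).

Codes come either from human coders (ingested CSV sheets, with
dual-coder reconciliation and Cohen's-kappa agreement reporting) or from
deterministic lexicon detectors that honour the rubric's sub-rules: loose
mood qualifiers ("stressed") never count as a mental-health link, a bare
"sources" never counts as official sourcing, intoxication at the time of
death never counts as a substance-abuse link, a single-factor claim is
cancelled by speculation cues, and helpline mentions are verified against
a local registry file, never a live lookup.

Corpus screening retains only articles on specific cases of death by
suicide or attempted suicide: a keyword prefilter ("suicide",
"kills self", "ends life"), category exclusions (commentary,
ideation-only, bombings intended to kill oneself and others,
undetermined cause of death) and a relevance rule excluding articles
where less than half of the body sentences concern the case, with a
PRISMA-style accounting of every exclusion.

## Worked example

`examples/01_score_one_article.py` codes a single constructed article:

```
criteria present:
   P1  Presence of help-seeking information  <- "Sneha Suicide Prevention Centre"; "044-24640050"
   P2  Help-seeking information is up to date and operational  <- "Sneha Suicide Prevention Centre"; "044-24640050"
   P3  Links to poor mental health  <- "depression"
  P10  Verified information and facts from official source  <- "Police officers"
   N1  Use of criminalizing language  <- "committed suicide"
   N2  Attention-grabbing headline  <- "over"; "debt"

positive score 4/10 (higher is better)
negative score 2/10 (lower is better)
```

The article earns positive credit for an operational helpline, a
mental-health link and official sourcing, and is penalised for the
phrase "committed suicide" and a headline that names the presumed
reason. The other examples run the full synthetic pipeline
(`02_synthetic_pipeline.py`), dual-coder reconciliation
(`03_dual_coders.py`) and quarter-over-quarter comparison
(`04_compare_quarters.py`).

The same workflow is available from the shell:

```sh
mediascorecard synth --n 500 --seed 42 --out run1
mediascorecard screen --corpus run1/corpus.jsonl --out run1
mediascorecard code   --corpus run1/corpus.jsonl --out run1
mediascorecard score  --codes run1/codes_auto.jsonl --corpus run1/corpus.jsonl --out run1
```

## Layout

- `src/mediascorecard/` — the library: `corpus` (data model + JSONL/CSV
  I/O), `screening`, `criteria`/`detectors`/`coding` (the rubric),
  `scoring`, `synth` (ground-truth corpus generator), `cli`.
- `src/mediascorecard/resources/` — the versioned default lexicon and a
  synthetic helpline registry (replace with a curated regional list in
  deployment).
- `docs/methods.md` — models, assumptions, parameter choices and
  limitations.
- `examples/` — one narrative script per capability.
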