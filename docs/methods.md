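# Methods

## The instrument and its assumptions

The scorecard treats responsible-reporting adherence as 20 independent
binary observations per article, 10 protective and 10 harmful, each with
equal weight. Summing within a polarity yields two integer scores on
0–10 scales; no attempt is made to weight criteria by effect size, since
the instrument's purpose is communicable monitoring, not causal
estimation. The operational-helpline criterion is defined as a
refinement of the helpline-presence criterion, so P2 ≤ P1 is enforced as
an invariant on every coding pathway (automatic, ingested, reconciled).

Newspaper summaries use the arithmetic mean and the sample (n−1)
standard deviation over each newspaper's article scores; the SD is
reported as absent for groups of fewer than two articles. The pooled
"All newspapers" row is computed over all articles (article-weighted),
not as an unweighted mean of the per-newspaper means — with very uneven
article counts these differ materially, and the article-weighted form is
the one consistent with "average score across all reports". Frequency
percentages are 100·count/total rounded **half-up** to two decimals
(`decimal.Decimal`, not banker's rounding), matching how such tables are
conventionally printed.

## Screening

Rules apply in a fixed, documented order — period, language, keyword
prefilter, category exclusions, content relevance — and the first
failure is the recorded reason, which makes decisions reproducible and
the PRISMA accounting conservative (each article counted exactly once).

The source rubric does not operationalize "less than 50% of the
content"; this package's proxy is the fraction of body **sentences**
containing at least one suicide-case term, computed with a deterministic
punctuation-rule sentence splitter. Exactly one half is included;
strictly less is excluded. Reports carry a note stating this proxy.
Word- or column-space-based fractions were considered and rejected
because they are no better grounded and are harder to reproduce across
text extractions.

Category exclusions (commentary, ideation-only, bombing, undetermined
cause) are judgments the stated rules cannot fully automate, so a
per-article tag from a human screener always wins; when no tag is
present a narrow lexicon-cue fallback is applied and flagged
`heuristic` in the output.

## Detection rules

Matching is case-insensitive, token-boundary anchored and span-based, so
"suicidal" never matches the keyword "suicide" and every positive code
carries character-offset evidence. Overlapping evidence spans are
merged. Criterion-specific contracts:

- **Reject-list precedence** (P3, P4, P10): a reject-only match ("he was
  stressed", "drunk at the time", "according to sources") yields 0; an
  accept match wins only as a span distinct from any reject span.
- **Sentence co-occurrence** (P5, P7, P8): expert role + attribution
  verb, digit + statistics marker, myth marker + refutation must share a
  sentence; cross-sentence coincidences do not fire.
- **Cardinality** (N4): at least two *distinct* method-detail terms.
- **Negation by speculation** (N6): a single-factor assertion is
  cancelled by any speculation cue in the body; this is the one detector
  that is deliberately non-monotone under text extension.
- **Metadata criteria** (N7, N10): photographs and front-page placement
  are read from record metadata, never inferred from text.
- **N9** requires both a note term and quoted material in the body.
- **N2** fires on a headline containing the token "suicide", a method
  term, or a reason pattern (cue word + stressor noun, both in the
  headline). The cue/stressor lists are closed and editable; any
  headline reason-cue is treated as sufficient without matching it to
  the article's asserted cause.
- **P2** verifies P1 evidence against a local helpline-registry file by
  name or by digit-normalized phone number. No network access is ever
  attempted, keeping detection deterministic; the shipped registry is
  synthetic and must be replaced with a curated regional list in
  deployment.

The shipped lexicon is this package's own versioned vocabulary, seeded
from the worked phrases the rubric prints and expanded conservatively;
every report records the lexicon version so that score movements can be
attributed to vocabulary changes versus reporting changes.

## Reconciliation and agreement

Dual coding is reconciled criterion-by-criterion. `flag` withholds
disagreements for a consensus entry (scoring then fails loudly unless a
permissive flag accepts the stricter reading); `conservative` resolves
immediately toward the stricter reading — 0 for protective criteria, 1
for harmful ones — which biases scores against the newspaper and is
therefore safe for monitoring use. Percent agreement is reported next to
Cohen's kappa (computed via scikit-learn); kappa is reported as NA when
expected chance agreement is 1, where the statistic is undefined.

## Synthetic corpus generator

The generator exists to make every stage testable with known ground
truth. Per-criterion truths are independent Bernoulli draws at
configurable prevalences whose defaults are the per-criterion article
proportions observed in the poorly-adhering newsprint regime the package
models (helpline information ≈ 10.6%, mental-health linkage ≈ 21.7%,
official sourcing ≈ 82.3%, method mention ≈ 86.5%, criminalizing
language ≈ 65.2%, …), with the operational-helpline truth drawn
conditionally on helpline presence (default conditional probability 1,
matching the observed identical frequencies of the two criteria). By
linearity of expectation the generated corpus then has mean positive
score ≈ 1.32 and mean negative score ≈ 3.31 — the regime's headline
averages — and tests assert this identity within three binomial
standard errors.

Screening categories are planted from a mix whose included share
(≈ 0.57) follows the observed identified→included ratio; the per-reason
split of the remainder is this package's own choice, as no published
breakdown exists. Articles planted as "not matching the prefilter" are
rendered with trigger-free text and all-zero truth codes, since any
criterion trigger would contain the word "suicide" and defeat the
category. Bodies are composed from templates that use only
lexicon-listed trigger phrases for present criteria and curated
near-miss distractors (planted at rate 0.3) for absent ones; relevance
fractions are tuned to the planted category by appending case or
neutral filler sentences. Newspapers are assigned by configurable
weights (default: nine English-language titles, equal weights — real
readership weights are editorial data the package does not model).

What the generator does **not** emulate: correlated criteria (real
articles surely correlate method mention with method detail, for
instance — no correlation structure is published, and independence keeps
the null model analyzable), natural-language variation beyond the
template pool, regional idiom, and OCR/extraction noise. Passing
detector-recovery tests therefore demonstrates that the rule engine
implements the rubric faithfully on text whose vocabulary it knows —
not that it matches human judgment on arbitrary newsprint. For real
corpora the automatic coder should be treated as one coder in the
dual-coding protocol, not as ground truth.

## Numerical and interface choices

- All randomness flows from a single integer seed through one
  `random.Random` instance; generation is byte-reproducible.
- Dates are ISO-8601 calendar dates; the instrument works at
  daily-edition granularity.
- JSONL preserves absent optional fields as absent; in CSV an empty cell
  is read as absent (not as an empty string), and embedded newlines are
  escaped by the delimited writer. Unknown extra fields round-trip but
  are ignored by computation.
- Percentage deltas in period comparisons are differences of the rounded
  percentages, so printed deltas always reconcile with printed tables.
- Problem sizes in the test-suite and acceptance measurements (1,000–
  2,000 generated articles, 10,000 random codings) were chosen to make
  binomial sampling error small relative to the asserted tolerances.

## Known limitations

- Sensationalizing/glamourizing language is deliberately out of scope
  (subjective), as in the source instrument; so is detection inside
  images — photo criteria rely on metadata flags.
- The sentence-fraction relevance proxy and the closed cue lists for
  headline "reason" and category fallback are this package's
  operationalizations of judgments the rubric leaves to humans; both are
  stated in reports and easy to re-configure.
- The frequency table of the modelled regime contains one internally
  inconsistent printed row (site-disclosure count 228 of 1,318 printed
  as 17.05%); this package reports the arithmetically correct 17.30% for
  that count.
- English only; multilingual lexicons are a data problem the YAML format
  supports but this distribution does not attempt.
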