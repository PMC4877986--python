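# Methods

## The measurement protocol

The package measures the 14 items of the PLEACS checklist that can be
assessed from a plain language summary (PLS) alone:

| item | measured quantity | applicability |
|---|---|---|
| 1 | PLS title identical to the review title (reverse-scored) | all |
| 2 | word count within the recommended 400–700 range | all |
| 3 | discouraged jargon terms present (reverse) | all |
| 4 | structured (any headings) vs narrative | all |
| 5 | all five recommended subtitles present | structured only |
| 6 | number of recommended headings missing (0–5) | structured only |
| 7 | search date: month+year / year only / none | all |
| 8 | search-strategy details leaked (reverse) | all |
| 9 | population described | non-empty reviews |
| 10 | number of included studies stated | non-empty reviews |
| 11 | number of participants stated | non-empty reviews |
| 12 | statistical notation without lay explanation (reverse) | non-empty reviews |
| 13 | quality of evidence addressed | non-empty reviews |
| 14 | quality addressed via GRADE | non-empty reviews |

An *empty review* has no included studies; its PLS is not assessed on items
9–14. The empty flag is document metadata, never inferred from the text,
because review status is a property of the review, not of its summary. A
checklist consistency item (agreement between the PLS and the review's own
findings tables) is out of scope by construction: it cannot be measured from
the PLS alone.

## Extraction rules

All detectors are deterministic functions of the text plus two configuration
objects (`Lexicons`, `ExtractorSettings`). Conventions that matter:

- **Headings.** Corpora are plain text; a heading is a line starting with
  `"## "`. A fallback heuristic for unmarked text (short title-case line, no
  terminal period) exists behind `heading_fallback`. Recommended headings
  match case-insensitively with trailing colons stripped; "Review
  question(s)" and "Quality of the evidence" are accepted variants. Content
  detectors (items 3, 7–14) run on the body with heading lines removed — a
  "Quality of Evidence" section label is not a statement about evidence
  quality. Word counting keeps heading words and strips only the marker.
- **Titles (item 1).** Compared after case-folding, whitespace collapse and
  terminal-punctuation stripping, so cosmetic differences do not count as
  restating the title.
- **Jargon (item 3).** Whole-word, case-insensitive phrase matching with
  optional plural stemming (default on). The discouraged terms (outcome,
  literature, case series, efficacy, effect size) are scored; the second
  tier of terms whose everyday meaning differs in medicine (local, blinding,
  control, practice) is reported separately and excluded from scoring by
  default, since the checklist flags rather than forbids them
  (`count_ambiguous_jargon` includes them).
- **Search date (item 7).** A date only counts if it shares a sentence with
  a search cue (search/searched/current to/up to date); this prevents trial
  publication years from matching. Sentence boundaries use a `". "`/newline
  heuristic. Month names are matched in English and case-sensitively (the
  modal "may" is not a month). Month+year outranks year-only.
- **Strategy leaks (item 8).** Bibliographic database names (matched
  case-sensitively — CENTRAL is a register, "central" is a word), quoted
  boolean syntax (`'pain' AND 'child'`), MeSH, and explicit term lists
  following "search terms".
- **Counts (items 10–11).** Numerals (with thousands separators) or spelled
  numbers up to twenty, at most two words before a kind-specific noun
  (studies/trials/RCTs vs participants/patients/people/women/children).
  Bare year-like numbers are ignored. "We found no trials" counts as a
  stated count of zero (`zero_counts_as_stated`, default on): it conveys the
  number.
- **Unexplained statistics (item 12).** Pattern classes for OR/RR/HR/SMD/MD
  with a nearby digit, confidence intervals and p-values; acronyms are
  case-sensitive and digit-anchored so prose cannot match. A match is
  suppressed ("explained") when a lay-explanation cue (*this means*, *out of
  1000*, ...) occurs within `explanation_window` tokens after it. The
  window default (12 tokens) is our operationalization — the checklist gives
  none — and is a tunable.
- **Quality (items 13–14).** Phrase lexicon (quality/certainty of the
  evidence, risk of bias, low/moderate/high quality). GRADE matches only as
  a whole capitalized word; a GRADE mention implies quality is addressed.

## Scoring

The published description fixes the scheme's envelope — 14 items, reverse
set {1, 3, 8, 12}, maximum 19 points for a non-empty context and 13 for an
empty one, a two-tier search-date item and a five-level headings item — but
the exact point table lives in a supplementary file that is not available
here. The default `ScoringScheme` is therefore the *minimal* assignment
consistent with every stated constraint: one point per binary item, 2/1/0
for the search-date tiers, and one point per present recommended heading.
`verify_scheme` confirms the declared maxima/minima by exhaustively
enumerating item-value extremes (~20k combinations, < 1 s), and the scheme
is a serializable configuration object so the true table can be dropped in
if it becomes available.

Not-applicable items contribute zero against a *fixed* per-context
denominator (19 or 13): the source describes fixed per-context score ranges,
not per-document maxima. Adherence % = 100·points/maximum, banded
[0, 25], (25, 50], (50, 75], (75, 100] after half-up rounding to an integer
(the published text uses both "75–100 %" and "above 76 %"; we read that as
the (75, 100] convention on rounded percentages). Item 2 is binary in-range
credit; whether the original scheme gave under- and over-length texts
different credit is unknown (see limitations).

## Aggregation and trend

The item table uses four denominators: all documents (items 1–4, 7–8),
non-empty documents (9–14), structured documents (5), and structured
documents with at least one missing heading (6, reported as a histogram).
Percentages are computed from counts; displayed values are rounded to
integers, raw values are retained in machine output.

The trend analysis regresses per-document adherence % on a month index
(months since March 2013, when the current checklist version took effect),
because the association of interest is between publication time and
per-document adherence, not monthly means. Documents without a publication
month are excluded by default; mid-year imputation is opt-in. Pearson *r*
and the OLS slope use the same pairs; the slope's p-value is the two-sided
t-test of zero slope. Degenerate designs (fewer than 3 dated documents, or
no time variation) raise a structured error; zero-variance adherence is
reported with *r* flagged undefined rather than NaN-propagated.

## Synthetic corpus generator

Each document is assembled from parameterized sentence templates — one
positive and one negative realization family per detector — plus neutral
filler sentences used to pad the text to an exact word target. Every
template is vetted against every detector, so in clean mode extraction
recovers the generated labels exactly (a property the test suite asserts at
n = 500, and which holds for any seed by construction).

Defaults are the published corpus conditions: per-item adherence rates are
the reported adherence counts over their applicable denominators; the empty
fraction is 176/1738; word counts are lognormal with median 304 and log-sd
0.316 (derived from the reported mean/median ratio 319/304), truncated to
the reported range 46–1125; the window spans 23 months. Review-group
heterogeneity defaults to eight groups with adherence offsets of ±1–12
percentage points, a smaller-scale echo of the reported 43–81 % group range;
the offsets are spread across the one-point binary items in independent
mode.

Two drawing modes:

- **Independent** (default): each item value is a Bernoulli/categorical draw
  at its configured rate. Useful for rate-recovery and denominator checks.
- **Target** (active when a trend slope or noise sd is set): each document
  draws a target adherence % = base + slope·month + N(0, sd), and a
  randomized greedy allocator picks item values whose score equals the
  rounded target (every integer total is reachable; the GRADE⇒quality
  constraint is respected). This is the only way to inject a chosen residual
  sd while keeping labels exactly faithful to the text; quantization to the
  19-point grid adds ≈1.5 % sd, which the OLS absorbs.

Noisy mode swaps in paraphrase variants for a small fraction of positive
realizations of items 7, 9, 10 and 13 (5–8 %) that the detectors are
designed to miss, to measure robustness; labels always record the truth, so
measured agreement is a property of the detectors, not of the labels.

What the generator does *not* emulate: real Cochrane prose (lexical variety,
discourse structure, typos), correlations between items beyond those induced
by targeting, non-English text, and semantic paraphrase. Passing tests
therefore show that the pipeline is correct and robust to the programmed
paraphrase families — not that the detectors would reach the same agreement
on real summaries, where human-level paraphrase detection is out of scope by
design.

## Problem sizes used in the test suite

Extraction-recovery and oracle-equivalence checks run on 500-document
corpora; rate recovery and word statistics on 1000; trend recovery on 100
replicates of 1000 documents over the 23-month window (slope 0.5 %/month,
residual sd 10); the score-invariant property suite on 10,000 randomized
assessments. These sizes give 3-sigma binomial resolution on every rate
while keeping the whole suite under a minute of compute.

## Known limitations

- The default point table is a reconstruction. With it, the expected score
  implied by the published per-item marginal rates is ≈8.5/19 (45 %),
  whereas the published mean score is 11/19 (57 %). Since expectation is
  linear, no correlation structure can reconcile the two: the original
  supplementary point table must distribute points differently. Corpus-level
  means therefore depend on the scheme configuration; the per-item table,
  the applicability logic, the maxima (19/13) and the trend machinery do
  not.
- Detectors are English-only and convention-bound (heading markers, sentence
  heuristics); they measure *reporting*, not correctness of content.
- The band edge between "51–75" and "76–100" follows the (75, 100]
  convention; sources using 76 as a lower bound on unrounded percentages
  would classify a 75.4 % document differently.
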