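# pleacs

Measurement of how well plain language summaries (PLSs) of systematic
reviews adhere to the PLEACS reporting checklist (*Standards for the
reporting of Plain Language Summaries in new Cochrane Intervention
Reviews*).

A PLS is the consumer-facing summary of a systematic review. PLEACS asks it
to restate the title in plain language, stay near 400 (at most 700) words,
avoid jargon, use a recommended heading structure, state the search date,
omit search-strategy details, and describe the population, the numbers of
studies and participants, statistical results in lay terms, and the quality
of the evidence (ideally via GRADE). This package implements the measurable
part of that checklist as an automated pipeline for meta-researchers who
study reporting quality:

- **`pleacs.extraction`** — deterministic rule-based detectors for the 14
  measurable items (lexicon matching, heading normalization, date/count
  pattern rules), fully configurable via `Lexicons` and `ExtractorSettings`.
- **`pleacs.scoring`** — the point-based adherence score. For a summary of
  a review with included studies the score *S* is

  `S = Σᵢ pᵢ(xᵢ) ∈ [0, 19]`,  adherence % = `100 · S / 19`

  with one point per binary item, a tiered search-date item (month+year = 2,
  year only = 1), one point per recommended heading present (5 − missing),
  and items 1, 3, 8, 12 scored in reverse (the point is earned when the
  element — identical title, jargon, strategy details, unexplained
  statistics — is *absent*). For an *empty* review (no included studies)
  items 9–14 do not apply and the maximum is 13. Adherence percentages are
  banded 0–25 / 26–50 / 51–75 / 76–100.
- **`pleacs.report`** — the corpus-level item-adherence table with its four
  applicability denominators, band distributions, per-group summaries, word
  statistics, and the adherence-over-time analysis (Pearson *r* plus OLS
  slope of adherence % on months since the checklist took effect, with a
  two-sided test of zero slope).
- **`pleacs.synthetic`** — a labeled corpus generator whose defaults emulate
  the published corpus conditions (per-item adherence rates, ~10 % empty
  reviews, lognormal word counts with median 304, a 23-month window), with
  controllable group heterogeneity, an injectable temporal trend, and a
  noisy mode for measuring detector robustness.
- **`pleacs.corpus`** — JSON-lines corpus/label I/O and validation.
- **`pleacs` CLI** — `generate`, `assess`, `report`, `verify-scheme`.

## Worked example

```python
from pleacs import GeneratorConfig, generate, assess, score, build_report

docs, labels = generate(GeneratorConfig(n_docs=200, seed=1))
assessments = [assess(d) for d in docs]
results = [score(a) for a in assessments]
report = build_report(docs, assessments, results)

print(report.n_total, report.n_empty, report.n_structured)
print(f"mean adherence {report.mean_adherence_pct:.1f} %")
print(results[0])
```

prints

```
200 19 84
mean adherence 44.8 %
doc_id='PLS-00001' points=4 max_points=19 percentage=21.05263157894737 band='0-25'
```

200 generated summaries of which 19 are empty reviews and 84 are structured;
the first document earns 4 of 19 points (21 % adherence, lowest band).
`report.render_text()` prints the item table; the row for item 1, for
example,

```
   1  adhering                  127    200   64
```

says 127 of all 200 summaries (64 %) restated the review title in plain
language. Items 9–14 use the 181 non-empty summaries as denominator, item 5
the 84 structured ones, and item 6 the 53 structured-but-nonconforming ones,
mirroring the applicability rules.

The same pipeline from the shell:

```sh
pleacs generate --n 200 --seed 1 --out out/
pleacs assess --corpus out/corpus.jsonl --out out/
pleacs report --corpus out/corpus.jsonl --render-text --out out/
```

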