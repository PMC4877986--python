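"""Labeled synthetic PLS corpora with controlled per-item ground truth.

The generator assembles each summary from parameterized sentence templates,
one realization per drawn item value (headings kept or dropped, jargon terms
injected or withheld, search-date phrases by tier, study/participant count
sentences, statistics with or without a lay explanation, quality/GRADE
statements).  The drawn values are emitted as ground-truth labels, so the
extractor, the scorer and the trend analysis can all be validated without any
real review data.

Default parameters emulate the published corpus conditions: per-item
adherence rates taken from the reported adherence counts over their
applicable denominators, a ~10 % empty-review fraction, a lognormal word-count
distribution matched to the reported mean/median/range, and a 23-month
publication window.

Two drawing modes exist:

* **independent** (the default): every item value is drawn independently at
  its configured rate; group membership shifts the Bernoulli rates slightly.
* **target** (active when a trend slope or noise sd is configured): each
  document draws a target adherence percentage — base + slope x month +
  Gaussian noise — and item values are then chosen so the resulting score
  matches the rounded target.  This is what makes an injected temporal trend
  (with a chosen residual sd) exactly recoverable while keeping the labels
  faithful to the text.

In ``noisy`` mode a small fraction of positive realizations use paraphrases
that the detectors are known to miss, to measure extraction robustness; the
labels always record the truth.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .assessment import GroundTruthLabels, ItemAssessment, SearchDateTier
from .corpus import HEADING_MARKER, PlsDocument, TREND_ORIGIN
from .errors import ValidationError
from .scoring import AdherenceResult, band_for_percentage

__all__ = [
    "ItemRates",
    "WordCountSpec",
    "GroupSpec",
    "TrendSpec",
    "GeneratorConfig",
    "generate",
    "make_fixture",
    "FIXTURE_NAMES",
]


# --------------------------------------------------------------------------
# configuration


class ItemRates(BaseModel):
    """Per-item adherence probabilities (independent mode).

    Defaults are the published per-item adherence fractions over their
    applicable denominators.
    """

    model_config = ConfigDict(frozen=True)

    title_restated: float = Field(default=1105 / 1738, ge=0, le=1)
    jargon_absent: float = Field(default=748 / 1738, ge=0, le=1)
    structured: float = Field(default=626 / 1738, ge=0, le=1)
    structured_conforming: float = Field(default=217 / 626, ge=0, le=1)
    #: Histogram weights for 1-5 missing headings among nonconforming PLSs.
    missing_weights: tuple[float, ...] = (141, 90, 47, 40, 94)
    search_month_year: float = Field(default=992 / 1738, ge=0, le=1)
    search_year_only: float = Field(default=20 / 1738, ge=0, le=1)
    strategy_absent: float = Field(default=1718 / 1738, ge=0, le=1)
    population: float = Field(default=236 / 1562, ge=0, le=1)
    studies_stated: float = Field(default=1429 / 1562, ge=0, le=1)
    participants_stated: float = Field(default=1201 / 1562, ge=0, le=1)
    stats_absent: float = Field(default=1527 / 1562, ge=0, le=1)
    quality_addressed: float = Field(default=875 / 1562, ge=0, le=1)
    grade_mentioned: float = Field(default=11 / 1562, ge=0, le=1)
    #: Second-tier ambiguous terms are injected at this rate (off by default;
    #: they are reported, not scored).
    ambiguous_present: float = Field(default=0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "ItemRates":
        if self.search_month_year + self.search_year_only > 1:
            raise ValueError("search-date tier probabilities exceed 1")
        if len(self.missing_weights) != 5 or sum(self.missing_weights) <= 0:
            raise ValueError("missing_weights must be 5 non-negative weights")
        return self


class WordCountSpec(BaseModel):
    """Lognormal word-count model matched to the reported summary lengths."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(default=304.0, gt=0)
    #: log-sd; the default reproduces the reported mean/median ratio 319/304.
    sigma: float = Field(default=math.sqrt(2 * math.log(319.0 / 304.0)), ge=0)
    min: int = Field(default=46, ge=1)
    max: int = Field(default=1125, ge=1)
    recommended: tuple[int, int] = (400, 700)

    @model_validator(mode="after")
    def _check(self) -> "WordCountSpec":
        if self.min > self.max:
            raise ValueError("word-count min exceeds max")
        if self.sigma == 0 and not (self.min <= self.median <= self.max):
            raise ValueError("degenerate word-count spec cannot satisfy its bounds")
        return self


class GroupSpec(BaseModel):
    """A review group with an adherence offset (percentage points)."""

    model_config = ConfigDict(frozen=True)

    label: str
    offset_pct: float = 0.0


_DEFAULT_GROUPS = tuple(
    GroupSpec(label=f"Group {c}", offset_pct=o)
    for c, o in zip("ABCDEFGH", (-12, -8, -4, -1, 1, 4, 8, 12))
)


class TrendSpec(BaseModel):
    """Temporal adherence trend over the publication window."""

    model_config = ConfigDict(frozen=True)

    slope_pct_per_month: float = 0.0
    #: Residual sd of per-document adherence % around the trend line
    #: (activates target mode).
    noise_sd_pct: Optional[float] = Field(default=None, ge=0)
    base_pct: float = Field(default=57.0, ge=0, le=100)
    n_months: int = Field(default=23, ge=1)


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_docs: int = Field(ge=1)
    seed: int = 0
    empty_fraction: float = Field(default=176 / 1738, ge=0, le=1)
    rates: ItemRates = ItemRates()
    words: WordCountSpec = WordCountSpec()
    groups: tuple[GroupSpec, ...] = _DEFAULT_GROUPS
    trend: TrendSpec = TrendSpec()
    noise_mode: str = Field(default="clean", pattern="^(clean|noisy)$")

    @property
    def target_mode(self) -> bool:
        return (
            self.trend.slope_pct_per_month != 0 or self.trend.noise_sd_pct is not None
        )


# --------------------------------------------------------------------------
# sentence templates
#
# Every sentence is vetted against all detectors: fillers contain no lexicon
# terms, no digits adjacent to count nouns, no population noun+qualifier
# pairs, no date-with-cue sentences, no statistical notation and no quality
# phrases, so a negative item stays negative no matter how sentences combine.

_INTERVENTIONS = (
    "Antibiotics",
    "Exercise programmes",
    "Corticosteroid injections",
    "Vitamin D supplements",
    "Acupuncture",
    "Cognitive behavioural therapy",
    "Inhaled bronchodilators",
    "Massage therapy",
    "Probiotics",
    "Nicotine replacement therapy",
)
_CONDITIONS = (
    "sore throat",
    "chronic low back pain",
    "knee osteoarthritis",
    "seasonal influenza",
    "migraine",
    "asthma",
    "depression",
    "eczema",
    "insomnia",
    "high blood pressure",
)

_FILLERS = (
    "This summary is written for a general audience.",
    "The review authors collected and analysed all relevant evidence.",
    "More research on this question may change these findings.",
    "The findings below reflect the evidence available at the time.",
    "We summarise here what the review found.",
    "Readers should discuss treatment choices with a clinician.",
    "Health decisions benefit from clear and balanced information.",
    "The review followed standard systematic methods throughout.",
    "Further details are available in the full review.",
)

_EXACT_CANDIDATES = (
    "Indeed.",
    "In short.",
    "Here is more.",
    "This is a summary.",
    "The findings are described here.",
    "This summary describes the review findings.",
    "The full review gives much more detail.",
    "Readers can consult the full review for detail.",
    "The full review text provides further detail for readers.",
    "Readers who want more information can consult the full review.",
    "Readers who want further information can consult the full review text.",
    "Readers who would like more information are encouraged to read the review.",
)
_EXACT_BY_LEN = {len(s.split()): s for s in _EXACT_CANDIDATES}
if set(_EXACT_BY_LEN) != set(range(1, 13)):  # pragma: no cover - template bug guard
    raise AssertionError("exact-length filler sentences must cover lengths 1-12")

_JARGON_SENTENCES = {
    "outcome": "The main outcome was relief of symptoms.",
    "literature": "We reviewed the published literature on this topic.",
    "case series": "One case series was also identified.",
    "efficacy": "The efficacy of the treatment varied across the research.",
    "effect size": "The overall effect size was judged to be small.",
}
_AMBIGUOUS_SENTENCES = {
    "local": "Studies of local treatment approaches were considered.",
    "blinding": "Blinding was not possible in most of the research.",
    "control": "Each trial compared the treatment with a control.",
    "practice": "These findings may influence everyday clinical practice.",
}

_MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
)

_EXTRA_HEADINGS = ("Overview", "What we did", "Findings", "Conclusions")

_DB_POOL = ("MEDLINE", "EMBASE", "CINAHL", "PsycINFO", "CENTRAL")

_POPULATION_PHRASES = (
    "adults older than 65 years",
    "children aged 5 to 12 years",
    "women",
    "men",
    "patients",
)

_QUALITY_ADJECTIVES = ("low", "moderate", "high", "very low")

# noisy-mode miss probabilities for positive realizations the detectors are
# designed not to catch (robustness measurement, not a tunable-to-pass knob)
_MISS_P = {"item7": 0.05, "item9": 0.08, "item10": 0.05, "item13": 0.05}


def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


# --------------------------------------------------------------------------
# value drawing


def _draw_independent(
    empty: bool, group: GroupSpec, config: GeneratorConfig, rng: np.random.Generator
) -> dict:
    r = config.rates
    # an offset of +x adherence-% is spread over the eight shiftable binary
    # items: x% of 19 points across 8 one-point items -> 19x/800 probability
    delta = group.offset_pct * 19.0 / 800.0

    def shifted(p: float) -> float:
        return float(np.clip(p + delta, 0.0, 1.0))

    def bern(p: float) -> bool:
        return bool(rng.random() < p)

    vals: dict = {"wc_mode": "free"}
    vals["title_same"] = not bern(shifted(r.title_restated))
    vals["jargon_present"] = not bern(shifted(r.jargon_absent))
    vals["ambiguous_present"] = bern(r.ambiguous_present)
    structured = bern(r.structured)
    vals["structured"] = structured
    if structured:
        if bern(r.structured_conforming):
            vals["missing"] = 0
        else:
            w = np.asarray(r.missing_weights, dtype=float)
            vals["missing"] = 1 + int(rng.choice(5, p=w / w.sum()))
    else:
        vals["missing"] = None
    u = rng.random()
    if u < r.search_month_year:
        vals["tier"] = SearchDateTier.MONTH_AND_YEAR
    elif u < r.search_month_year + r.search_year_only:
        vals["tier"] = SearchDateTier.YEAR_ONLY
    else:
        vals["tier"] = SearchDateTier.NONE
    vals["leak_present"] = not bern(shifted(r.strategy_absent))
    if not empty:
        vals["population"] = bern(shifted(r.population))
        vals["studies"] = bern(shifted(r.studies_stated))
        vals["participants"] = bern(shifted(r.participants_stated))
        vals["stats_present"] = not bern(shifted(r.stats_absent))
        grade = bern(r.grade_mentioned)
        if grade:
            quality = True
        else:
            residual = (r.quality_addressed - r.grade_mentioned) / max(
                1.0 - r.grade_mentioned, 1e-9
            )
            quality = bern(shifted(float(np.clip(residual, 0, 1))))
        vals["quality"] = quality
        vals["grade"] = grade
    return vals


_NONEMPTY_BINARIES = (1, 2, 3, 8, 9, 10, 11, 12, 13, 14)
_EMPTY_BINARIES = (1, 2, 3, 8)


def _realize_points(
    points: int, empty: bool, rng: np.random.Generator
) -> dict:
    """Choose item values whose default-scheme score equals ``points``.

    Randomized greedy allocation over point-carrying slots: ten (four, when
    empty) one-point binary items, the two-point search-date tier, and the
    structure block (item 4 + one point per recommended heading, with the
    fifth heading also granting the subtitles point).  Item 14 stays blocked
    until item 13 is chosen, preserving the GRADE-implies-quality invariant.
    """
    binaries = _EMPTY_BINARIES if empty else _NONEMPTY_BINARIES
    maxp = 13 if empty else 19
    if not 0 <= points <= maxp:
        raise ValidationError(f"target points {points} outside [0, {maxp}]")
    bset: set[int] = set()
    tier = 0
    item4 = False
    headings = 0
    remaining = points
    while remaining > 0:
        moves: list[tuple] = []
        for b in binaries:
            if b in bset:
                continue
            if b == 14 and 13 not in bset:
                continue
            moves.append(("b", b, 1))
        if tier < 2:
            moves.append(("tier", None, 1))
        if not item4:
            moves.append(("i4", None, 1))
        elif headings < 5:
            cost = 2 if headings == 4 else 1
            if cost <= remaining:
                moves.append(("head", None, cost))
        moves = [m for m in moves if m[2] <= remaining]
        if not moves:
            # only reachable state: one point left, everything full except the
            # fifth heading (which costs 2) — swap a binary for it
            if remaining == 1 and item4 and headings == 4 and bset:
                # keep quality (13) whenever GRADE (14) is set
                removable = sorted(b for b in bset if b != 13 or 14 not in bset)
                bset.remove(_choice(rng, removable))
                headings = 5
                remaining -= 1
                continue
            raise ValidationError("unreachable point target")  # pragma: no cover
        kind, arg, cost = moves[int(rng.integers(len(moves)))]
        if kind == "b":
            bset.add(arg)
        elif kind == "tier":
            tier += 1
        elif kind == "i4":
            item4 = True
        else:  # "head": the fifth heading carries the subtitles point (cost 2)
            headings += 1
        remaining -= cost
    vals: dict = {
        "title_same": 1 not in bset,
        "wc_mode": "in" if 2 in bset else "out",
        "jargon_present": 3 not in bset,
        "ambiguous_present": False,
        "structured": item4,
        "missing": (5 - headings) if item4 else None,
        "tier": (
            SearchDateTier.MONTH_AND_YEAR
            if tier == 2
            else SearchDateTier.YEAR_ONLY if tier == 1 else SearchDateTier.NONE
        ),
        "leak_present": 8 not in bset,
    }
    if not empty:
        vals.update(
            population=9 in bset,
            studies=10 in bset,
            participants=11 in bset,
            stats_present=12 not in bset,
            quality=13 in bset,
            grade=14 in bset,
        )
    return vals


# --------------------------------------------------------------------------
# word-count targets


def _draw_word_target(mode: str, words: WordCountSpec, rng: np.random.Generator) -> int:
    lo, hi = words.recommended
    if mode == "in":
        return int(rng.integers(lo + 6, hi - 5))
    mu = math.log(words.median)
    if mode == "free":
        draw = math.exp(rng.normal(mu, words.sigma)) if words.sigma else words.median
        return int(np.clip(round(draw), words.min, words.max))
    # mode == "out": mostly below the recommended range, occasionally above
    over_p = 8 / 1334  # reported split of out-of-range summaries
    if words.max > hi + 6 and rng.random() < over_p:
        return int(rng.integers(hi + 6, words.max + 1))
    for _ in range(100):
        draw = math.exp(rng.normal(mu, words.sigma)) if words.sigma else words.median
        val = int(np.clip(round(draw), words.min, words.max))
        if val <= lo - 6:
            return val
    return int(rng.integers(words.min, lo - 5))


# --------------------------------------------------------------------------
# document realization


def _month_year(m_idx: int) -> tuple[int, int]:
    oy, om = TREND_ORIGIN
    total = (om - 1) + m_idx
    return oy + total // 12, total % 12 + 1


def _search_sentences(
    vals: dict, pub_year: int, pub_month: int, noisy: bool, rng: np.random.Generator
) -> list[str]:
    month_name = _MONTH_NAMES[pub_month - 1]
    tier = vals["tier"]
    if tier is SearchDateTier.MONTH_AND_YEAR:
        if noisy and rng.random() < _MISS_P["item7"]:
            # no search cue near the date — a deliberate detector miss
            return [f"Evidence was gathered until {month_name} {pub_year}."]
        options = (
            f"The evidence is current to {month_name} {pub_year}.",
            f"We searched for studies up to {month_name} {pub_year}.",
            f"Databases were searched in {month_name} {pub_year}.",
        )
        return [_choice(rng, options)]
    if tier is SearchDateTier.YEAR_ONLY:
        return [f"We searched for relevant evidence in {pub_year}."]
    if rng.random() < 0.5:
        return ["We searched widely for evidence on this question."]
    return []


def _build_document(
    i: int,
    vals: dict,
    empty: bool,
    group: GroupSpec,
    m_idx: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[PlsDocument, GroundTruthLabels]:
    noisy = config.noise_mode == "noisy"
    pub_year, pub_month = _month_year(m_idx)
    intervention = _choice(rng, _INTERVENTIONS)
    condition = _choice(rng, _CONDITIONS)
    review_title = f"{intervention} for {condition}"
    if vals["title_same"]:
        pls_title = review_title
        if noisy and rng.random() < 0.3:
            pls_title = review_title.lower() + "."
    else:
        pls_title = _choice(
            rng,
            (
                f"Can {intervention.lower()} help with {condition}?",
                f"What are the benefits and harms of {intervention.lower()} for {condition}?",
            ),
        )

    question = [f"We reviewed the evidence on {intervention.lower()} for {condition}."]
    background = [
        f"{condition.capitalize()} is a common health problem.",
        "Better information about treatment choices is needed.",
    ]

    characteristics: list[str] = []
    characteristics += _search_sentences(vals, pub_year, pub_month, noisy, rng)
    leak_labels: tuple[str, ...] = ()
    if vals["leak_present"]:
        kind = rng.random()
        if kind < 0.6:
            k = 1 + int(rng.integers(2))
            dbs = list(rng.choice(len(_DB_POOL), size=k, replace=False))
            names = [_DB_POOL[int(j)] for j in sorted(dbs)]
            if len(names) == 2:
                characteristics.append(
                    f"We searched {names[0]} and {names[1]} for relevant evidence."
                )
            else:
                characteristics.append(f"We searched {names[0]} for relevant evidence.")
            leak_labels = tuple(names)
        elif kind < 0.85:
            characteristics.append("The search used the terms 'pain' AND 'relief'.")
            leak_labels = ("boolean-syntax",)
        else:
            characteristics.append(
                "Medical Subject Headings (MeSH) were used in the search."
            )
            leak_labels = ("MeSH",)

    if empty:
        characteristics.append("The review found no studies for inclusion.")
        key_results = ["No evidence was available to answer the question."]
        quality_sec = ["The evidence base could not be assessed."]
    else:
        if vals["population"]:
            if noisy and rng.random() < _MISS_P["item9"]:
                # no population cue noun — a deliberate detector miss
                characteristics.append(
                    f"The review focused on elderly individuals living with {condition}."
                )
            else:
                pop = _choice(rng, _POPULATION_PHRASES)
                characteristics.append(f"The review focused on {pop} with {condition}.")
        if vals["studies"]:
            if noisy and rng.random() < _MISS_P["item10"]:
                # no numeral — a deliberate detector miss
                characteristics.append(
                    "The evidence base comprised a handful of studies."
                )
            elif rng.random() < 0.05 and not vals["participants"]:
                characteristics.append(
                    "We found no trials that answered the review question."
                )
            else:
                n = int(rng.integers(2, 150))
                if noisy and n <= 20 and rng.random() < 0.3:
                    spelled = (
                        "two three four five six seven eight nine ten eleven twelve "
                        "thirteen fourteen fifteen sixteen seventeen eighteen nineteen twenty"
                    ).split()[n - 2]
                    characteristics.append(f"We included {spelled} studies in this review.")
                else:
                    characteristics.append(f"We included {n} studies in this review.")
        if vals["participants"]:
            m = int(rng.integers(50, 20000))
            characteristics.append(
                _choice(
                    rng,
                    (
                        f"Altogether the included studies involved {m:,} participants.",
                        f"In total {m:,} patients took part in the research.",
                    ),
                )
            )

        key_results = ["The results suggested some benefit from the treatment."]
        stats_labels: tuple[str, ...] = ()
        if vals["stats_present"]:
            stat_kind = rng.random()
            if stat_kind < 0.35:
                key_results.append(
                    "Pain scores fell with treatment (SMD -0.41, 95% CI -0.62 to -0.21)."
                )
                stats_labels = ("smd", "confidence-interval")
            elif stat_kind < 0.7:
                key_results.append("The risk ratio was 0.80 (95% CI 0.65 to 0.98).")
                stats_labels = ("risk-ratio", "confidence-interval")
            elif stat_kind < 0.85:
                key_results.append("The odds ratio for improvement was 1.45.")
                stats_labels = ("odds-ratio",)
            else:
                key_results.append("Symptoms improved more with treatment (p = 0.003).")
                stats_labels = ("p-value",)
        elif rng.random() < 0.3:
            key_results.append(
                "The risk ratio was 0.80; this means slightly fewer people had symptoms."
            )

        quality_sec = []
        if vals["grade"]:
            quality_sec.append(
                "We assessed the quality of the evidence using the GRADE approach."
            )
        elif vals["quality"]:
            if noisy and rng.random() < _MISS_P["item13"]:
                # paraphrase without a quality phrase — a deliberate miss
                quality_sec.append("The included studies were generally well conducted.")
            else:
                adj = _choice(rng, _QUALITY_ADJECTIVES)
                quality_sec.append(
                    _choice(
                        rng,
                        (
                            f"The quality of the evidence was {adj}.",
                            "We judged the risk of bias to be low across the included research.",
                        ),
                    )
                )
        else:
            quality_sec.append("The review considered how dependable the research was.")

    jargon_labels: tuple[str, ...] = ()
    if vals["jargon_present"]:
        terms = sorted(_JARGON_SENTENCES)
        k = 1 + int(rng.integers(3))
        picked = sorted(
            terms[int(j)] for j in rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        )
        key_results += [_JARGON_SENTENCES[t] for t in picked]
        jargon_labels = tuple(picked)
    ambiguous_labels: tuple[str, ...] = ()
    if vals.get("ambiguous_present"):
        term = _choice(rng, sorted(_AMBIGUOUS_SENTENCES))
        key_results.append(_AMBIGUOUS_SENTENCES[term])
        ambiguous_labels = (term,)

    sections = [
        ("Review Question", question),
        ("Background", background),
        ("Study Characteristics", characteristics),
        ("Key Results", key_results),
        ("Quality of Evidence", quality_sec),
    ]

    structured = vals["structured"]
    lines: list[str] = []
    if structured:
        missing = vals["missing"]
        present_idx = sorted(
            int(j) for j in rng.choice(5, size=5 - missing, replace=False)
        )
        for idx, (name, sents) in enumerate(sections):
            if idx in present_idx:
                shown = name
                if noisy:
                    u = rng.random()
                    if u < 0.2:
                        shown = name + ":"
                    elif u < 0.3:
                        shown = name.lower()
                    elif u < 0.4 and name == "Review Question":
                        shown = "Review question"
                    elif u < 0.4 and name == "Quality of Evidence":
                        shown = "Quality of the evidence"
                lines.append(HEADING_MARKER + shown)
            if sents:
                lines.append(" ".join(sents))
        if missing == 5:
            # structured but entirely off-standard: non-recommended headings
            lines.insert(0, HEADING_MARKER + _choice(rng, _EXTRA_HEADINGS))
    else:
        for _, sents in sections:
            if sents:
                lines.append(" ".join(sents))

    body = "\n".join(lines)
    core = len(
        "\n".join(
            ln[len(HEADING_MARKER):] if ln.startswith(HEADING_MARKER) else ln
            for ln in body.splitlines()
        ).split()
    )
    target = _draw_word_target(vals["wc_mode"], config.words, rng)
    pad: list[str] = []
    remaining = target - core
    while remaining > 12:
        s = _FILLERS[int(rng.integers(len(_FILLERS)))]
        pad.append(s)
        remaining -= len(s.split())
    if remaining > 0:
        pad.append(_EXACT_BY_LEN[remaining])
    if pad:
        lines.append(" ".join(pad))
        body = "\n".join(lines)

    word_count = core + max(target - core, 0)

    doc = PlsDocument(
        doc_id=f"PLS-{i + 1:05d}",
        review_title=review_title,
        pls_title=pls_title,
        body=body,
        pub_year=pub_year,
        pub_month=pub_month,
        review_group=group.label,
        is_empty_review=empty,
    )
    label_kwargs: dict = dict(
        doc_id=doc.doc_id,
        is_empty_review=empty,
        item1_title_same=vals["title_same"],
        item2_word_count=word_count,
        item3_jargon_terms_found=jargon_labels,
        item3_ambiguous_terms_found=ambiguous_labels,
        item4_structured=structured,
        item5_subtitles_recommended=(vals["missing"] == 0) if structured else None,
        item6_missing_headings=vals["missing"] if structured else None,
        item7_search_date=vals["tier"],
        item8_strategy_details_found=leak_labels,
    )
    if not empty:
        label_kwargs.update(
            item9_population_details=vals["population"],
            item10_n_studies_stated=vals["studies"],
            item11_n_participants_stated=vals["participants"],
            item12_unexplained_stats_found=stats_labels if vals["stats_present"] else (),
            item13_quality_addressed=vals["quality"],
            item14_grade_mentioned=vals["grade"],
        )
    return doc, GroundTruthLabels(**label_kwargs)


def generate(
    config: GeneratorConfig,
) -> tuple[list[PlsDocument], list[GroundTruthLabels]]:
    """Generate a labeled corpus; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    t = config.trend
    docs: list[PlsDocument] = []
    labels: list[GroundTruthLabels] = []
    for i in range(config.n_docs):
        group = config.groups[int(rng.integers(len(config.groups)))]
        m_idx = int(rng.integers(t.n_months))
        empty = bool(rng.random() < config.empty_fraction)
        if config.target_mode:
            maxp = 13 if empty else 19
            target = (
                t.base_pct
                + group.offset_pct
                + t.slope_pct_per_month * m_idx
                + (rng.normal(0.0, t.noise_sd_pct) if t.noise_sd_pct else 0.0)
            )
            points = int(np.clip(round(target / 100.0 * maxp), 0, maxp))
            vals = _realize_points(points, empty, rng)
        else:
            vals = _draw_independent(empty, group, config, rng)
        doc, label = _build_document(i, vals, empty, group, m_idx, config, rng)
        docs.append(doc)
        labels.append(label)
    return docs, labels


# --------------------------------------------------------------------------
# hand-authored edge-case fixtures


def _fixture_minimal() -> tuple[PlsDocument, ItemAssessment, AdherenceResult]:
    # A three-sentence, 46-word narrative summary — the shortest realistic
    # extreme — with an identical title and almost nothing reported.
    body = (
        "We wanted to learn whether antibiotics shorten sore throat in adults and children. "
        "We included two trials with a small number of people overall. "
        "The evidence was not strong enough for us to draw firm conclusions about "
        "whether these medicines help or harm in usual care."
    )
    doc = PlsDocument(
        doc_id="fixture-minimal",
        review_title="Antibiotics for sore throat",
        pls_title="Antibiotics for sore throat",
        body=body,
        pub_year=2013,
        pub_month=5,
        review_group="Group A",
        is_empty_review=False,
    )
    assessment = ItemAssessment(
        doc_id=doc.doc_id,
        is_empty_review=False,
        item1_title_same=True,
        item2_word_count=46,
        item4_structured=False,
        item7_search_date=SearchDateTier.NONE,
        item9_population_details=False,
        item10_n_studies_stated=True,
        item11_n_participants_stated=False,
        item12_unexplained_stats_found=(),
        item13_quality_addressed=False,
        item14_grade_mentioned=False,
    )
    result = AdherenceResult(
        doc_id=doc.doc_id,
        points=4,
        max_points=19,
        percentage=100.0 * 4 / 19,
        band="0-25",
    )
    return doc, assessment, result


def _fixture_empty() -> tuple[PlsDocument, ItemAssessment, AdherenceResult]:
    body = "\n".join(
        [
            "## Review Question",
            "We reviewed the evidence on antibiotics for sore throat.",
            "## Background",
            "Sore throat is a common health problem.",
            "## Study Characteristics",
            "We searched for studies up to June 2014. The review found no studies for inclusion.",
            "## Key Results",
            "No evidence was available to answer the question.",
            "## Quality of Evidence",
            "The evidence base could not be assessed.",
        ]
    )
    doc = PlsDocument(
        doc_id="fixture-empty",
        review_title="Antibiotics for sore throat",
        pls_title="Can antibiotics help with sore throat?",
        body=body,
        pub_year=2014,
        pub_month=7,
        review_group="Group B",
        is_empty_review=True,
    )
    assessment = ItemAssessment(
        doc_id=doc.doc_id,
        is_empty_review=True,
        item1_title_same=False,
        item2_word_count=56,
        item4_structured=True,
        item5_subtitles_recommended=True,
        item6_missing_headings=0,
        item7_search_date=SearchDateTier.MONTH_AND_YEAR,
    )
    pct = 100.0 * 12 / 13
    result = AdherenceResult(
        doc_id=doc.doc_id,
        points=12,
        max_points=13,
        percentage=pct,
        band=band_for_percentage(pct),
    )
    return doc, assessment, result


def _fixture_heading_variants() -> tuple[PlsDocument, ItemAssessment, AdherenceResult]:
    body = "\n".join(
        [
            "## Review question:",
            "We reviewed the evidence on exercise programmes for chronic low back pain.",
            "## BACKGROUND",
            "Chronic low back pain is a common health problem.",
            "## Study characteristics:",
            "We included 12 studies involving 2,317 participants.",
            "## Key results",
            "The results suggested some benefit from the treatment.",
            "## Quality of the evidence",
            "The quality of the evidence was moderate.",
        ]
    )
    doc = PlsDocument(
        doc_id="fixture-headings",
        review_title="Exercise programmes for chronic low back pain",
        pls_title="Can exercise programmes help with chronic low back pain?",
        body=body,
        pub_year=2014,
        pub_month=1,
        review_group="Group C",
        is_empty_review=False,
    )
    assessment = ItemAssessment(
        doc_id=doc.doc_id,
        is_empty_review=False,
        item1_title_same=False,
        item2_word_count=54,
        item4_structured=True,
        item5_subtitles_recommended=True,
        item6_missing_headings=0,
        item7_search_date=SearchDateTier.NONE,
        item9_population_details=False,
        item10_n_studies_stated=True,
        item11_n_participants_stated=True,
        item12_unexplained_stats_found=(),
        item13_quality_addressed=True,
        item14_grade_mentioned=False,
    )
    pct = 100.0 * 14 / 19
    result = AdherenceResult(
        doc_id=doc.doc_id,
        points=14,
        max_points=19,
        percentage=pct,
        band=band_for_percentage(pct),
    )
    return doc, assessment, result


def _fixture_narrative_perfect() -> tuple[PlsDocument, ItemAssessment, AdherenceResult]:
    core = [
        "We reviewed the evidence on probiotics for eczema.",
        "Eczema is a common health problem.",
        "The review focused on children aged 5 to 12 years with eczema.",
        "We searched for studies up to June 2014.",
        "We included 12 studies in this review.",
        "Altogether the included studies involved 2,317 participants.",
        "The results suggested some benefit from the treatment.",
        "The risk ratio was 0.80; this means slightly fewer children had eczema symptoms.",
        "We assessed the quality of the evidence using the GRADE approach.",
    ]
    # core is 80 words; 41 eight-word fillers bring the total to 408,
    # inside the recommended 400-700 range
    filler = "Readers can consult the full review for detail."
    body = " ".join(core) + "\n" + " ".join([filler] * 41)
    doc = PlsDocument(
        doc_id="fixture-narrative",
        review_title="Probiotics for eczema",
        pls_title="Do probiotics help people with eczema?",
        body=body,
        pub_year=2014,
        pub_month=11,
        review_group="Group D",
        is_empty_review=False,
    )
    assessment = ItemAssessment(
        doc_id=doc.doc_id,
        is_empty_review=False,
        item1_title_same=False,
        item2_word_count=408,
        item4_structured=False,
        item7_search_date=SearchDateTier.MONTH_AND_YEAR,
        item9_population_details=True,
        item10_n_studies_stated=True,
        item11_n_participants_stated=True,
        item12_unexplained_stats_found=(),
        item13_quality_addressed=True,
        item14_grade_mentioned=True,
    )
    pct = 100.0 * 12 / 19
    result = AdherenceResult(
        doc_id=doc.doc_id,
        points=12,
        max_points=19,
        percentage=pct,
        band=band_for_percentage(pct),
    )
    return doc, assessment, result


_FIXTURES = {
    "minimal_three_sentence": _fixture_minimal,
    "empty_review_basic": _fixture_empty,
    "heading_variants": _fixture_heading_variants,
    "narrative_perfect": _fixture_narrative_perfect,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> tuple[PlsDocument, ItemAssessment, AdherenceResult]:
    """Hand-authored edge-case document with fully specified expectations."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()
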