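"""Rule-based detectors for the 14 measurable checklist items.

Each detector is a pure function of the text (plus the configurable
:class:`~pleacs.lexicons.Lexicons` and :class:`ExtractorSettings`), so the
whole assessment is deterministic: the same document always yields the same
:class:`~pleacs.assessment.ItemAssessment`.

Conventions shared by the detectors:

* Heading lines (marker ``"## "``) define document structure (items 4-6) and
  are *removed* before the content detectors run — a section label such as
  "Quality of Evidence" is not a statement about evidence quality.
* Word counting (item 2) keeps heading words, stripping only the marker.
* Sentences are delimited by ``.``, ``?`` or ``!`` followed by whitespace, or
  by line breaks — a deliberate plain-text heuristic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict

from .assessment import ItemAssessment, SearchDateTier
from .corpus import HEADING_MARKER, PlsDocument
from .errors import ValidationError
from .lexicons import Lexicons

__all__ = [
    "ExtractorSettings",
    "Match",
    "count_words",
    "title_identical",
    "find_jargon",
    "detect_structure",
    "detect_search_date",
    "find_strategy_details",
    "detect_population_details",
    "detect_count_statement",
    "find_unexplained_stats",
    "detect_quality_statement",
    "assess",
]


class ExtractorSettings(BaseModel):
    """Tunable knobs of the extraction rules."""

    model_config = ConfigDict(frozen=True)

    #: Allow a trailing plural ``s``/``es`` on the last word of a jargon term.
    plural_stemming: bool = True
    #: Token window after a statistical match within which an explanation cue
    #: suppresses the match (item 12).
    explanation_window: int = 12
    #: Treat "no trials were found" as stating a study count of zero.
    zero_counts_as_stated: bool = True
    #: Detect headings heuristically (short title-case lines without terminal
    #: period) when the corpus heading marker is absent from the text.
    heading_fallback: bool = False


DEFAULT_SETTINGS = ExtractorSettings()


class Match(NamedTuple):
    """A lexicon/pattern hit: canonical label plus character span."""

    term: str
    start: int
    end: int


# --------------------------------------------------------------------------
# basic text utilities


def _strip_markers(body: str) -> str:
    return "\n".join(
        line[len(HEADING_MARKER):] if line.startswith(HEADING_MARKER) else line
        for line in body.splitlines()
    )


def count_words(body: str) -> int:
    """Whitespace-token count after stripping heading markers."""
    return len(_strip_markers(body).split())


_TERMINAL_PUNCT = ".?!;:,"


def _normalize_title(title: str) -> str:
    t = " ".join(title.split()).strip()
    t = t.rstrip(_TERMINAL_PUNCT).strip()
    return t.casefold()


def title_identical(review_title: str, pls_title: str) -> bool:
    """Item 1: are the two titles the same after normalization?

    Normalization: case-fold, collapse whitespace, strip terminal punctuation.
    """
    if not review_title.strip() or not pls_title.strip():
        raise ValidationError("titles must be non-empty")
    return _normalize_title(review_title) == _normalize_title(pls_title)


_SENT_SPLIT = re.compile(r"(?<=[.?!])\s+|\n+")


def _sentences(text: str) -> list[str]:
    return [s for s in _SENT_SPLIT.split(text) if s.strip()]


def _heading_and_content_lines(body: str, settings: ExtractorSettings) -> tuple[list[str], list[str]]:
    lines = body.splitlines()
    headings = [ln[len(HEADING_MARKER):] for ln in lines if ln.startswith(HEADING_MARKER)]
    content = [ln for ln in lines if not ln.startswith(HEADING_MARKER)]
    if not headings and settings.heading_fallback:
        headings = [
            ln.strip()
            for ln in content
            if ln.strip()
            and len(ln.split()) <= 6
            and not ln.rstrip().endswith(".")
            and (ln.rstrip().endswith(":") or ln.strip() == ln.strip().title())
        ]
        content = [ln for ln in content if ln.strip() not in headings]
    return headings, content


def _content_text(body: str, settings: ExtractorSettings = DEFAULT_SETTINGS) -> str:
    _, content = _heading_and_content_lines(body, settings)
    return "\n".join(content)


# --------------------------------------------------------------------------
# item 3 — jargon


def _phrase_regex(term: str, stem: bool) -> re.Pattern:
    words = [re.escape(w) for w in term.split()]
    if stem and words:
        words[-1] = words[-1] + r"(?:es|s)?"
    return re.compile(r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE)


def _find_terms(text: str, terms: tuple[str, ...], stem: bool) -> list[Match]:
    out = []
    for term in terms:
        m = _phrase_regex(term, stem).search(text)
        if m:
            out.append(Match(term, m.start(), m.end()))
    out.sort(key=lambda m: m.start)
    return out


def find_jargon(
    body: str,
    lex: Lexicons | None = None,
    include_ambiguous: bool = False,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> list[Match]:
    """Item 3: discouraged terms found in the text (first hit per term).

    With ``include_ambiguous`` the second-tier terms are reported too;
    otherwise use :func:`find_ambiguous_terms` to list them separately.
    """
    lex = lex or Lexicons()
    terms = lex.jargon_terms + (lex.ambiguous_terms if include_ambiguous else ())
    return _find_terms(body, terms, settings.plural_stemming)


def find_ambiguous_terms(
    body: str,
    lex: Lexicons | None = None,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> list[Match]:
    """Second-tier terms (different meaning in medicine), reported separately."""
    lex = lex or Lexicons()
    return _find_terms(body, lex.ambiguous_terms, settings.plural_stemming)


# --------------------------------------------------------------------------
# items 4-6 — structure and recommended headings


@dataclass(frozen=True)
class StructureResult:
    structured: bool
    matched_recommended: Optional[frozenset[str]]
    missing_count: Optional[int]


_HEADING_VARIANTS = {
    "review question": "Review Question",
    "review questions": "Review Question",
    "quality of the evidence": "Quality of Evidence",
    "certainty of the evidence": "Quality of Evidence",
}


def _normalize_heading(h: str) -> str:
    h = " ".join(h.split()).strip().rstrip(":").strip()
    return h.casefold()


def detect_structure(
    body: str,
    lex: Lexicons | None = None,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> StructureResult:
    """Items 4-6: is the PLS structured, and which recommended headings appear?

    Headings match case-insensitively with trailing colons stripped;
    "Review question(s)" and "Quality of the evidence" are accepted variants.
    For a narrative text the matched/missing fields are not applicable.
    """
    lex = lex or Lexicons()
    headings, _ = _heading_and_content_lines(body, settings)
    if not headings:
        return StructureResult(False, None, None)
    canon = {_normalize_heading(h): h for h in lex.recommended_headings}
    matched: set[str] = set()
    for h in headings:
        norm = _normalize_heading(h)
        if norm in _HEADING_VARIANTS:
            norm = _normalize_heading(_HEADING_VARIANTS[norm])
        if norm in canon:
            matched.add(canon[norm])
    missing = len(lex.recommended_headings) - len(matched)
    return StructureResult(True, frozenset(matched), missing)


# --------------------------------------------------------------------------
# item 7 — search date


_MONTHS = (
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
    "Jan", "Feb", "Mar", "Apr", "Jun", "Jul", "Aug", "Sep", "Sept", "Oct",
    "Nov", "Dec",
)
# Case-sensitive month names so the modal "may" cannot match.
_MONTH_YEAR_RE = re.compile(
    r"\b(?:" + "|".join(_MONTHS) + r")\.?,?\s+((?:19|20)\d\d)\b"
)
_YEAR_RE = re.compile(r"\b(?:19|20)\d\d\b")
_SEARCH_CUE_RE = re.compile(
    r"(?<!\w)(?:search(?:ed|es|ing)?|current\s+to|up\s+to\s+date|up-to-date)(?!\w)",
    re.IGNORECASE,
)


class SearchDateResult(NamedTuple):
    tier: SearchDateTier
    span: Optional[tuple[int, int]]


def detect_search_date(body: str, settings: ExtractorSettings = DEFAULT_SETTINGS) -> SearchDateResult:
    """Item 7: search-date tier, from date expressions near search cues.

    A date only counts when it shares a sentence with a search-related cue
    (search/searched/current to/up to date), so unrelated years — e.g. trial
    publication years — are ignored.  Month+year outranks year-only.
    """
    best = SearchDateResult(SearchDateTier.NONE, None)
    offset = 0
    text = _content_text(body, settings)
    for sent in _sentences(text):
        pos = text.find(sent, offset)
        offset = pos + len(sent)
        if not _SEARCH_CUE_RE.search(sent):
            continue
        m = _MONTH_YEAR_RE.search(sent)
        if m:
            return SearchDateResult(
                SearchDateTier.MONTH_AND_YEAR, (pos + m.start(), pos + m.end())
            )
        m = _YEAR_RE.search(sent)
        if m and best.tier is SearchDateTier.NONE:
            best = SearchDateResult(SearchDateTier.YEAR_ONLY, (pos + m.start(), pos + m.end()))
    return best


# --------------------------------------------------------------------------
# item 8 — search-strategy details


_BOOLEAN_SYNTAX_RE = re.compile(
    r"['\"‘“][^'\"’”]{1,60}['\"’”]\s+(?:AND|OR|NOT)\s+['\"‘“]"
)
_MESH_RE = re.compile(r"(?<!\w)MeSH(?!\w)")
_TERMS_LIST_RE = re.compile(
    r"\bsearch\s+terms\b[^.\n]{0,20}?[:(\"'‘“]", re.IGNORECASE
)


def find_strategy_details(
    body: str,
    lex: Lexicons | None = None,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> list[Match]:
    """Item 8: search-strategy leaks — database names, boolean syntax, MeSH.

    Database names are proper names and match case-sensitively.
    """
    lex = lex or Lexicons()
    text = _content_text(body, settings)
    out: list[Match] = []
    for name in lex.database_names:
        pat = re.compile(r"(?<!\w)" + re.escape(name) + r"(?!\w)")
        m = pat.search(text)
        if m:
            out.append(Match(name, m.start(), m.end()))
    for label, pat in (
        ("boolean-syntax", _BOOLEAN_SYNTAX_RE),
        ("MeSH", _MESH_RE),
        ("search-terms-list", _TERMS_LIST_RE),
    ):
        m = pat.search(text)
        if m:
            out.append(Match(label, m.start(), m.end()))
    out.sort(key=lambda m: m.start)
    return out


# --------------------------------------------------------------------------
# item 9 — population details


_POP_NOUN = r"(?:adults?|children|child|women|men|patients?|people|infants?|adolescents?)"
_POP_AGE_RE = re.compile(
    r"\baged?\b|\byears?\s+(?:old|of\s+age)\b|\bolder\s+than\b|\byounger\s+than\b"
    r"|\bover\s+the\s+age\b|\bunder\s+the\s+age\b|\b\d+\s*(?:to|-|–)\s*\d+\s+years\b",
    re.IGNORECASE,
)
_POP_COND_RE = re.compile(
    _POP_NOUN + r"(?:\s+\w+){0,2}?\s+(?:with|who|having|suffering|diagnosed|undergoing|living\s+with)\b",
    re.IGNORECASE,
)
_POP_NOUN_RE = re.compile(r"(?<!\w)" + _POP_NOUN + r"(?!\w)", re.IGNORECASE)


def detect_population_details(body: str, settings: ExtractorSettings = DEFAULT_SETTINGS) -> bool:
    """Item 9: does any sentence describe *who* was studied?

    Requires a population noun (adults, children, women, men, patients,
    people...) plus, in the same sentence, an age expression or a condition
    linkage ("with ...", "who ...", "diagnosed ...").
    """
    text = _content_text(body, settings)
    for sent in _sentences(text):
        if not _POP_NOUN_RE.search(sent):
            continue
        if _POP_AGE_RE.search(sent) or _POP_COND_RE.search(sent):
            return True
    return False


# --------------------------------------------------------------------------
# items 10-11 — counts of studies / participants


_SPELLED = {
    w: i + 1
    for i, w in enumerate(
        "one two three four five six seven eight nine ten eleven twelve "
        "thirteen fourteen fifteen sixteen seventeen eighteen nineteen twenty".split()
    )
}
_NUM = r"(\d{1,3}(?:,\d{3})+|\d+|" + "|".join(_SPELLED) + r")"
_KIND_NOUNS = {
    "studies": r"(?:studies|study|trials?|RCTs?)",
    "participants": r"(?:participants?|patients?|people|women|children)",
}


class CountResult(NamedTuple):
    stated: bool
    value: Optional[int]


def _parse_number(token: str) -> int:
    token = token.lower().replace(",", "")
    return _SPELLED.get(token, None) if not token.isdigit() else int(token)


def detect_count_statement(
    body: str,
    kind: str,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> CountResult:
    """Items 10-11: is the number of studies / participants stated?

    Matches numerals (with thousands separators) or spelled-out numbers up to
    twenty immediately before a kind-specific noun, allowing up to two
    intervening words ("12 included studies").  "We found no trials" counts
    as a stated count of zero (configurable).  Bare 4-digit year-like numbers
    are ignored.  Returns the first match in text order.
    """
    if kind not in _KIND_NOUNS:
        raise ValidationError(f"kind must be one of {sorted(_KIND_NOUNS)}; got {kind!r}")
    noun = _KIND_NOUNS[kind]
    text = _content_text(body, settings)
    stated_re = re.compile(
        _NUM + r"\s+(?:\w+\s+){0,2}?" + noun + r"(?!\w)", re.IGNORECASE
    )
    zero_re = re.compile(
        r"\b(?:no|did\s+not\s+(?:find|identify)\s+any|found\s+no)\s+(?:\w+\s+){0,2}?"
        + noun + r"(?!\w)",
        re.IGNORECASE,
    )
    candidates: list[tuple[int, CountResult]] = []
    for m in stated_re.finditer(text):
        token = m.group(1)
        if re.fullmatch(r"(?:19|20)\d\d", token):
            continue  # looks like a year, not a count
        candidates.append((m.start(), CountResult(True, _parse_number(token))))
        break
    if settings.zero_counts_as_stated:
        m = zero_re.search(text)
        if m:
            candidates.append((m.start(), CountResult(True, 0)))
    if not candidates:
        return CountResult(False, None)
    return min(candidates, key=lambda c: c[0])[1]


# --------------------------------------------------------------------------
# item 12 — unexplained statistics


def find_unexplained_stats(
    body: str,
    lex: Lexicons | None = None,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> list[Match]:
    """Item 12: statistical notation without a nearby lay explanation.

    Each pattern-class match is suppressed ("explained") when an explanation
    cue (e.g. "this means", "out of 1000") occurs within
    ``settings.explanation_window`` tokens after the match.
    """
    lex = lex or Lexicons()
    text = _content_text(body, settings)
    out: list[Match] = []
    for label, pattern in lex.stat_patterns.items():
        m = re.compile(pattern).search(text)
        if not m:
            continue
        following = " ".join(text[m.end():].split()[: settings.explanation_window]).lower()
        if any(cue in following for cue in lex.explanation_cues):
            continue
        out.append(Match(label, m.start(), m.end()))
    out.sort(key=lambda m: m.start)
    return out


# --------------------------------------------------------------------------
# items 13-14 — quality of evidence and GRADE


_GRADED_QUALITY_RE = re.compile(
    r"\b(?:very\s+)?(?:low|moderate|high)[-\s]quality\b", re.IGNORECASE
)
_GRADE_RE = re.compile(r"(?<![\w])GRADE(?![\w])")  # capitals only, whole word


class QualityResult(NamedTuple):
    quality_addressed: bool
    grade_mentioned: bool


def detect_quality_statement(
    body: str,
    lex: Lexicons | None = None,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> QualityResult:
    """Items 13-14: is evidence quality addressed, and via GRADE?

    GRADE matches only as a whole capitalized word; a GRADE mention implies
    quality is addressed.
    """
    lex = lex or Lexicons()
    text = _content_text(body, settings)
    quality = bool(_GRADED_QUALITY_RE.search(text)) or any(
        re.search(r"(?<!\w)" + re.escape(p).replace(r"\ ", r"\s+") + r"(?!\w)", text, re.IGNORECASE)
        for p in lex.quality_phrases
    )
    grade = bool(_GRADE_RE.search(text))
    return QualityResult(quality or grade, grade)


# --------------------------------------------------------------------------
# composition


def assess(
    doc: PlsDocument,
    lex: Lexicons | None = None,
    settings: ExtractorSettings = DEFAULT_SETTINGS,
) -> ItemAssessment:
    """Run every detector on one document and return the full assessment.

    Applicability is enforced here: items 9-14 are not applicable when the
    review is empty (a metadata fact, never inferred from the text) and items
    5-6 are not applicable for a narrative PLS.
    """
    lex = lex or Lexicons()
    structure = detect_structure(doc.body, lex, settings)
    jargon = find_jargon(doc.body, lex, include_ambiguous=False, settings=settings)
    ambiguous = find_ambiguous_terms(doc.body, lex, settings=settings)
    kwargs: dict[str, object] = dict(
        doc_id=doc.doc_id,
        is_empty_review=doc.is_empty_review,
        item1_title_same=title_identical(doc.review_title, doc.pls_title),
        item2_word_count=count_words(doc.body),
        item3_jargon_terms_found=tuple(m.term for m in jargon),
        item3_ambiguous_terms_found=tuple(m.term for m in ambiguous),
        item4_structured=structure.structured,
        item5_subtitles_recommended=(
            (structure.missing_count == 0) if structure.structured else None
        ),
        item6_missing_headings=structure.missing_count if structure.structured else None,
        item7_search_date=detect_search_date(doc.body, settings).tier,
        item8_strategy_details_found=tuple(
            m.term for m in find_strategy_details(doc.body, lex, settings)
        ),
    )
    if not doc.is_empty_review:
        quality = detect_quality_statement(doc.body, lex, settings)
        kwargs.update(
            item9_population_details=detect_population_details(doc.body, settings),
            item10_n_studies_stated=detect_count_statement(doc.body, "studies", settings).stated,
            item11_n_participants_stated=detect_count_statement(
                doc.body, "participants", settings
            ).stated,
            item12_unexplained_stats_found=tuple(
                m.term for m in find_unexplained_stats(doc.body, lex, settings)
            ),
            item13_quality_addressed=quality.quality_addressed,
            item14_grade_mentioned=quality.grade_mentioned,
        )
    return ItemAssessment(**kwargs)
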