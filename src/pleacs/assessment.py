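"""Typed representation of the 14 measured checklist items for one summary.

A plain language summary (PLS) of a systematic review is assessed against the
14 measurable items of the PLEACS reporting checklist.  Some items are
conditionally applicable:

* items 9-14 (population, counts, statistics, quality, GRADE) are only
  collected for reviews that include studies — for an *empty review* they are
  not applicable;
* items 5 and 6 (recommended subtitles, missing headings) only apply to a
  *structured* PLS, i.e. one that uses headings at all.

Not-applicable is represented as ``None`` and the model validators enforce the
applicability closure, so an :class:`ItemAssessment` can never encode an
inconsistent state.  :class:`GroundTruthLabels` carries the same per-item
fields without enforcement, because a labels file is allowed to be wrong —
that is what :func:`pleacs.corpus.validate_labels` reports on.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ValidationError

__all__ = [
    "SearchDateTier",
    "ItemAssessment",
    "GroundTruthLabels",
    "ITEM_NUMBERS",
    "item_values",
    "agreement_by_item",
]

#: The checklist items measured from the text (item numbering as in PLEACS).
ITEM_NUMBERS = tuple(range(1, 15))


class SearchDateTier(str, enum.Enum):
    """How precisely the search date is reported (item 7)."""

    MONTH_AND_YEAR = "month_and_year"
    YEAR_ONLY = "year_only"
    NONE = "none"


class ItemAssessment(BaseModel):
    """The measured values of the 14 checklist items for one PLS."""

    model_config = ConfigDict(frozen=True)

    doc_id: str
    is_empty_review: bool

    #: item 1 — PLS title identical to the review title (after normalization).
    #: Adherence means the title was *restated*, i.e. this is False.
    item1_title_same: bool
    #: item 2 — whitespace-token count of the body (heading markers stripped).
    item2_word_count: int = Field(ge=0)
    #: item 3 — jargon terms from the discouraged lexicon found in the text.
    item3_jargon_terms_found: tuple[str, ...] = ()
    #: item 3, second tier — ambiguous-in-medicine terms (reported, not scored
    #: by default).
    item3_ambiguous_terms_found: tuple[str, ...] = ()
    #: item 4 — does the PLS use headings at all?
    item4_structured: bool
    #: item 5 — all five recommended subtitles present (None when narrative).
    item5_subtitles_recommended: Optional[bool] = None
    #: item 6 — how many of the five recommended headings are missing
    #: (None when narrative; 0 when fully conforming).
    item6_missing_headings: Optional[int] = Field(default=None, ge=0, le=5)
    #: item 7 — search-date reporting tier.
    item7_search_date: SearchDateTier
    #: item 8 — search-strategy leaks found (database names, boolean syntax...).
    item8_strategy_details_found: tuple[str, ...] = ()
    #: items 9-14 — None iff the review is empty.
    item9_population_details: Optional[bool] = None
    item10_n_studies_stated: Optional[bool] = None
    item11_n_participants_stated: Optional[bool] = None
    item12_unexplained_stats_found: Optional[tuple[str, ...]] = None
    item13_quality_addressed: Optional[bool] = None
    item14_grade_mentioned: Optional[bool] = None

    @model_validator(mode="after")
    def _check_applicability(self) -> "ItemAssessment":
        content_items = {
            "item9_population_details": self.item9_population_details,
            "item10_n_studies_stated": self.item10_n_studies_stated,
            "item11_n_participants_stated": self.item11_n_participants_stated,
            "item12_unexplained_stats_found": self.item12_unexplained_stats_found,
            "item13_quality_addressed": self.item13_quality_addressed,
            "item14_grade_mentioned": self.item14_grade_mentioned,
        }
        if self.is_empty_review:
            bad = [k for k, v in content_items.items() if v is not None]
            if bad:
                raise ValidationError(
                    f"items 9-14 are not applicable for an empty review; got {bad}"
                )
        else:
            bad = [k for k, v in content_items.items() if v is None]
            if bad:
                raise ValidationError(
                    f"items 9-14 required for a non-empty review; missing {bad}"
                )
        if self.item4_structured:
            if self.item5_subtitles_recommended is None or self.item6_missing_headings is None:
                raise ValidationError("items 5-6 required for a structured PLS")
            if self.item5_subtitles_recommended and self.item6_missing_headings != 0:
                raise ValidationError(
                    "subtitles-as-recommended implies zero missing headings"
                )
        else:
            if self.item5_subtitles_recommended is not None or self.item6_missing_headings is not None:
                raise ValidationError("items 5-6 are not applicable for a narrative PLS")
        if self.item14_grade_mentioned and not self.item13_quality_addressed:
            raise ValidationError("a GRADE mention is a form of addressing quality")
        return self


class GroundTruthLabels(BaseModel):
    """Generator-known true item values for one document.

    Deliberately unvalidated against the applicability rules: label files are
    external input and may violate them — that is surfaced by
    :func:`pleacs.corpus.validate_labels`, not by a parse failure.
    """

    model_config = ConfigDict(frozen=True)

    doc_id: str
    is_empty_review: Optional[bool] = None
    item1_title_same: Optional[bool] = None
    item2_word_count: Optional[int] = None
    item3_jargon_terms_found: Optional[tuple[str, ...]] = None
    item3_ambiguous_terms_found: Optional[tuple[str, ...]] = None
    item4_structured: Optional[bool] = None
    item5_subtitles_recommended: Optional[bool] = None
    item6_missing_headings: Optional[int] = None
    item7_search_date: Optional[SearchDateTier] = None
    item8_strategy_details_found: Optional[tuple[str, ...]] = None
    item9_population_details: Optional[bool] = None
    item10_n_studies_stated: Optional[bool] = None
    item11_n_participants_stated: Optional[bool] = None
    item12_unexplained_stats_found: Optional[tuple[str, ...]] = None
    item13_quality_addressed: Optional[bool] = None
    item14_grade_mentioned: Optional[bool] = None

    def to_assessment(self) -> ItemAssessment:
        """Promote labels to a validated :class:`ItemAssessment`.

        Raises :class:`~pleacs.errors.ValidationError` if required fields are
        missing or the applicability rules are violated.
        """
        if self.is_empty_review is None:
            raise ValidationError(f"label {self.doc_id!r} lacks is_empty_review")
        required = {
            "item1_title_same": self.item1_title_same,
            "item2_word_count": self.item2_word_count,
            "item4_structured": self.item4_structured,
            "item7_search_date": self.item7_search_date,
        }
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ValidationError(f"label {self.doc_id!r} missing fields {missing}")
        return ItemAssessment(
            doc_id=self.doc_id,
            is_empty_review=self.is_empty_review,
            item1_title_same=self.item1_title_same,
            item2_word_count=self.item2_word_count,
            item3_jargon_terms_found=self.item3_jargon_terms_found or (),
            item3_ambiguous_terms_found=self.item3_ambiguous_terms_found or (),
            item4_structured=self.item4_structured,
            item5_subtitles_recommended=self.item5_subtitles_recommended,
            item6_missing_headings=self.item6_missing_headings,
            item7_search_date=self.item7_search_date,
            item8_strategy_details_found=self.item8_strategy_details_found or (),
            item9_population_details=self.item9_population_details,
            item10_n_studies_stated=self.item10_n_studies_stated,
            item11_n_participants_stated=self.item11_n_participants_stated,
            item12_unexplained_stats_found=self.item12_unexplained_stats_found,
            item13_quality_addressed=self.item13_quality_addressed,
            item14_grade_mentioned=self.item14_grade_mentioned,
        )


def _tier_value(t: SearchDateTier | str | None) -> str | None:
    if t is None:
        return None
    return t.value if isinstance(t, SearchDateTier) else str(t)


def item_values(a: ItemAssessment | GroundTruthLabels) -> dict[str, object]:
    """Canonical per-item projection used for agreement comparison.

    List-valued items are compared as case-folded sets: the *identity* of the
    matched terms matters, their order and duplication do not.
    """

    def norm_set(v):
        if v is None:
            return None
        return frozenset(t.lower() for t in v)

    return {
        "item1": a.item1_title_same,
        "item2": a.item2_word_count,
        "item3": norm_set(a.item3_jargon_terms_found),
        "item4": a.item4_structured,
        "item5": a.item5_subtitles_recommended,
        "item6": a.item6_missing_headings,
        "item7": _tier_value(a.item7_search_date),
        "item8": norm_set(a.item8_strategy_details_found),
        "item9": a.item9_population_details,
        "item10": a.item10_n_studies_stated,
        "item11": a.item11_n_participants_stated,
        "item12": norm_set(a.item12_unexplained_stats_found),
        "item13": a.item13_quality_addressed,
        "item14": a.item14_grade_mentioned,
    }


def agreement_by_item(
    assessments: list[ItemAssessment],
    labels: list[GroundTruthLabels],
) -> dict[str, float]:
    """Per-item agreement fraction between extractor output and ground truth.

    Both lists must be aligned by ``doc_id``.  Returns a mapping
    ``{"item1": fraction, ..., "item14": fraction}``.
    """
    if len(assessments) != len(labels):
        raise ValidationError("assessments and labels differ in length")
    keys = [f"item{i}" for i in ITEM_NUMBERS]
    agree = {k: 0 for k in keys}
    for a, lab in zip(assessments, labels):
        if a.doc_id != lab.doc_id:
            raise ValidationError(f"doc_id mismatch: {a.doc_id!r} vs {lab.doc_id!r}")
        va, vl = item_values(a), item_values(lab)
        for k in keys:
            if va[k] == vl[k]:
                agree[k] += 1
    n = len(assessments)
    return {k: (agree[k] / n if n else 1.0) for k in keys}
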