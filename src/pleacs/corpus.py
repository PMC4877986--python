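"""Document model and JSON-lines corpus / labels input-output.

A corpus is one UTF-8 JSON object per line with the :class:`PlsDocument`
fields; heading lines inside ``body`` start with the marker ``"## "``.  The
empty-review flag is metadata supplied with the document, never inferred from
its text, mirroring how review status is recorded at the source rather than in
the summary itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .assessment import GroundTruthLabels
from .errors import CorpusParseError, ValidationError

__all__ = [
    "HEADING_MARKER",
    "TREND_ORIGIN",
    "PlsDocument",
    "time_index",
    "read_corpus",
    "write_corpus",
    "read_labels",
    "write_labels",
    "validate_labels",
    "LabelValidationReport",
    "corpus_to_frame",
]

#: Line-leading marker that identifies a heading line inside ``body``.
HEADING_MARKER = "## "

#: (year, month) origin of the publication-time index: the first month in
#: which the current checklist version applied.
TREND_ORIGIN = (2013, 3)


class PlsDocument(BaseModel):
    """One plain language summary plus its review-level metadata."""

    model_config = ConfigDict(frozen=True)

    doc_id: str = Field(min_length=1)
    review_title: str = Field(min_length=1)
    pls_title: str = Field(min_length=1)
    body: str
    pub_year: Optional[int] = None
    pub_month: Optional[int] = Field(default=None, ge=1, le=12)
    review_group: str = ""
    is_empty_review: bool = False

    @field_validator("body")
    @classmethod
    def _body_not_blank(cls, v: str) -> str:
        if not v.split():
            raise ValueError("body is empty after whitespace normalization")
        return v

    @property
    def eligible_for_trend(self) -> bool:
        """True when a month-resolution publication time can be computed."""
        return self.pub_year is not None and self.pub_month is not None


def time_index(
    doc: PlsDocument,
    origin: tuple[int, int] = TREND_ORIGIN,
    impute_midyear: bool = False,
) -> Optional[float]:
    """Months elapsed since ``origin`` for this document's publication date.

    Returns ``None`` when the date is insufficient.  With
    ``impute_midyear=True`` a document with a year but no month is placed at
    mid-year (month 6.5); by default such documents are excluded from trend
    analysis.
    """
    if doc.pub_year is None:
        return None
    if doc.pub_month is not None:
        month: float = doc.pub_month
    elif impute_midyear:
        month = 6.5
    else:
        return None
    oy, om = origin
    return (doc.pub_year - oy) * 12.0 + (month - om)


def _read_jsonl(path: str | Path, model, what: str):
    path = Path(path)
    records = []
    with path.open("r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"invalid JSON in {what} file: {exc}", i) from exc
            if not isinstance(obj, dict):
                raise CorpusParseError(f"{what} record is not an object", i)
            try:
                records.append(model(**obj))
            except Exception as exc:  # pydantic ValidationError and friends
                raise CorpusParseError(f"invalid {what} record: {exc}", i) from exc
    return records


def read_corpus(path: str | Path) -> list[PlsDocument]:
    """Read a JSON-lines corpus, preserving file order.

    Raises :class:`CorpusParseError` (naming the line) on malformed records
    and :class:`ValidationError` on duplicate ``doc_id``.
    """
    docs = _read_jsonl(path, PlsDocument, "corpus")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {d.doc_id!r} in corpus")
        seen.add(d.doc_id)
    return docs


def write_corpus(docs: Iterable[PlsDocument], path: str | Path) -> None:
    """Write documents as JSON-lines; round-trips field-for-field."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps(d.model_dump(), ensure_ascii=False) + "\n")


def read_labels(path: str | Path) -> list[GroundTruthLabels]:
    """Read a JSON-lines ground-truth labels file (lenient: see model docs)."""
    return _read_jsonl(path, GroundTruthLabels, "labels")


def write_labels(labels: Iterable[GroundTruthLabels], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for lab in labels:
            fh.write(
                json.dumps(lab.model_dump(exclude_none=True), ensure_ascii=False) + "\n"
            )


@dataclass
class LabelValidationReport:
    """Structured result of cross-checking labels against a corpus."""

    orphan_labels: list[str] = field(default_factory=list)
    unlabeled_docs: list[str] = field(default_factory=list)
    applicability_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.orphan_labels or self.unlabeled_docs or self.applicability_violations
        )


_CONTENT_ITEM_FIELDS = (
    "item9_population_details",
    "item10_n_studies_stated",
    "item11_n_participants_stated",
    "item12_unexplained_stats_found",
    "item13_quality_addressed",
    "item14_grade_mentioned",
)
_STRUCTURE_ITEM_FIELDS = ("item5_subtitles_recommended", "item6_missing_headings")


def validate_labels(
    labels: Iterable[GroundTruthLabels], docs: Iterable[PlsDocument]
) -> LabelValidationReport:
    """Report orphan labels, unlabeled documents and applicability violations.

    Total: never raises on any input — all findings come back in the report.
    An item 9-14 label on an empty review, or an item 5-6 label on a narrative
    PLS, is an applicability violation.
    """
    docs = list(docs)
    labels = list(labels)
    doc_by_id = {d.doc_id: d for d in docs}
    label_ids = {lab.doc_id for lab in labels}
    report = LabelValidationReport(
        orphan_labels=[lab.doc_id for lab in labels if lab.doc_id not in doc_by_id],
        unlabeled_docs=[d.doc_id for d in docs if d.doc_id not in label_ids],
    )
    for lab in labels:
        doc = doc_by_id.get(lab.doc_id)
        if doc is None:
            continue
        if lab.is_empty_review is not None and lab.is_empty_review != doc.is_empty_review:
            report.applicability_violations.append(
                f"{lab.doc_id}: empty-review flag disagrees with corpus metadata"
            )
        if doc.is_empty_review:
            for f in _CONTENT_ITEM_FIELDS:
                if getattr(lab, f) is not None:
                    report.applicability_violations.append(
                        f"{lab.doc_id}: {f} labeled for an empty review"
                    )
        if lab.item4_structured is False:
            for f in _STRUCTURE_ITEM_FIELDS:
                if getattr(lab, f) is not None:
                    report.applicability_violations.append(
                        f"{lab.doc_id}: {f} labeled for a narrative PLS"
                    )
    return report


def corpus_to_frame(docs: Iterable[PlsDocument]) -> pd.DataFrame:
    """Tabular view of document metadata (CSV-exportable)."""
    return pd.DataFrame([d.model_dump() for d in docs])
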