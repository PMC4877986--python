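"""Corpus-level aggregation: item-adherence table, bands, groups, trend.

The item table uses four denominators, reflecting each item's applicability:

* items 1-4 and 7-8 — all documents;
* items 9-14 — documents from reviews with included studies;
* item 5 — structured documents;
* item 6 — structured documents not fully conforming (>= 1 missing heading),
  reported as a histogram over the number of missing headings.

The trend analysis regresses per-document adherence percentage on the
publication-time index (months since the checklist took effect) and reports
the Pearson correlation alongside the OLS slope and its two-sided p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assessment import ItemAssessment, SearchDateTier
from .corpus import PlsDocument, time_index
from .errors import DegenerateDesignError, ValidationError
from .extraction import count_words
from .scoring import AdherenceResult, BAND_LABELS, ScoringScheme, default_scheme

__all__ = [
    "ItemRow",
    "WordStats",
    "TrendResult",
    "GroupSummary",
    "CorpusReport",
    "word_stats",
    "trend_analysis",
    "build_report",
]


@dataclass(frozen=True)
class ItemRow:
    """One row of the item-adherence table: counts over a denominator."""

    counts: dict[str, int]
    denominator: int

    def percent(self, key: str = "adhering") -> float:
        if self.denominator == 0:
            return float("nan")
        return 100.0 * self.counts[key] / self.denominator


@dataclass(frozen=True)
class WordStats:
    mean: float
    median: float
    min: int
    max: int


@dataclass(frozen=True)
class TrendResult:
    """Adherence-over-time association."""

    pearson_r: float
    slope: float
    intercept: float
    slope_p: float
    n_used: int
    #: True when adherence had zero variance, leaving r undefined.
    zero_variance: bool = False


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_pls: int
    mean_adherence_pct: float


@dataclass
class CorpusReport:
    n_total: int
    n_empty: int
    n_structured: int
    n_structured_nonconforming: int
    item_adherence: dict[int, ItemRow]
    band_counts: dict[str, dict[str, int]]  # context -> band -> count
    word_stats: WordStats
    group_summaries: list[GroupSummary]
    mean_adherence_pct: float
    trend: Optional[TrendResult] = None

    # -- exports ----------------------------------------------------------
    def item_table(self) -> pd.DataFrame:
        rows = []
        for item, row in sorted(self.item_adherence.items()):
            for key, count in row.counts.items():
                rows.append(
                    {
                        "item": item,
                        "category": key,
                        "count": count,
                        "denominator": row.denominator,
                        "percent_display": (
                            round(100.0 * count / row.denominator)
                            if row.denominator
                            else float("nan")
                        ),
                        "percent_raw": (
                            100.0 * count / row.denominator
                            if row.denominator
                            else float("nan")
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def band_table(self) -> pd.DataFrame:
        rows = []
        for context, counts in self.band_counts.items():
            total = sum(counts.values())
            for band in BAND_LABELS:
                c = counts.get(band, 0)
                rows.append(
                    {
                        "context": context,
                        "band": band,
                        "count": c,
                        "percent_raw": 100.0 * c / total if total else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def group_table(self) -> pd.DataFrame:
        return pd.DataFrame([g.__dict__ for g in self.group_summaries])

    def to_json_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_empty": self.n_empty,
            "n_structured": self.n_structured,
            "n_structured_nonconforming": self.n_structured_nonconforming,
            "mean_adherence_pct": self.mean_adherence_pct,
            "item_adherence": {
                str(i): {"counts": r.counts, "denominator": r.denominator}
                for i, r in sorted(self.item_adherence.items())
            },
            "band_counts": self.band_counts,
            "word_stats": self.word_stats.__dict__,
            "group_summaries": [g.__dict__ for g in self.group_summaries],
            "trend": self.trend.__dict__ if self.trend else None,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.item_table().to_csv(out / "item_table.csv", index=False)
        self.band_table().to_csv(out / "band_table.csv", index=False)
        self.group_table().to_csv(out / "group_table.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2), encoding="utf-8"
        )

    def render_text(self) -> str:
        """Plain-text rendering of the item-adherence table."""
        lines = [
            f"{'item':>4}  {'category':<22} {'count':>6} {'denom':>6} {'%':>4}",
            "-" * 48,
        ]
        for item, row in sorted(self.item_adherence.items()):
            for key, count in row.counts.items():
                pct = (
                    f"{round(100.0 * count / row.denominator):>4d}"
                    if row.denominator
                    else "  --"
                )
                lines.append(
                    f"{item:>4}  {key:<22} {count:>6} {row.denominator:>6} {pct}"
                )
        return "\n".join(lines)


def word_stats(docs: Sequence[PlsDocument]) -> WordStats:
    """Mean / median / min / max of the per-document word counts."""
    if not docs:
        raise ValidationError("word statistics need a non-empty corpus")
    counts = np.array([count_words(d.body) for d in docs])
    return WordStats(
        mean=float(counts.mean()),
        median=float(np.median(counts)),
        min=int(counts.min()),
        max=int(counts.max()),
    )


def trend_analysis(pairs: Iterable[tuple[float, float]]) -> TrendResult:
    """Pearson r and OLS slope of adherence % on the month index.

    ``pairs`` are per-document ``(time_index, adherence_percentage)``.
    Raises :class:`DegenerateDesignError` when fewer than 3 points are
    available or all time indices coincide.  Zero-variance adherence is
    flagged (r undefined) with the slope reported as 0.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or len(arr) < 3:
        raise DegenerateDesignError("trend analysis needs at least 3 dated documents")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite time index or adherence percentage")
    t, y = arr[:, 0], arr[:, 1]
    if np.ptp(t) == 0:
        raise DegenerateDesignError("all publication-time indices are identical")
    if np.ptp(y) == 0:
        return TrendResult(
            pearson_r=float("nan"),
            slope=0.0,
            intercept=float(y[0]),
            slope_p=float("nan"),
            n_used=len(y),
            zero_variance=True,
        )
    r = float(stats.pearsonr(t, y).statistic)
    fit = sm.OLS(y, sm.add_constant(t)).fit()
    return TrendResult(
        pearson_r=r,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_p=float(fit.pvalues[1]),
        n_used=len(y),
    )


def _adhering(a: ItemAssessment, item: int, scheme: ScoringScheme) -> bool:
    """Table-row adherence indicator for the single-count items."""
    if item == 1:
        return not a.item1_title_same
    if item == 2:
        lo, hi = scheme.word_range
        return lo <= a.item2_word_count <= hi
    if item == 3:
        terms = set(a.item3_jargon_terms_found)
        if scheme.count_ambiguous_jargon:
            terms |= set(a.item3_ambiguous_terms_found)
        return not terms
    if item == 4:
        return a.item4_structured
    if item == 5:
        return bool(a.item5_subtitles_recommended)
    if item == 8:
        return not a.item8_strategy_details_found
    if item == 9:
        return bool(a.item9_population_details)
    if item == 10:
        return bool(a.item10_n_studies_stated)
    if item == 11:
        return bool(a.item11_n_participants_stated)
    if item == 12:
        return not a.item12_unexplained_stats_found
    if item == 13:
        return bool(a.item13_quality_addressed)
    if item == 14:
        return bool(a.item14_grade_mentioned)
    raise ValidationError(f"no single-count adherence rule for item {item}")


def build_report(
    docs: Sequence[PlsDocument],
    assessments: Sequence[ItemAssessment],
    results: Sequence[AdherenceResult],
    scheme: Optional[ScoringScheme] = None,
    impute_midyear: bool = False,
) -> CorpusReport:
    """Aggregate per-document outputs into the corpus report.

    The trend block is included when at least 3 documents carry a usable
    publication time; otherwise it is ``None``.
    """
    scheme = scheme or default_scheme()
    if not (len(docs) == len(assessments) == len(results)):
        raise ValidationError("docs, assessments and results must align one-to-one")
    for d, a, r in zip(docs, assessments, results):
        if not (d.doc_id == a.doc_id == r.doc_id):
            raise ValidationError(
                f"id mismatch: doc {d.doc_id!r}, assessment {a.doc_id!r}, result {r.doc_id!r}"
            )

    n_total = len(docs)
    n_empty = sum(d.is_empty_review for d in docs)
    structured = [a for a in assessments if a.item4_structured]
    nonconforming = [a for a in structured if a.item6_missing_headings != 0]
    nonempty_assessments = [a for a in assessments if not a.is_empty_review]

    item_adherence: dict[int, ItemRow] = {}
    for item in (1, 2, 3, 4):
        item_adherence[item] = ItemRow(
            {"adhering": sum(_adhering(a, item, scheme) for a in assessments)}, n_total
        )
    item_adherence[5] = ItemRow(
        {"adhering": sum(_adhering(a, 5, scheme) for a in structured)}, len(structured)
    )
    hist = {
        f"{k}_missing": sum(a.item6_missing_headings == k for a in nonconforming)
        for k in range(1, 6)
    }
    item_adherence[6] = ItemRow(hist, len(nonconforming))
    item_adherence[7] = ItemRow(
        {
            "month_and_year": sum(
                a.item7_search_date is SearchDateTier.MONTH_AND_YEAR for a in assessments
            ),
            "year_only": sum(
                a.item7_search_date is SearchDateTier.YEAR_ONLY for a in assessments
            ),
        },
        n_total,
    )
    item_adherence[8] = ItemRow(
        {"adhering": sum(_adhering(a, 8, scheme) for a in assessments)}, n_total
    )
    for item in (9, 10, 11, 12, 13, 14):
        item_adherence[item] = ItemRow(
            {"adhering": sum(_adhering(a, item, scheme) for a in nonempty_assessments)},
            n_total - n_empty,
        )

    band_counts: dict[str, dict[str, int]] = {
        "non_empty": {b: 0 for b in BAND_LABELS},
        "empty": {b: 0 for b in BAND_LABELS},
    }
    for d, r in zip(docs, results):
        context = "empty" if d.is_empty_review else "non_empty"
        band_counts[context][r.band] += 1

    by_group: dict[str, list[float]] = {}
    for d, r in zip(docs, results):
        by_group.setdefault(d.review_group, []).append(r.percentage)
    group_summaries = [
        GroupSummary(g, len(v), float(np.mean(v))) for g, v in sorted(by_group.items())
    ]
    mean_pct = float(np.mean([r.percentage for r in results])) if results else float("nan")

    pairs = []
    for d, r in zip(docs, results):
        ti = time_index(d, impute_midyear=impute_midyear)
        if ti is not None:
            pairs.append((ti, r.percentage))
    trend: Optional[TrendResult]
    try:
        trend = trend_analysis(pairs)
    except DegenerateDesignError:
        trend = None

    return CorpusReport(
        n_total=n_total,
        n_empty=n_empty,
        n_structured=len(structured),
        n_structured_nonconforming=len(nonconforming),
        item_adherence=item_adherence,
        band_counts=band_counts,
        word_stats=word_stats(docs) if docs else WordStats(0, 0, 0, 0),
        group_summaries=group_summaries,
        mean_adherence_pct=mean_pct,
        trend=trend,
    )
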