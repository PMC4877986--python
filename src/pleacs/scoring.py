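"""Point-based adherence scoring of an item assessment.

The default scheme is the minimal point assignment consistent with the
checklist's published constraints: 14 items; items 1, 3, 8 and 12 scored in
reverse (adherence = the element is *absent*); a tiered search-date item
(month+year 2, year only 1, none 0); a graded headings item awarding one
point per present recommended heading (5 - missing); one point for every
other item.  The achievable maxima are 19 points for a PLS of a review with
included studies and 13 points for an empty review's PLS — not-applicable
items score zero against that fixed per-context denominator.

Adherence percentage = points / context-maximum x 100, banded into
0-25 / 26-50 / 51-75 / 76-100 after half-up rounding to an integer.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional

from pydantic import BaseModel, ConfigDict

from .assessment import ITEM_NUMBERS, ItemAssessment, SearchDateTier
from .errors import ValidationError

__all__ = [
    "ScoringScheme",
    "AdherenceResult",
    "BAND_LABELS",
    "default_scheme",
    "score",
    "band_for_percentage",
    "verify_scheme",
    "SchemeReport",
]

BAND_LABELS = ("0-25", "26-50", "51-75", "76-100")

#: Items where adherence means absence of the measured element.
PAPER_REVERSE_ITEMS = frozenset({1, 3, 8, 12})

_BINARY_ITEMS = (1, 2, 3, 4, 5, 8, 9, 10, 11, 12, 13, 14)


class ScoringScheme(BaseModel):
    """Configurable item -> points mapping with applicability rules."""

    model_config = ConfigDict(frozen=True)

    #: Weight of each binary item (items 6 and 7 have dedicated rules).
    item_weights: dict[int, int] = {i: 1 for i in _BINARY_ITEMS}
    #: Points per present recommended heading; item 6 awards
    #: ``item6_per_heading * (5 - missing)``.
    item6_per_heading: int = 1
    item7_tier_points: dict[SearchDateTier, int] = {
        SearchDateTier.MONTH_AND_YEAR: 2,
        SearchDateTier.YEAR_ONLY: 1,
        SearchDateTier.NONE: 0,
    }
    reverse_items: frozenset[int] = PAPER_REVERSE_ITEMS
    #: Recommended word-count range granting the item-2 point (inclusive).
    word_range: tuple[int, int] = (400, 700)
    #: Count second-tier ambiguous terms as item-3 violations.
    count_ambiguous_jargon: bool = False
    #: Declared per-context maxima; checked by :func:`verify_scheme`.
    max_nonempty: int = 19
    max_empty: int = 13

    @property
    def n_items(self) -> int:
        return len(ITEM_NUMBERS)

    def max_points(self, empty: bool) -> int:
        return self.max_empty if empty else self.max_nonempty

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "item_weights": {str(k): v for k, v in self.item_weights.items()},
            "item6_per_heading": self.item6_per_heading,
            "item7_tier_points": {t.value: p for t, p in self.item7_tier_points.items()},
            "reverse_items": sorted(self.reverse_items),
            "word_range": list(self.word_range),
            "count_ambiguous_jargon": self.count_ambiguous_jargon,
            "max_nonempty": self.max_nonempty,
            "max_empty": self.max_empty,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringScheme":
        d = dict(d)
        if "item_weights" in d:
            d["item_weights"] = {int(k): v for k, v in d["item_weights"].items()}
        if "item7_tier_points" in d:
            d["item7_tier_points"] = {
                SearchDateTier(k): v for k, v in d["item7_tier_points"].items()
            }
        if "reverse_items" in d:
            d["reverse_items"] = frozenset(d["reverse_items"])
        if "word_range" in d:
            d["word_range"] = tuple(d["word_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ScoringScheme":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def default_scheme() -> ScoringScheme:
    """The bundled default scheme (maxima 19 non-empty / 13 empty)."""
    return ScoringScheme()


class AdherenceResult(BaseModel):
    """Score of one PLS under a scheme."""

    model_config = ConfigDict(frozen=True)

    doc_id: str
    points: int
    max_points: int
    percentage: float
    band: str

    @property
    def rounded_percentage(self) -> int:
        return _round_half_up(self.percentage)


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def band_for_percentage(percentage: float) -> str:
    """Band of a raw percentage: half-up round to integer, then
    [0,25], (25,50], (50,75], (75,100]."""
    r = _round_half_up(percentage)
    if not 0 <= r <= 100:
        raise ValidationError(f"percentage out of range: {percentage}")
    if r <= 25:
        return BAND_LABELS[0]
    if r <= 50:
        return BAND_LABELS[1]
    if r <= 75:
        return BAND_LABELS[2]
    return BAND_LABELS[3]


# --------------------------------------------------------------------------
# the per-item point rules, shared by score() and verify_scheme()


def _points_by_item(scheme: ScoringScheme, v: Mapping[str, object]) -> dict[int, int]:
    """Points per item from a canonical value mapping (None = not applicable).

    Keys mirror :func:`pleacs.assessment.item_values`, plus ``item3_ambiguous``.
    """
    w = scheme.item_weights
    rev = scheme.reverse_items

    def directed(i: int, present: bool) -> int:
        # reverse-scored items award their point when the element is absent
        adherent = not present if i in rev else present
        return w[i] if adherent else 0

    pts: dict[int, int] = {}
    pts[1] = directed(1, bool(v["item1"]))  # element: identical title
    lo, hi = scheme.word_range
    pts[2] = w[2] if lo <= v["item2"] <= hi else 0
    jargon = set(v["item3"] or ())
    if scheme.count_ambiguous_jargon:
        jargon |= set(v.get("item3_ambiguous") or ())
    pts[3] = directed(3, bool(jargon))  # element: jargon present
    pts[4] = w[4] if v["item4"] else 0
    pts[5] = w[5] if v["item5"] else 0
    pts[6] = (
        scheme.item6_per_heading * (5 - v["item6"]) if v["item6"] is not None else 0
    )
    tier = v["item7"]
    if isinstance(tier, str):
        tier = SearchDateTier(tier)
    pts[7] = scheme.item7_tier_points[tier]
    pts[8] = directed(8, bool(v["item8"]))  # element: strategy details present
    for i, key in ((9, "item9"), (10, "item10"), (11, "item11"), (13, "item13"), (14, "item14")):
        pts[i] = w[i] if v[key] else 0
    if v["item12"] is None:
        pts[12] = 0
    else:
        pts[12] = directed(12, bool(v["item12"]))  # element: unexplained stats
    return pts


def _values_from_assessment(a: ItemAssessment) -> dict[str, object]:
    from .assessment import item_values

    v = dict(item_values(a))
    v["item3_ambiguous"] = a.item3_ambiguous_terms_found
    return v


def score(
    assessment: ItemAssessment,
    empty: Optional[bool] = None,
    scheme: Optional[ScoringScheme] = None,
) -> AdherenceResult:
    """Score one assessment: points, fixed-context maximum, percentage, band.

    ``empty`` defaults to the assessment's own empty-review flag; passing a
    conflicting value is a validation error since the applicability of items
    9-14 would no longer match.
    """
    scheme = scheme or default_scheme()
    if empty is None:
        empty = assessment.is_empty_review
    elif empty != assessment.is_empty_review:
        raise ValidationError(
            "empty flag conflicts with the assessment's applicability context"
        )
    pts = _points_by_item(scheme, _values_from_assessment(assessment))
    total = sum(pts.values())
    max_points = scheme.max_points(empty)
    pct = 100.0 * total / max_points
    return AdherenceResult(
        doc_id=assessment.doc_id,
        points=total,
        max_points=max_points,
        percentage=pct,
        band=band_for_percentage(pct),
    )


# --------------------------------------------------------------------------
# scheme verification by exhaustive enumeration


@dataclass
class SchemeReport:
    """Brute-force check of a scheme's declared properties."""

    declared_max_nonempty: int
    declared_max_empty: int
    observed_max_nonempty: int
    observed_max_empty: int
    observed_min_nonempty: int
    observed_min_empty: int
    n_items: int
    reverse_divergence: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.declared_max_nonempty == self.observed_max_nonempty
            and self.declared_max_empty == self.observed_max_empty
            and self.observed_min_nonempty == 0
            and self.observed_min_empty == 0
            and self.n_items == 14
            and not self.reverse_divergence
        )


def _enumerate_value_grids(scheme: ScoringScheme, empty: bool):
    """All combinations of per-item extreme values valid for the context."""
    lo, hi = scheme.word_range
    grids: list[list] = [
        [True, False],                      # item1
        [0, (lo + hi) // 2, hi + 100],      # item2: below / inside / above
        [(), ("outcome",)],                 # item3
    ]
    structure_opts = [(False, None, None)]
    structure_opts += [(True, m == 0, m) for m in range(6)]
    structure_opts.append((True, False, 0))  # all headings yet renamed subtitles
    grids.append(structure_opts)             # (item4, item5, item6)
    grids.append(list(SearchDateTier))        # item7
    grids.append([(), ("MEDLINE",)])          # item8
    if empty:
        grids.append([None])  # single placeholder for items 9-14
    else:
        grids.append(
            list(
                itertools.product(
                    [True, False],                 # item9
                    [True, False],                 # item10
                    [True, False],                 # item11
                    [(), ("smd",)],                # item12
                    [(True, True), (True, False), (False, False)],  # (13, 14)
                )
            )
        )
    for combo in itertools.product(*grids):
        item1, item2, item3, (i4, i5, i6), tier, item8, content = combo
        v = {
            "item1": item1,
            "item2": item2,
            "item3": item3,
            "item3_ambiguous": (),
            "item4": i4,
            "item5": i5,
            "item6": i6,
            "item7": tier,
            "item8": item8,
        }
        if empty:
            v.update(item9=None, item10=None, item11=None, item12=None, item13=None, item14=None)
        else:
            i9, i10, i11, i12, (i13, i14) = content
            v.update(item9=i9, item10=i10, item11=i11, item12=i12, item13=i13, item14=i14)
        yield v


def verify_scheme(scheme: Optional[ScoringScheme] = None) -> SchemeReport:
    """Confirm declared maxima/minima by enumerating item-value extremes.

    Also flags any divergence of the reverse-item set from the published
    default {1, 3, 8, 12}.
    """
    scheme = scheme or default_scheme()
    observed = {}
    for empty in (False, True):
        totals = [
            sum(_points_by_item(scheme, v).values())
            for v in _enumerate_value_grids(scheme, empty)
        ]
        observed[empty] = (min(totals), max(totals))
    return SchemeReport(
        declared_max_nonempty=scheme.max_nonempty,
        declared_max_empty=scheme.max_empty,
        observed_max_nonempty=observed[False][1],
        observed_max_empty=observed[True][1],
        observed_min_nonempty=observed[False][0],
        observed_min_empty=observed[True][0],
        n_items=scheme.n_items,
        reverse_divergence=sorted(scheme.reverse_items ^ PAPER_REVERSE_ITEMS),
    )
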