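"""Scoring scheme defaults, point rules, bands and score properties."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pleacs.assessment import ItemAssessment, SearchDateTier
from pleacs.errors import ValidationError
from pleacs.scoring import (
    BAND_LABELS,
    ScoringScheme,
    band_for_percentage,
    default_scheme,
    score,
    verify_scheme,
)
from pleacs.synthetic import make_fixture


def best_nonempty(**overrides) -> ItemAssessment:
    base = dict(
        doc_id="best",
        is_empty_review=False,
        item1_title_same=False,
        item2_word_count=500,
        item3_jargon_terms_found=(),
        item4_structured=True,
        item5_subtitles_recommended=True,
        item6_missing_headings=0,
        item7_search_date=SearchDateTier.MONTH_AND_YEAR,
        item8_strategy_details_found=(),
        item9_population_details=True,
        item10_n_studies_stated=True,
        item11_n_participants_stated=True,
        item12_unexplained_stats_found=(),
        item13_quality_addressed=True,
        item14_grade_mentioned=True,
    )
    base.update(overrides)
    return ItemAssessment(**base)


class TestDefaultScheme:
    def test_declared_maxima(self):
        s = default_scheme()
        assert s.max_nonempty == 19
        assert s.max_empty == 13

    def test_fourteen_items(self):
        assert default_scheme().n_items == 14

    def test_reverse_items(self):
        assert default_scheme().reverse_items == frozenset({1, 3, 8, 12})

    def test_roundtrip_serialization(self, tmp_path):
        s = default_scheme()
        path = tmp_path / "scheme.json"
        s.save(path)
        assert ScoringScheme.load(path) == s


class TestScore:
    def test_best_case_nonempty_is_19_of_19(self):
        r = score(best_nonempty())
        assert (r.points, r.max_points, r.percentage, r.band) == (19, 19, 100.0, "76-100")

    def test_worst_case_is_zero(self):
        worst = best_nonempty(
            item1_title_same=True,
            item2_word_count=100,
            item3_jargon_terms_found=("outcome",),
            item4_structured=False,
            item5_subtitles_recommended=None,
            item6_missing_headings=None,
            item7_search_date=SearchDateTier.NONE,
            item8_strategy_details_found=("MEDLINE",),
            item9_population_details=False,
            item10_n_studies_stated=False,
            item11_n_participants_stated=False,
            item12_unexplained_stats_found=("smd",),
            item13_quality_addressed=False,
            item14_grade_mentioned=False,
        )
        assert score(worst).points == 0

    def test_narrative_but_otherwise_perfect_scores_12(self):
        # loses item 4 (1), item 5 (1) and all five heading points
        r = score(
            best_nonempty(
                item4_structured=False,
                item5_subtitles_recommended=None,
                item6_missing_headings=None,
            )
        )
        assert r.points == 12
        assert r.band == "51-75"

    def test_empty_review_best_is_13_of_13(self):
        best_empty = ItemAssessment(
            doc_id="e",
            is_empty_review=True,
            item1_title_same=False,
            item2_word_count=450,
            item4_structured=True,
            item5_subtitles_recommended=True,
            item6_missing_headings=0,
            item7_search_date=SearchDateTier.MONTH_AND_YEAR,
        )
        r = score(best_empty)
        assert (r.points, r.max_points) == (13, 13)

    def test_missing_headings_award_graded_points(self):
        for missing in range(1, 6):
            r = score(
                best_nonempty(
                    item5_subtitles_recommended=False, item6_missing_headings=missing
                )
            )
            # one point lost for the subtitles item plus one per missing heading
            assert r.points == 19 - 1 - missing

    def test_search_date_tiers(self):
        base = score(best_nonempty()).points
        year = score(best_nonempty(item7_search_date=SearchDateTier.YEAR_ONLY)).points
        none = score(best_nonempty(item7_search_date=SearchDateTier.NONE)).points
        assert (base - year, base - none) == (1, 2)

    def test_conflicting_empty_flag_rejected(self):
        with pytest.raises(ValidationError):
            score(best_nonempty(), empty=True)

    def test_fixture_scores(self):
        for name in (
            "minimal_three_sentence",
            "empty_review_basic",
            "heading_variants",
            "narrative_perfect",
        ):
            _, assessment, expected = make_fixture(name)
            assert score(assessment) == expected

    def test_ambiguous_terms_only_count_when_enabled(self):
        a = best_nonempty(item3_ambiguous_terms_found=("control",))
        assert score(a).points == 19
        strict = default_scheme().model_copy(update={"count_ambiguous_jargon": True})
        assert score(a, scheme=strict).points == 18


class TestBands:
    @pytest.mark.parametrize(
        "pct,band",
        [
            (0.0, "0-25"),
            (25.0, "0-25"),
            (25.4, "0-25"),   # rounds to 25
            (25.5, "26-50"),  # half-up rounds to 26
            (50.0, "26-50"),
            (100.0 * 4 / 19, "0-25"),   # 21.05
            (100.0 * 12 / 19, "51-75"),  # 63.2
            (75.4, "51-75"),
            (75.5, "76-100"),
            (100.0, "76-100"),
        ],
    )
    def test_boundaries_half_up(self, pct, band):
        assert band_for_percentage(pct) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            band_for_percentage(101.0)


class TestVerifyScheme:
    def test_default_scheme_maxima_confirmed_by_enumeration(self):
        rep = verify_scheme()
        assert rep.ok
        assert (rep.observed_max_nonempty, rep.observed_max_empty) == (19, 13)
        assert (rep.observed_min_nonempty, rep.observed_min_empty) == (0, 0)

    def test_changed_item6_weight_flagged(self):
        s = default_scheme().model_copy(update={"item6_per_heading": 3})
        rep = verify_scheme(s)
        assert not rep.ok
        assert rep.observed_max_nonempty == 29

    def test_empty_reverse_set_divergence_reported(self):
        s = default_scheme().model_copy(update={"reverse_items": frozenset()})
        rep = verify_scheme(s)
        assert rep.reverse_divergence == [1, 3, 8, 12]


# ---------------------------------------------------------------------------
# property-based score behaviour


@st.composite
def assessments(draw, empty=None):
    if empty is None:
        empty = draw(st.booleans())
    structured = draw(st.booleans())
    missing = draw(st.integers(0, 5)) if structured else None
    kwargs = dict(
        doc_id="h",
        is_empty_review=empty,
        item1_title_same=draw(st.booleans()),
        item2_word_count=draw(st.integers(0, 1200)),
        item3_jargon_terms_found=tuple(
            draw(st.sets(st.sampled_from(["outcome", "efficacy", "literature"])))
        ),
        item4_structured=structured,
        item5_subtitles_recommended=(missing == 0) if structured else None,
        item6_missing_headings=missing,
        item7_search_date=draw(st.sampled_from(list(SearchDateTier))),
        item8_strategy_details_found=tuple(
            draw(st.sets(st.sampled_from(["MEDLINE", "EMBASE"])))
        ),
    )
    if not empty:
        grade = draw(st.booleans())
        kwargs.update(
            item9_population_details=draw(st.booleans()),
            item10_n_studies_stated=draw(st.booleans()),
            item11_n_participants_stated=draw(st.booleans()),
            item12_unexplained_stats_found=tuple(
                draw(st.sets(st.sampled_from(["smd", "p-value"])))
            ),
            item13_quality_addressed=True if grade else draw(st.booleans()),
            item14_grade_mentioned=grade,
        )
    return ItemAssessment(**kwargs)


class TestScoreProperties:
    @given(assessments())
    def test_points_within_context_range_and_band_consistent(self, a):
        r = score(a)
        assert 0 <= r.points <= r.max_points
        assert r.max_points == (13 if a.is_empty_review else 19)
        assert r.band == band_for_percentage(r.percentage)
        assert r.band in BAND_LABELS

    @given(assessments(empty=False))
    def test_single_item_improvement_never_decreases_points(self, a):
        base = score(a).points
        improvements = {
            "item1_title_same": False,
            "item2_word_count": 500,
            "item3_jargon_terms_found": (),
            "item7_search_date": SearchDateTier.MONTH_AND_YEAR,
            "item8_strategy_details_found": (),
            "item9_population_details": True,
            "item10_n_studies_stated": True,
            "item11_n_participants_stated": True,
            "item12_unexplained_stats_found": (),
            "item13_quality_addressed": True,
        }
        for field, good in improvements.items():
            better = a.model_copy(update={field: good})
            assert score(better).points >= base
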