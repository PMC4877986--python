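"""Detector-level behaviour: each rule exercised on hand-built sentences."""

import pytest

from pleacs.assessment import SearchDateTier
from pleacs.errors import ValidationError
from pleacs.extraction import (
    ExtractorSettings,
    assess,
    count_words,
    detect_count_statement,
    detect_population_details,
    detect_quality_statement,
    detect_search_date,
    detect_structure,
    find_jargon,
    find_strategy_details,
    find_unexplained_stats,
    title_identical,
)
from pleacs.synthetic import make_fixture


class TestCountWords:
    @pytest.mark.parametrize(
        "body,expected",
        [
            ("", 0),
            ("Antibiotics reduce sore throat duration.", 5),
            ("## Background\nOne two three.", 4),  # heading words count, marker does not
        ],
    )
    def test_token_counts(self, body, expected):
        assert count_words(body) == expected


class TestTitleIdentical:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("Antibiotics for sore throat", "Antibiotics for sore throat", True),
            ("Antibiotics for sore throat", "Do antibiotics help sore throat?", False),
            # normalization: whitespace collapse, case fold, terminal punctuation
            ("Antibiotics  for sore throat.", "antibiotics for sore throat", True),
        ],
    )
    def test_normalized_comparison(self, a, b, expected):
        assert title_identical(a, b) is expected

    def test_empty_title_rejected(self):
        with pytest.raises(ValidationError):
            title_identical("", "x")


class TestJargon:
    def test_no_jargon(self):
        assert find_jargon("We looked at pain relief.") == []

    def test_two_terms_found(self):
        found = find_jargon("The main outcome was pain; efficacy was high.")
        assert [m.term for m in found] == ["outcome", "efficacy"]

    def test_plural_stemming(self):
        found = find_jargon("Outcomes were measured")
        assert [m.term for m in found] == ["outcome"]
        strict = ExtractorSettings(plural_stemming=False)
        assert find_jargon("Outcomes were measured", settings=strict) == []

    def test_ambiguous_tier_only_when_flagged(self):
        text = "Blinding was not used; the outcome was pain."
        assert [m.term for m in find_jargon(text)] == ["outcome"]
        both = find_jargon(text, include_ambiguous=True)
        assert {m.term for m in both} == {"outcome", "blinding"}

    def test_adding_jargon_never_shrinks_matches(self):
        base = "We looked at pain relief; the outcome was clear."
        before = {m.term for m in find_jargon(base)}
        after = {m.term for m in find_jargon(base + " The efficacy was high.")}
        assert before <= after


class TestStructure:
    FIVE = "\n".join(
        [
            "## Review Question", "a",
            "## Background", "b",
            "## Study Characteristics", "c",
            "## Key Results", "d",
            "## Quality of Evidence", "e",
        ]
    )

    def test_all_five_recommended(self):
        res = detect_structure(self.FIVE)
        assert res.structured and res.missing_count == 0
        assert len(res.matched_recommended) == 5

    def test_narrative(self):
        res = detect_structure("No headings here. Just prose.")
        assert (res.structured, res.matched_recommended, res.missing_count) == (
            False,
            None,
            None,
        )

    def test_partial_match_with_unrecognized_heading(self):
        body = "\n".join(["## Background", "x", "## Key results", "y", "## Conclusions", "z"])
        res = detect_structure(body)
        assert res.structured
        assert res.matched_recommended == {"Background", "Key Results"}
        assert res.missing_count == 3

    def test_variant_spellings_accepted(self):
        body = "\n".join(
            [
                "## Review question:", "a",
                "## BACKGROUND", "b",
                "## Study characteristics:", "c",
                "## Key results", "d",
                "## Quality of the evidence", "e",
            ]
        )
        res = detect_structure(body)
        assert res.missing_count == 0

    def test_removing_heading_never_increases_matches(self):
        res_all = detect_structure(self.FIVE)
        reduced = "\n".join(
            ln for ln in self.FIVE.splitlines() if ln != "## Key Results"
        )
        res_less = detect_structure(reduced)
        assert res_less.matched_recommended <= res_all.matched_recommended

    def test_fallback_heuristic_behind_flag(self):
        body = "Key Results:\nPain improved with treatment."
        assert not detect_structure(body).structured
        fb = detect_structure(body, settings=ExtractorSettings(heading_fallback=True))
        assert fb.structured


class TestSearchDate:
    @pytest.mark.parametrize(
        "body,tier",
        [
            ("The evidence is current to June 2014.", SearchDateTier.MONTH_AND_YEAR),
            ("We searched databases in 2013.", SearchDateTier.YEAR_ONLY),
            ("We searched several databases.", SearchDateTier.NONE),
            # a year without a search cue in its sentence must not count
            ("One trial was published in 2012. We searched widely.", SearchDateTier.NONE),
            # month+year outranks year-only
            (
                "We searched in 2012. The evidence is current to May 2014.",
                SearchDateTier.MONTH_AND_YEAR,
            ),
        ],
    )
    def test_tiers(self, body, tier):
        assert detect_search_date(body).tier is tier

    def test_lowercase_may_is_not_a_month(self):
        assert (
            detect_search_date("We searched whatever may help in 2013.").tier
            is SearchDateTier.YEAR_ONLY
        )


class TestStrategyDetails:
    def test_database_names(self):
        found = find_strategy_details("We searched MEDLINE and EMBASE.")
        assert [m.term for m in found] == ["MEDLINE", "EMBASE"]

    def test_generic_mention_is_clean(self):
        assert find_strategy_details("We searched medical databases.") == []

    def test_boolean_syntax(self):
        found = find_strategy_details("using the terms ('pain' AND 'child')")
        assert [m.term for m in found] == ["boolean-syntax"]

    def test_mesh_case_sensitive(self):
        assert [m.term for m in find_strategy_details("MeSH terms were used.")] == ["MeSH"]
        assert find_strategy_details("The mesh implant was studied.") == []


class TestPopulation:
    @pytest.mark.parametrize(
        "body,expected",
        [
            ("The review included adults aged over 65 with diabetes.", True),
            ("This review assessed one drug versus another.", False),
            ("The review focused on women with migraine.", True),
            # a population noun without any qualifier is not enough
            ("In total 2,317 patients took part.", False),
        ],
    )
    def test_cue_plus_qualifier(self, body, expected):
        assert detect_population_details(body) is expected


class TestCountStatements:
    def test_studies_and_participants_from_one_sentence(self):
        body = "We included 12 studies (2,317 participants)."
        assert detect_count_statement(body, "studies") == (True, 12)
        assert detect_count_statement(body, "participants") == (True, 2317)

    def test_no_trials_counts_as_zero(self):
        assert detect_count_statement("We found no trials.", "studies") == (True, 0)
        off = ExtractorSettings(zero_counts_as_stated=False)
        assert detect_count_statement("We found no trials.", "studies", off) == (
            False,
            None,
        )

    def test_spelled_numbers(self):
        assert detect_count_statement("We included twelve studies.", "studies") == (
            True,
            12,
        )

    def test_year_like_number_ignored(self):
        assert detect_count_statement(
            "Studies in 2013 trials registries were scanned.", "studies"
        ).value != 2013

    def test_absent(self):
        assert detect_count_statement("Some studies exist.", "studies") == (False, None)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            detect_count_statement("x", "reviews")


class TestUnexplainedStats:
    def test_smd_with_ci(self):
        found = find_unexplained_stats("pain decreased (SMD -0.41, 95 % CI -0.62 to -0.21)")
        assert {m.term for m in found} == {"smd", "confidence-interval"}

    def test_plain_language_numbers_are_fine(self):
        assert find_unexplained_stats("about 3 more people in 100 improved") == []

    def test_explanation_cue_suppresses_within_window(self):
        assert find_unexplained_stats("RR 0.80; this means 20 % fewer events") == []

    def test_explanation_outside_window_does_not_suppress(self):
        filler = "and " * 15
        text = f"RR 0.80 was reported {filler}this means fewer events"
        assert [m.term for m in find_unexplained_stats(text)] == ["risk-ratio"]

    def test_lowercase_or_is_not_an_odds_ratio(self):
        assert find_unexplained_stats("Treatment may help or harm 3 people.") == []


class TestQuality:
    @pytest.mark.parametrize(
        "body,quality,grade",
        [
            ("The quality of the evidence was low.", True, False),
            ("We rated certainty using GRADE.", True, True),
            ("We graded the essays", False, False),  # lowercase must not match
            ("We judged the risk of bias to be low.", True, False),
        ],
    )
    def test_quality_and_grade(self, body, quality, grade):
        assert detect_quality_statement(body) == (quality, grade)

    def test_heading_is_not_a_quality_statement(self):
        body = "## Quality of Evidence\nNothing was said about it."
        assert detect_quality_statement(body).quality_addressed is False


class TestAssessComposition:
    def test_empty_review_marks_items_9_14_not_applicable(self):
        doc, expected, _ = make_fixture("empty_review_basic")
        a = assess(doc)
        assert a == expected
        assert a.item9_population_details is None
        assert a.item12_unexplained_stats_found is None

    @pytest.mark.parametrize(
        "name",
        ["minimal_three_sentence", "empty_review_basic", "heading_variants", "narrative_perfect"],
    )
    def test_fixture_assessments_recovered_exactly(self, name):
        doc, expected, _ = make_fixture(name)
        assert assess(doc) == expected

    def test_determinism(self):
        doc, _, _ = make_fixture("narrative_perfect")
        assert assess(doc) == assess(doc)


class TestLexiconLoading:
    def test_sectioned_file_overrides_defaults(self, tmp_path):
        from pleacs.lexicons import Lexicons, load_lexicons

        path = tmp_path / "lex.txt"
        path.write_text(
            "# custom lexicon\n[jargon]\nrandomised\nplacebo\n[databases]\nScopus\n",
            encoding="utf-8",
        )
        lex = load_lexicons(path)
        assert lex.jargon_terms == ("randomised", "placebo")
        assert lex.database_names == ("Scopus",)
        # untouched sections keep their defaults
        assert lex.quality_phrases == Lexicons().quality_phrases
        found = find_jargon("A randomised comparison.", lex)
        assert [m.term for m in found] == ["randomised"]

    def test_unknown_section_rejected(self, tmp_path):
        from pleacs.lexicons import load_lexicons

        path = tmp_path / "lex.txt"
        path.write_text("[nonsense]\nfoo\n", encoding="utf-8")
        with pytest.raises(ValidationError):
            load_lexicons(path)

    def test_five_headings_enforced(self):
        from pleacs.lexicons import Lexicons

        with pytest.raises(Exception):
            Lexicons(recommended_headings=("Only", "Four", "Headings", "Here"))
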