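"""Scorecard engine: screening gates, grading, rating and sample summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rih import (
    ATTRIBUTES,
    Grade,
    INTERVAL_LABELS,
    Scorecard,
    ScreeningRecord,
    best_source,
    classify_interval,
    count_documented,
    grade_to_points,
    mean_quality,
    overall_score,
    rate,
    summarize_sample,
)
from rih.scorecard import (
    AttributeAssessment,
    IncompleteScreeningError,
    NoScoreError,
    QualityNotAssessableError,
    UndocumentedAttributeError,
)


class TestGradePoints:
    @pytest.mark.parametrize(
        "grade,points", [("A", 5), ("B", 4), ("C", 2), ("D", 1)]
    )
    def test_non_equidistant_mapping(self, grade, points):
        assert grade_to_points(Grade(grade)) == points

    def test_missing_grade_signals_undocumented(self):
        with pytest.raises(UndocumentedAttributeError):
            grade_to_points(Grade.MISSING)

    def test_parse_rejects_unknown_letter(self):
        with pytest.raises(ValueError, match="invalid grade"):
            Grade.parse("E")


class TestBestSource:
    @pytest.mark.parametrize(
        "sources,expected",
        [([1, 3, 2], 3), ([2], 2), ([], None), ([None, 1, None], 1), ([None], None)],
    )
    def test_highest_quality_rule(self, sources, expected):
        assert best_source(sources) == expected


class TestScreening:
    @pytest.mark.parametrize(
        "answers,proceed,reasons",
        [
            ((True, True, False, False), True, ()),
            ((True, True, True, False), False, ("unavailability",)),
            ((True, True, False, True), False, ("corporate_social_irresponsibility",)),
            ((False, True, False, False), False, ("determinants_of_health",)),
            ((False, False, True, True), False,
             ("determinants_of_health", "innovativeness",
              "unavailability", "corporate_social_irresponsibility")),
        ],
    )
    def test_inclusion_and_exclusion_gates(self, answers, proceed, reasons):
        out = ScreeningRecord(*answers).outcome()
        assert out.proceed is proceed
        assert out.reasons == reasons

    def test_missing_answer_blocks_outcome(self):
        with pytest.raises(IncompleteScreeningError, match="innovativeness"):
            ScreeningRecord(True, None, False, False).outcome()

    def test_yes_no_strings_parse(self):
        rec = ScreeningRecord("yes", "Yes", "no", "NO")
        assert rec.outcome().proceed


class TestRatingComponents:
    @pytest.mark.parametrize("n_graded,sufficient", [(9, True), (7, True), (6, False)])
    def test_documented_count_threshold(self, n_graded, sufficient):
        pts = [5] * n_graded + [None] * (9 - n_graded)
        sc = Scorecard.from_points("x", pts)
        assert count_documented(sc) == (n_graded, sufficient)

    @pytest.mark.parametrize(
        "sources,mean,sufficient",
        [
            ([3] * 9, 3.0, True),
            ([1] * 9, 1.0, False),
            ([3, 2, 2, 1, 2, 2, 2, 2, 2], 2.0, True),  # 18/9, boundary inclusive
        ],
    )
    def test_mean_quality_threshold(self, sources, mean, sufficient):
        sc = Scorecard.from_points("x", [5] * 9, sources=sources)
        assert mean_quality(sc) == (mean, sufficient)

    def test_quality_unassessable_without_sources(self):
        sc = Scorecard.from_points("x", [5] * 9)
        with pytest.raises(QualityNotAssessableError):
            mean_quality(sc)

    def test_graded_attribute_without_source_counts_for_availability_only(self):
        sources = [3] * 8 + [None]
        sc = Scorecard.from_points("x", [5] * 9, sources=sources)
        assert count_documented(sc) == (9, True)
        assert mean_quality(sc) == (3.0, True)  # mean over the 8 sourced attributes

    @pytest.mark.parametrize(
        "name,expected",
        [("innovation_1", 4.6), ("innovation_2", 3.6), ("innovation_3", 2.3)],
    )
    def test_overall_score_worked_examples(self, worked_scorecards, name, expected):
        assert overall_score(worked_scorecards[name]) == expected

    def test_no_documented_attribute_means_no_score(self):
        sc = Scorecard.from_points("x", [None] * 9)
        with pytest.raises(NoScoreError):
            overall_score(sc)

    def test_round_half_up(self):
        # 3.25 rounds up to 3.3 under half-up (half-even would give 3.2)
        sc = Scorecard.from_points("x", [4, 4, 4, 4, 2, 2, None, None, None])
        assert overall_score(sc) == 3.3


class TestClassifyInterval:
    @pytest.mark.parametrize(
        "score,label",
        [
            (4.6, "Almost all RIH features are present"),
            (4.1, "Almost all RIH features are present"),
            (4.0, "Many RIH features are present"),
            (3.1, "Many RIH features are present"),
            (3.0, "Few RIH features are present"),
            (2.3, "Few RIH features are present"),
            (2.1, "Few RIH features are present"),
            (2.0, "Almost no RIH features are present"),
            (1.0, "Almost no RIH features are present"),
            (5.0, "Almost all RIH features are present"),
        ],
    )
    def test_interval_edges(self, score, label):
        assert classify_interval(score) == label

    @pytest.mark.parametrize("score", [0.9, 5.1, -1.0])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            classify_interval(score)

    def test_one_decimal_grid_is_partitioned(self):
        # every 1-decimal score in [1.0, 5.0] maps to exactly one label
        for tenth in range(10, 51):
            label = classify_interval(tenth / 10)
            assert label in INTERVAL_LABELS


class TestRate:
    def test_worked_example_full_composition(self, worked_scorecards):
        s = rate(worked_scorecards["innovation_1"])
        assert s.overall_score == 4.6
        assert s.interval_label == "Almost all RIH features are present"
        assert s.n_documented == 9
        assert s.meaningful

    def test_seven_documented_still_meaningful_with_good_sources(self, worked_scorecards):
        s = rate(worked_scorecards["innovation_3"])
        assert s.n_documented == 7
        assert s.availability_sufficient
        assert s.overall_score == 2.3
        assert s.interval_label == "Few RIH features are present"
        assert s.quality_mean >= 2 and s.meaningful

    def test_five_documented_never_meaningful(self):
        sc = Scorecard.from_points(
            "x", [5, 5, 5, 5, 5, None, None, None, None], sources=[3] * 5 + [None] * 4
        )
        s = rate(sc)
        assert s.overall_score == 5.0
        assert not s.availability_sufficient and not s.meaningful

    def test_low_quality_sources_block_meaningfulness(self):
        sc = Scorecard.from_points("x", [5] * 9, sources=[1] * 9)
        s = rate(sc)
        assert s.quality_mean == 1.0
        assert not s.quality_sufficient and not s.meaningful

    def test_excluded_innovation_is_still_rated(self):
        sc = Scorecard.from_points(
            "x", [5] * 9, screening=ScreeningRecord(True, True, True, False), sources=[3] * 9
        )
        s = rate(sc)
        assert s.screening_proceed is False
        assert s.screening_reasons == ("unavailability",)
        assert s.overall_score == 5.0


class TestScoringInvariants:
    def test_all_a_and_all_d_extremes(self):
        s_a = rate(Scorecard.from_points("a", [5] * 9, sources=[3] * 9))
        assert s_a.overall_score == 5.0
        assert s_a.interval_label == "Almost all RIH features are present"
        s_d = rate(Scorecard.from_points("d", [1] * 9, sources=[3] * 9))
        assert s_d.overall_score == 1.0
        assert s_d.interval_label == "Almost no RIH features are present"

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        pts=st.lists(
            st.one_of(st.none(), st.sampled_from([5, 4, 2, 1])), min_size=9, max_size=9
        ).filter(lambda p: any(x is not None for x in p)),
        perm=st.permutations(range(9)),
    )
    def test_overall_score_permutation_invariant(self, pts, perm):
        base = overall_score(Scorecard.from_points("x", pts))
        shuffled = overall_score(Scorecard.from_points("x", [pts[i] for i in perm]))
        assert base == shuffled

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        pts=st.lists(st.sampled_from([5, 4, 2, 1]), min_size=7, max_size=8),
        extra=st.sampled_from([5, 4, 2, 1]),
        sources=st.sampled_from([1, 2, 3]),
    )
    def test_adding_documented_attribute_never_drops_availability(self, pts, extra, sources):
        # meaningful is monotone through its availability component
        n = len(pts)
        padded = list(pts) + [None] * (9 - n)
        src = [sources] * n + [None] * (9 - n)
        before = rate(Scorecard.from_points("x", padded, sources=src))
        padded[n] = extra
        src[n] = sources
        after = rate(Scorecard.from_points("x", padded, sources=src))
        assert after.availability_sufficient >= before.availability_sufficient

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n_doc=st.integers(min_value=1, max_value=9),
        quality=st.sampled_from([1, 2, 3]),
    )
    def test_meaningfulness_obeys_both_thresholds(self, n_doc, quality):
        pts = [5] * n_doc + [None] * (9 - n_doc)
        src = [quality] * n_doc + [None] * (9 - n_doc)
        s = rate(Scorecard.from_points("x", pts, sources=src))
        assert s.meaningful == (n_doc >= 7 and quality >= 2)


class TestSummarizeSample:
    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample([])

    def test_known_counts_and_percentages(self):
        # 21 of 25 graded A on the first attribute -> "21 (84%)"
        cards = []
        for i in range(25):
            first = 5 if i < 21 else (4 if i < 22 else (2 if i < 23 else 1))
            cards.append(Scorecard.from_points(f"i{i}", [first] + [5] * 8, sources=[3] * 9))
        summary = summarize_sample(cards)
        row = summary.grades.loc["health_relevance"]
        assert row["A_count"] == 21 and row["A_pct"] == 84
        assert row["B_count"] == 1 and row["D_pct"] == 8
        # grade percentages sum to 100 within rounding
        assert abs(sum(row[f"{g}_pct"] for g in "ABCD") - 100) <= 2

    def test_percentages_use_documented_denominator(self):
        cards = [
            Scorecard.from_points("a", [5, None, 5, 5, 5, 5, 5, 5, 5], sources=[3] * 9),
            Scorecard.from_points("b", [2, 4, 5, 5, 5, 5, 5, 5, 5], sources=[3] * 9),
        ]
        summary = summarize_sample(cards)
        row = summary.grades.loc["elsis"]
        assert row["n_documented"] == 1 and row["B_pct"] == 100

    def test_copies_have_zero_sd(self):
        card = Scorecard.from_points("x", [5, 4, 2, 1, 5, 4, 2, 1, 5], sources=[3] * 9)
        summary = summarize_sample([card] * 10)
        assert (summary.points["sd"].dropna() == 0).all()

    def test_single_scorecard_distributions_are_total(self):
        card = Scorecard.from_points("x", [5] * 9, sources=[3] * 9)
        summary = summarize_sample([card])
        assert (summary.grades["A_pct"] == 100).all()
        assert summary.rating.loc["availability_sufficient", "pct"] == 100

    def test_sample_stats_match_direct_tally(self):
        rng = np.random.default_rng(11)
        pool = [5, 4, 2, 1, None]
        cards, raw = [], {a: [] for a in ATTRIBUTES}
        for i in range(40):
            pts = [pool[k] for k in rng.integers(0, 5, size=9)]
            if all(p is None for p in pts):
                pts[0] = 5
            cards.append(Scorecard.from_points(f"i{i}", pts, sources=[3] * 9))
            for a, p in zip(ATTRIBUTES, pts):
                if p is not None:
                    raw[a].append(p)
        summary = summarize_sample(cards)
        for a in ATTRIBUTES:
            assert summary.points.loc[a, "mean"] == pytest.approx(np.mean(raw[a]))
            assert summary.points.loc[a, "sd"] == pytest.approx(np.std(raw[a], ddof=1))


class TestDomainStructure:
    def test_five_value_domains_partition_the_nine_attributes(self):
        domains = {AttributeAssessment(a).domain for a in ATTRIBUTES}
        sizes = {
            d: sum(AttributeAssessment(a).domain == d for a in ATTRIBUTES) for d in domains
        }
        assert sizes == {
            "population_health": 3,
            "health_system": 3,
            "economic": 1,
            "organizational": 1,
            "environmental": 1,
        }

    def test_scorecard_requires_known_attributes(self):
        with pytest.raises(ValueError, match="unknown attribute"):
            AttributeAssessment("not_an_attribute")
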