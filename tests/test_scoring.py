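"""Classification and scoring rules, totals, ranking, validity."""

import pytest
from hypothesis import given, settings, strategies as st

from cfirf import (
    Classification,
    CodedDataset,
    EndorsementRecord,
    Group,
    GroupThemeSummary,
    Salience,
    ScoringPolicy,
    Theme,
    Valence,
    classify_group_cfirf,
    concurrent_validity,
    is_relevant,
    rank_themes,
    score_original_group,
    score_study,
)
from cfirf.scoring import IndeterminateSummaryError

from _oracle import all_cells, classify_oracle


def cell(size, e=0, b=0, n=0, group="g", theme="t", esub=None, bsub=None):
    return GroupThemeSummary(
        group_id=group,
        theme_id=theme,
        group_size=size,
        mention_count=e + b + n,
        enabler_count=e,
        barrier_count=b,
        neutral_count=n,
        enabler_substantive=esub,
        barrier_substantive=bsub,
    )


@st.composite
def random_cells(draw, max_size=10):
    size = draw(st.integers(1, max_size))
    e = draw(st.integers(0, size))
    b = draw(st.integers(0, size - e))
    n = draw(st.integers(0, size - e - b))
    return cell(size, e, b, n, esub=e, bsub=b)


class TestRelevance:
    @pytest.mark.parametrize(
        "mentions, size, expected",
        [
            (2, 5, False),  # below half
            (3, 5, True),
            (3, 6, True),  # exactly 50% is inclusive
            (2, 6, False),
            (4, 7, True),
            (3, 7, False),
            (0, 6, False),
        ],
    )
    def test_half_threshold(self, mentions, size, expected):
        assert is_relevant(cell(size, n=mentions)) is expected

    def test_custom_threshold(self):
        lax = ScoringPolicy(relevance_threshold=0.25)
        assert is_relevant(cell(7, n=2), lax)
        assert not is_relevant(cell(7, n=1), lax)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "summary, expected_class, expected_score",
        [
            (cell(7, b=4), Classification.BARRIER, -4),
            (cell(5, b=3), Classification.BARRIER, -3),
            (cell(6, e=2, b=2), Classification.NEUTRAL, 0),
            (cell(5, b=2, n=1), Classification.INDETERMINATE, 0),
            (cell(6, e=3), Classification.ENABLER, 3),
            (cell(6, n=3), Classification.NEUTRAL, 0),
            (cell(5, n=2), Classification.EXCLUDED, 0),
            (cell(7, e=3, b=4), Classification.NEUTRAL, 0),  # odd-group one-person margin
            (cell(6, e=2, b=4), Classification.BARRIER, -4),  # even group: no margin
        ],
    )
    def test_decision_sequence(self, summary, expected_class, expected_score):
        gs = classify_group_cfirf(summary)
        assert (gs.classification, gs.cfirf_score) == (expected_class, expected_score)

    def test_matches_bruteforce_decision_table_exhaustively(self):
        for size, e, b, n in all_cells(8):
            gs = classify_group_cfirf(cell(size, e, b, n))
            assert (gs.classification, gs.cfirf_score) == classify_oracle(size, e, b, n), (
                size, e, b, n,
            )

    def test_margin_requires_both_valences_by_default(self):
        # 3-vs-0 in a group of 5: enabler majority, not an odd-group balance
        gs = classify_group_cfirf(cell(5, e=3))
        assert gs.classification == Classification.ENABLER
        relaxed = ScoringPolicy(neutrality_requires_both_valences=False)
        gs2 = classify_group_cfirf(cell(5, e=1, n=2), relaxed)
        assert gs2.classification == Classification.NEUTRAL

    def test_indeterminate_can_escalate_to_error(self):
        strict = ScoringPolicy(indeterminate_handling="error")
        with pytest.raises(IndeterminateSummaryError):
            classify_group_cfirf(cell(5, b=2, n=1), strict)

    def test_reasons_name_the_rule(self):
        assert classify_group_cfirf(cell(5, n=2)).reasons == ("below_threshold",)
        assert classify_group_cfirf(cell(6, n=3)).reasons == ("neutral_majority",)
        assert classify_group_cfirf(cell(6, e=2, b=2)).reasons == ("balanced_valences",)

    @settings(derandomize=True, max_examples=300)
    @given(random_cells())
    def test_boundedness(self, summary):
        gs = classify_group_cfirf(summary)
        assert abs(gs.cfirf_score) <= summary.group_size

    @settings(derandomize=True, max_examples=300)
    @given(random_cells())
    def test_exclusion_dominance(self, summary):
        if not is_relevant(summary):
            gs = classify_group_cfirf(summary)
            assert gs.classification == Classification.EXCLUDED
            assert gs.cfirf_score == 0
            assert score_original_group(summary, gs) == 0

    @settings(derandomize=True, max_examples=300)
    @given(random_cells())
    def test_sign_coherence_with_original_scorer(self, summary):
        gs = classify_group_cfirf(summary)
        original = score_original_group(summary, gs)
        assert gs.cfirf_score * original >= 0

    def test_barrier_score_strictly_monotone_in_endorsers(self):
        for size in range(2, 9):
            lo = -(-size // 2)  # ceil(size / 2)
            scores = [classify_group_cfirf(cell(size, b=b)).cfirf_score
                      for b in range(lo, size + 1)]
            assert all(s2 < s1 for s1, s2 in zip(scores, scores[1:]))


class TestOriginalScorer:
    def test_paper_mode_maps_classes(self):
        assert score_original_group(cell(7, b=4)) == -2
        assert score_original_group(cell(6, e=3)) == 2
        assert score_original_group(cell(5, n=2)) == 0  # sub-threshold
        assert score_original_group(cell(6, n=3)) == 0

    def test_rubric_mode_in_passing_scores_one(self):
        assert score_original_group(cell(7, b=1, bsub=0), mode="rubric") == -1
        assert score_original_group(cell(7, e=1, esub=0), mode="rubric") == 1

    def test_rubric_mode_two_substantive_scores_two(self):
        assert score_original_group(cell(7, b=2, bsub=2), mode="rubric") == -2
        assert score_original_group(cell(7, e=3, esub=2), mode="rubric") == 2

    def test_rubric_mode_tie_scores_zero(self):
        assert score_original_group(cell(6, e=2, b=2, esub=2, bsub=2), mode="rubric") == 0
        assert score_original_group(cell(6), mode="rubric") == 0

    def test_rubric_mode_ignores_relevance_filter(self):
        # one mention in a group of 7 would be excluded by the frequency rules
        assert score_original_group(cell(7, b=1, bsub=1), mode="rubric") == -1

    def test_rubric_mode_without_salience_tallies_raises(self):
        with pytest.raises(ValueError, match="salience"):
            score_original_group(cell(7, b=3), mode="rubric")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            score_original_group(cell(7, b=3), mode="classic")


def worked_example_dataset():
    """Four groups; one theme; tallies from the data-collection example."""
    groups = [
        Group("purveyors", "Model purveyors", 5),
        Group("intermediaries", "Intermediaries", 7),
        Group("tfm", "Their Futures Matter", 6),
        Group("dcj", "DCJ", 6),
    ]
    themes = [Theme("data", "Outcome measures and data collection")]
    records = []
    for i in range(2):
        records.append(EndorsementRecord(f"mp{i}", "purveyors", "data", Valence.NEUTRAL))
    for i in range(4):
        records.append(EndorsementRecord(f"in{i}", "intermediaries", "data", Valence.BARRIER))
    for i in range(4):
        records.append(EndorsementRecord(f"tf{i}", "tfm", "data", Valence.BARRIER))
    for i in range(2):
        records.append(EndorsementRecord(f"dc{i}", "dcj", "data", Valence.ENABLER))
    for i in range(2, 4):
        records.append(EndorsementRecord(f"dc{i}", "dcj", "data", Valence.BARRIER))
    return CodedDataset(groups, themes, records)


class TestScoreStudy:
    def test_worked_example_totals(self):
        (result,) = score_study(worked_example_dataset())
        by_group = {gs.group_id: gs for gs in result.group_scores}
        assert by_group["purveyors"].classification == Classification.EXCLUDED
        assert by_group["intermediaries"].cfirf_score == -4
        assert by_group["tfm"].cfirf_score == -4
        assert by_group["dcj"].classification == Classification.NEUTRAL
        assert result.total_cfirf == -8
        assert result.total_original == -4
        assert result.overall_class == Classification.BARRIER

    def test_all_groups_excluded_is_neutral(self):
        groups = [Group("g", "G", 6)]
        themes = [Theme("t", "T")]
        records = [EndorsementRecord("p1", "g", "t", Valence.BARRIER)]
        (result,) = score_study(CodedDataset(groups, themes, records))
        assert (result.total_cfirf, result.overall_class) == (0, Classification.NEUTRAL)

    def test_totals_are_sums_of_group_scores(self, study_results):
        for r in study_results:
            assert r.total_cfirf == sum(gs.cfirf_score for gs in r.group_scores)
            assert r.total_original == sum(gs.original_score for gs in r.group_scores)


class TestRanking:
    def test_sections_and_order(self, study_results):
        ranked = rank_themes(study_results)
        assert [r.total_cfirf for r in ranked.barriers] == sorted(
            r.total_cfirf for r in ranked.barriers
        )
        assert ranked.barriers[0].label == "Technical, logistical and referral challenges"
        assert ranked.enablers[0].label == "Nature and structure of FFT-CW program"
        assert len(ranked.neutral) == 7

    def test_tie_break_is_lexicographic_and_stable(self):
        def result(theme_id, label):
            from cfirf.scoring import ThemeResult

            return ThemeResult(
                theme_id=theme_id,
                label=label,
                group_scores=(),
                total_cfirf=-4,
                total_original=-2,
                overall_class=Classification.BARRIER,
                mentioner_total=6,
            )

        a, b = result("t1", "alpha"), result("t2", "beta")
        for order in ([a, b], [b, a]):
            assert [r.label for r in rank_themes(order).barriers] == ["alpha", "beta"]


class TestConcurrentValidity:
    def test_self_comparison_full_agreement(self, study_results):
        report = concurrent_validity(study_results, study_results)
        assert report.agreement_count == report.n_themes == len(study_results)

    def test_disagreeing_single_theme(self):
        from cfirf.scoring import ThemeResult

        def result(total_cfirf, total_original):
            return ThemeResult(
                theme_id="t",
                label="T",
                group_scores=(),
                total_cfirf=total_cfirf,
                total_original=total_original,
                overall_class=Classification.BARRIER,
                mentioner_total=4,
            )

        report = concurrent_validity([result(-3, 0)], [result(0, 2)])
        assert report.agreement_count == 0
        assert report.pairs["t"] == (Classification.BARRIER, Classification.ENABLER)

    def test_mismatched_theme_sets_rejected(self, study_results):
        with pytest.raises(ValueError, match="different themes"):
            concurrent_validity(study_results, study_results[:-1])
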