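import numpy as np
import pytest

from pufftop import (
    ConfigurationError,
    ParticipantSummary,
    PesResponse,
    assign_groups,
    compare_groups,
    pes_domain_scores,
    pes_group_tests,
)
from pufftop.groupstats import (
    DEFAULT_PES_MAPPING,
    format_p_value,
    percentile_ranks,
)

from oracles import brute_anova_f, brute_percentile_ranks


def summary_with(pid, daily_puffs, total=None, **kw):
    defaults = dict(
        daily_sessions=5.0, session_length_s=100.0, within_ipi_s=30.0,
        puffs_per_session=4.0, puff_duration_s=2.0, isi_min=90.0,
    )
    defaults.update(kw)
    total = int(daily_puffs * 14) if total is None else total
    return ParticipantSummary(
        participant_id=pid, total_puffs=total, daily_puffs=daily_puffs, **defaults
    )


class TestAssignGroups:
    def test_low_total_puffs_excluded_before_ranking(self):
        summaries = [summary_with("A", 0.5, total=7)] + [
            summary_with(f"B{i}", float(i + 1)) for i in range(10)
        ]
        out = assign_groups(summaries)
        assert out[0].group == "excluded" and np.isnan(out[0].percentile_rank)
        assert all(a.group != "excluded" for a in out[1:])

    def test_equally_spaced_cohort_rank_bins(self):
        summaries = [summary_with(f"P{i}", float(i + 1)) for i in range(10)]
        out = assign_groups(summaries)
        ranks = [a.percentile_rank for a in out]
        assert ranks == pytest.approx([100.0 * i / 9 for i in range(10)])
        groups = [a.group for a in out]
        # ranks 0..33.3 low, 44.4..66.7 moderate, 77.8..100 high
        assert groups == ["low"] * 4 + ["moderate"] * 3 + ["high"] * 3

    def test_single_participant_is_low(self):
        out = assign_groups([summary_with("A", 5.0)])
        assert out[0].group == "low" and out[0].percentile_rank == 0.0

    def test_groups_partition_non_excluded(self):
        rng = np.random.default_rng(8)
        summaries = [
            summary_with(f"P{i}", float(rng.uniform(0.1, 200.0))) for i in range(55)
        ]
        out = assign_groups(summaries)
        assert len(out) == 55
        assert all(a.group in ("excluded", "low", "moderate", "high") for a in out)

    def test_ranks_match_brute_force(self):
        rng = np.random.default_rng(15)
        vals = rng.choice([1.0, 2.0, 5.0, 9.0], size=30)  # with ties
        got = percentile_ranks(vals)
        assert np.allclose(got, brute_percentile_ranks(vals.tolist()))


class TestCompareGroups:
    def _cohort(self, values_by_group):
        summaries, assignments = [], []
        from pufftop import UseGroupAssignment

        i = 0
        for g, vals in values_by_group.items():
            for v in vals:
                pid = f"P{i:03d}"
                summaries.append(summary_with(pid, 10.0, puff_duration_s=float(v)))
                assignments.append(UseGroupAssignment(pid, 50.0, g))
                i += 1
        return assignments, summaries

    def test_textbook_fixture_f_statistic(self):
        assignments, summaries = self._cohort(
            {"low": [1, 2, 3], "moderate": [2, 3, 4], "high": [7, 8, 9]}
        )
        comp = compare_groups(assignments, summaries, "puff_duration_s")
        assert comp.f == pytest.approx(
            brute_anova_f([[1, 2, 3], [2, 3, 4], [7, 8, 9]]), rel=1e-12
        )
        assert comp.f == pytest.approx(31.0)

    def test_identical_groups_give_f_zero_p_one(self):
        assignments, summaries = self._cohort(
            {"low": [2, 2], "moderate": [2, 2], "high": [2, 2]}
        )
        comp = compare_groups(assignments, summaries, "puff_duration_s")
        assert comp.f == 0.0 and comp.p_overall == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        assignments, summaries = self._cohort(
            {"low": [1, 2, 3, 4], "moderate": [2, 3, 4, 5], "high": [30, 31, 32, 33]}
        )
        comp = compare_groups(assignments, summaries, "puff_duration_s")
        for pair, raw in comp.pairwise_raw.items():
            assert comp.pairwise_adjusted[pair] == pytest.approx(min(1.0, raw * 3))

    def test_single_member_group_pairwise_not_computable(self):
        assignments, summaries = self._cohort(
            {"low": [1.0], "moderate": [2, 3, 4], "high": [7, 8, 9]}
        )
        comp = compare_groups(assignments, summaries, "puff_duration_s")
        assert np.isnan(comp.pairwise_raw[("low", "moderate")])
        assert not np.isnan(comp.pairwise_raw[("moderate", "high")])

    def test_fewer_than_two_groups_rejected(self):
        assignments, summaries = self._cohort({"low": [1, 2, 3]})
        with pytest.raises(ConfigurationError):
            compare_groups(assignments, summaries, "puff_duration_s")


class TestPes:
    def test_uniform_extremes(self):
        for score in (1, 7):
            resp = PesResponse("A", np.full(21, score))
            scores = pes_domain_scores(resp)
            assert set(scores) == {
                "satisfaction", "psychological reward", "aversion",
                "comfort and ease of use", "relief",
            }
            assert all(v == float(score) for v in scores.values())

    def test_mixed_fixture_hand_computed(self):
        items = np.ones(21, dtype=int)
        items[0:3] = [7, 5, 3]       # satisfaction -> 5.0
        items[19:21] = [2, 4]        # comfort and ease of use -> 3.0
        scores = pes_domain_scores(PesResponse("A", items), DEFAULT_PES_MAPPING)
        assert scores["satisfaction"] == pytest.approx(5.0)
        assert scores["comfort and ease of use"] == pytest.approx(3.0)
        assert scores["aversion"] == pytest.approx(1.0)

    def test_incomplete_mapping_rejected(self):
        partial = {k: v for k, v in DEFAULT_PES_MAPPING.items() if k != 21}
        with pytest.raises(ConfigurationError):
            pes_domain_scores(PesResponse("A", np.full(21, 4)), partial)

    def test_score_range_enforced(self):
        with pytest.raises(ConfigurationError):
            PesResponse("A", np.full(21, 8))

    def test_identical_groups_not_significant(self):
        rows = pes_group_tests({"low": [4, 4, 4], "high": [4, 4, 4]})
        (row,) = rows
        assert row.p == 1.0 and not row.significant

    def test_large_true_gap_flagged_significant(self):
        rng = np.random.default_rng(19)
        a = rng.normal(2.0, 0.5, size=15)
        b = rng.normal(6.0, 0.5, size=15)
        (row,) = pes_group_tests({"low": a, "high": b})
        assert row.significant and row.p < 1e-6

    def test_alpha_boundary_is_strict(self):
        rows = pes_group_tests({"low": [1, 2, 3], "high": [1, 2, 3]}, alpha=1.0)
        # p == 1.0 equals alpha -> strictly-less rule says not significant
        assert not rows[0].significant

    def test_small_group_not_computable(self):
        (row,) = pes_group_tests({"low": [4.0], "high": [5.0, 6.0]})
        assert np.isnan(row.p) and not row.significant


def test_format_p_value_display_convention():
    assert format_p_value(0.0004) == "<.001"
    assert format_p_value(0.016) == ".016"
    assert format_p_value(float("nan")) == "NA"
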