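import numpy as np
import pytest

from pufftop import ConfigurationError, GroupParams
from pufftop.cleansing import CleansingConfig, false_puff_mask
from pufftop.synthetic import (
    PRESETS,
    TABLE2_N_PER_GROUP,
    dump_scenario,
    fit_truncated_lognormal,
    load_scenario,
    separable_preset,
    simulate_participant,
    simulate_pes_responses,
    simulate_study,
    table2_preset,
    truth_to_frame,
    TABLE3_PES_PRESET,
)

BASE = GroupParams(
    label="moderate", sessions_per_day_mean=6.0, puffs_per_session_mean=5.0,
    within_ipi_mean_s=30.0, within_ipi_sd_s=10.0,
    puff_duration_mean_s=2.2, puff_duration_sd_s=0.6, isi_mean_min=60.0,
)


class TestGroupParams:
    def test_inseparable_params_rejected(self):
        with pytest.raises(ConfigurationError):
            GroupParams(
                label="low", sessions_per_day_mean=5.0, puffs_per_session_mean=4.0,
                within_ipi_mean_s=120.0, within_ipi_sd_s=10.0,
                puff_duration_mean_s=2.0, puff_duration_sd_s=0.5, isi_mean_min=1.0,
            )

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigurationError):
            GroupParams(
                label="extreme", sessions_per_day_mean=5.0, puffs_per_session_mean=4.0,
                within_ipi_mean_s=30.0, within_ipi_sd_s=10.0,
                puff_duration_mean_s=2.0, puff_duration_sd_s=0.5, isi_mean_min=60.0,
            )


class TestTruncatedLognormal:
    def test_truncated_moments_match_targets(self):
        d = fit_truncated_lognormal(2.18, 0.71)
        assert d.mean == pytest.approx(2.18, abs=1e-6)
        assert d.sd == pytest.approx(0.71, abs=1e-6)

    def test_samples_respect_bounds_and_mean(self):
        d = fit_truncated_lognormal(30.0, 20.0)
        rng = np.random.default_rng(0)
        x = d.sample(rng, 200_000)
        assert x.min() >= d.lo and x.max() <= d.hi
        assert abs(x.mean() - 30.0) < 3 * x.std() / np.sqrt(x.size)

    def test_zero_sd_is_constant(self):
        d = fit_truncated_lognormal(5.0, 0.0)
        rng = np.random.default_rng(0)
        assert np.allclose(d.sample(rng, 10), 5.0)


class TestSimulateParticipant:
    def test_stream_satisfies_invariants(self):
        stream, truth = simulate_participant(BASE, days=14, seed=42)
        # construction succeeded => ParticipantStream validation passed
        assert stream.n_puffs == truth.session_index.size
        assert truth.interval_class.size == max(stream.n_puffs - 1, 0)

    def test_deterministic_under_seed(self):
        s1, t1 = simulate_participant(BASE, days=7, seed=5)
        s2, t2 = simulate_participant(BASE, days=7, seed=5)
        assert np.array_equal(s1.start_s, s2.start_s)
        assert np.array_equal(s1.duration_s, s2.duration_s)
        assert np.array_equal(t1.session_index, t2.session_index)

    def test_different_seeds_differ(self):
        s1, _ = simulate_participant(BASE, days=7, seed=1)
        s2, _ = simulate_participant(BASE, days=7, seed=2)
        assert not np.array_equal(s1.start_s, s2.start_s)

    def test_session_indices_non_decreasing(self):
        _, truth = simulate_participant(BASE, days=14, seed=3)
        genuine = truth.session_index[truth.session_index >= 0]
        assert np.all(np.diff(genuine) >= 0)

    def test_artifacts_match_false_puff_rule_exactly(self):
        stream, truth = simulate_participant(BASE, days=14, seed=11)
        mask = false_puff_mask(stream, CleansingConfig())
        assert np.array_equal(mask, truth.session_index < 0)

    def test_vanishing_session_rate_yields_artifacts_only(self):
        params = GroupParams(
            label="low", sessions_per_day_mean=1e-9, puffs_per_session_mean=5.0,
            within_ipi_mean_s=30.0, within_ipi_sd_s=10.0,
            puff_duration_mean_s=2.2, puff_duration_sd_s=0.6, isi_mean_min=60.0,
        )
        stream, truth = simulate_participant(params, days=7, seed=0)
        assert np.all(truth.session_index == -1)

    def test_compound_mean_total_puffs(self):
        # E[puffs] = days * sessions/day * puffs/session for the
        # Poisson-Poisson compound process
        totals = []
        for seed in range(10):
            _, truth = simulate_participant(BASE, days=14, seed=100 + seed)
            totals.append(int((truth.session_index >= 0).sum()))
        totals = np.array(totals, dtype=float)
        expected = 14 * BASE.sessions_per_day_mean * BASE.puffs_per_session_mean
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - expected) < 3 * se

    def test_within_ipi_mean_recovered_from_truth(self):
        stream, truth = simulate_participant(BASE, days=14, seed=7)
        within = truth.interval_class == "within-session"
        lengths = stream.start_s[1:] - (stream.start_s[:-1] + stream.duration_s[:-1])
        vals = lengths[within]
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - BASE.within_ipi_mean_s) < 3 * se

    def test_overnight_gaps_in_configured_range(self):
        stream, truth = simulate_participant(BASE, days=14, seed=9)
        nonuse = truth.interval_class == "nonuse"
        lengths = stream.start_s[1:] - (stream.start_s[:-1] + stream.duration_s[:-1])
        gaps_h = lengths[nonuse] / 3600.0
        assert gaps_h.size > 0
        assert gaps_h.min() >= BASE.overnight_gap_hours[0] * 0.95

    def test_intersession_gaps_dominate_within_ipis(self):
        stream, truth = simulate_participant(BASE, days=14, seed=13)
        lengths = stream.start_s[1:] - (stream.start_s[:-1] + stream.duration_s[:-1])
        inter = lengths[truth.interval_class == "intersession"]
        within = lengths[truth.interval_class == "within-session"]
        assert inter.min() > within.max()


class TestSimulateStudy:
    def test_cohort_split_matches_requested_sizes(self):
        ds, truth = simulate_study(table2_preset(), TABLE2_N_PER_GROUP, days=2, seed=0)
        assert len(ds) == 55
        labels = list(truth.groups.values())
        assert labels.count("low") == 12
        assert labels.count("moderate") == 24
        assert labels.count("high") == 19

    def test_empty_cohort(self):
        ds, truth = simulate_study(table2_preset(), [0, 0, 0], days=2, seed=0)
        assert len(ds) == 0 and truth.labels == {}

    def test_seed_changes_streams_not_counts(self):
        ds1, _ = simulate_study(separable_preset(), [3], days=2, seed=1)
        ds2, _ = simulate_study(separable_preset(), [3], days=2, seed=2)
        assert len(ds1) == len(ds2) == 3
        assert not np.array_equal(ds1.streams[0].start_s, ds2.streams[0].start_s)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_study(table2_preset(), [5, 5], days=2, seed=0)

    def test_participant_substreams_stable_across_cohort_sizes(self):
        params = separable_preset()
        ds1, _ = simulate_study(params, [1], days=2, seed=9)
        ds2, _ = simulate_study(params, [4], days=2, seed=9)
        assert np.array_equal(ds1.streams[0].start_s, ds2.streams[0].start_s)


class TestScenarioFiles:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        dump_scenario(table2_preset(), path)
        back = load_scenario(path)
        assert back == table2_preset()

    def test_presets_registry(self):
        assert set(PRESETS) == {"table2", "separable"}
        for build in PRESETS.values():
            assert all(isinstance(p, GroupParams) for p in build())


def test_truth_frame_has_one_row_per_puff():
    ds, truth = simulate_study(separable_preset(), [2], days=2, seed=3)
    frame = truth_to_frame(truth)
    assert len(frame) == sum(s.n_puffs for s in ds)
    assert set(frame.columns) == {
        "participant_id", "puff_index", "session_index", "interval_class"
    }


def test_simulated_pes_responses_track_domain_means():
    resp = simulate_pes_responses(TABLE3_PES_PRESET["high"], n=50, seed=1)
    assert len(resp) == 50
    from pufftop import pes_domain_scores

    scores = np.array([pes_domain_scores(r)["aversion"] for r in resp])
    # high-use preset aversion mean 1.55; clipped Likert draws stay low
    assert scores.mean() < 2.5
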