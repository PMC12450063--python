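import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gastromill.core import AnalysisConfig, ValidationError, segment_windows
from gastromill.cycles import GastricCycle, analyze_incubation
from gastromill.bursts import Burst
from gastromill.features import (FEATURE_NAMES, N_FEATURES, burstiness,
                                 deciles, embed_2d, featurize_segment,
                                 fit_cluster_model, isi_order_ratio,
                                 map_clusters, max_ratio, phase_of_spikes,
                                 segment_categories, transition_table)
from gastromill.core import SpikeTrain


class TestBurstiness:
    @pytest.mark.parametrize("isis,expected", [
        ([0.1, 0.1, 0.2, 1.8], 1.6 / 1.8),
        ([0.5, 0.5, 0.5], 0.0),
        ([0.1, 1.0], 0.9),
    ])
    def test_max_sorted_gap_over_its_isi(self, isis, expected):
        assert burstiness(isis) == pytest.approx(expected)

    def test_sentinel_below_two_isis(self):
        assert math.isnan(burstiness([0.5]))

    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_always_within_unit_interval(self, isis):
        assert 0.0 <= burstiness(isis) < 1.0 + 1e-12


class TestIsiOrderRatio:
    def test_regular_spiking_is_zero(self):
        assert isi_order_ratio(np.diff(np.arange(10) * 0.5)) == 0.0

    def test_hand_example(self):
        # spikes [0, 1, 3]: ISIs [1, 2], second difference 1, mean ISI 1.5
        assert isi_order_ratio([1.0, 2.0]) == pytest.approx(1 / 1.5)

    def test_sentinel_below_three_spikes(self):
        assert math.isnan(isi_order_ratio([1.0]))


class TestMaxRatio:
    @pytest.mark.parametrize("isis,expected", [
        ([0.1, 0.2, 2.0], 10.0), ([0.4, 0.4, 0.4], 1.0), ([3.0, 1.0], 3.0),
    ])
    def test_largest_over_second_largest(self, isis, expected):
        assert max_ratio(isis) == pytest.approx(expected)

    def test_sentinel_and_lower_bound(self):
        assert math.isnan(max_ratio([1.0]))

    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_at_least_one(self, isis):
        assert max_ratio(isis) >= 1.0


def brute_force_deciles(values):
    """Independent linear-interpolation quantile oracle."""
    s = sorted(values)
    n = len(s)
    out = []
    for i in range(1, 11):
        p = i / 10
        if n == 1:
            out.append(s[0])
            continue
        h = p * (n - 1)
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        out.append(s[lo] + (h - lo) * (s[hi] - s[lo]))
    return out


class TestDeciles:
    def test_matches_brute_force_on_1_to_100(self):
        values = np.arange(1, 101, dtype=float)
        np.testing.assert_allclose(deciles(values), brute_force_deciles(values))

    def test_single_value_repeats(self):
        np.testing.assert_array_equal(deciles([7.0]), np.full(10, 7.0))

    def test_empty_gives_sentinels(self):
        assert np.isnan(deciles([])).all()

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_non_decreasing_and_matches_oracle(self, values):
        d = deciles(values)
        assert np.all(np.diff(d) >= -1e-9)
        np.testing.assert_allclose(d, brute_force_deciles(values), atol=1e-9)


class TestPhaseOfSpikes:
    def _cycle(self, onset, period):
        b = Burst("IC", np.array([onset, onset + 0.5]))
        return GastricCycle(onset=onset, period=period, long_ic_burst=b)

    def test_fraction_of_cycle(self):
        train = SpikeTrain("LG", np.array([2.5]), 0.0, 20.0)
        phases = phase_of_spikes(train, [self._cycle(0.0, 10.0)])
        assert phases.tolist() == [0.25]

    def test_spike_at_onset_is_phase_zero(self):
        train = SpikeTrain("LG", np.array([5.0]), 0.0, 20.0)
        assert phase_of_spikes(train, [self._cycle(5.0, 10.0)]).tolist() == [0.0]

    def test_spikes_outside_cycles_dropped(self):
        train = SpikeTrain("LG", np.array([11.0, 12.0]), 0.0, 20.0)
        assert phase_of_spikes(train, [self._cycle(0.0, 10.0)]).size == 0


class TestFeaturizeSegment:
    def test_fixed_length_and_decile_blocks_monotone(self, full_recording, cfg):
        rec, _ = full_recording
        window = segment_windows(rec, cfg)[0]
        vec = featurize_segment(rec, window, cfg)
        assert vec.shape == (N_FEATURES,) == (len(FEATURE_NAMES),)
        for j in range(5):
            base = j * 24
            for block in (vec[base:base + 10], vec[base + 10:base + 20]):
                vals = block[~np.isnan(block)]
                assert np.all(np.diff(vals) >= -1e-9)

    def test_translation_invariance(self, full_recording, cfg):
        rec, _ = full_recording
        shifted = rec.shifted(123.0)
        v1 = featurize_segment(rec, segment_windows(rec, cfg)[1], cfg)
        v2 = featurize_segment(shifted, segment_windows(shifted, cfg)[1], cfg)
        np.testing.assert_allclose(v1, v2, rtol=1e-9, atol=1e-12)

    def test_empty_segment_is_all_sentinel(self, cfg):
        from gastromill.core import Recording
        rec = Recording("s", "saline", 0.0, 900.0, trains={
            "PD": SpikeTrain("PD", np.array([880.0, 880.1, 880.2]), 0.0, 900.0)})
        vec = featurize_segment(rec, segment_windows(rec, cfg)[0], cfg)
        assert np.isnan(vec).all()

    def test_determinism(self, full_recording, cfg):
        rec, _ = full_recording
        w = segment_windows(rec, cfg)[2]
        np.testing.assert_array_equal(featurize_segment(rec, w, cfg),
                                      featurize_segment(rec, w, cfg))


@pytest.fixture(scope="module")
def fitted(balanced_batch):
    cfg = AnalysisConfig(rng_seed=1)
    vecs, counts, cvs, rules, truths = [], [], [], [], []
    for rec, gt in balanced_batch:
        ana = analyze_incubation(rec, cfg)
        rules += segment_categories(rec, cfg, analysis=ana)
        truths += gt.segment_categories
        for w in segment_windows(rec, cfg):
            vecs.append(featurize_segment(rec, w, cfg, analysis=ana))
            counts.append(sum(1 for b in ana.long_ic_bursts
                              if w.contains(b.onset)))
            periods = [c.period for c in ana.gastric_cycles
                       if w.contains(c.onset)]
            cvs.append(np.std(periods) / np.mean(periods)
                       if len(periods) >= 2 else np.nan)
    X = np.asarray(vecs)
    model = fit_cluster_model(X, cfg, long_burst_counts=counts,
                              period_cvs=cvs)
    return X, model, rules, truths


class TestClusterModel:
    def test_rule_based_matches_ground_truth_everywhere(self, fitted):
        _, _, rules, truths = fitted
        assert rules == truths

    def test_cluster_categories_agree_with_rule_based(self, fitted):
        X, model, rules, _ = fitted
        predicted = model.categorize(X)
        agreement = np.mean([p == r for p, r in zip(predicted, rules)])
        assert agreement >= 0.90

    def test_mapping_is_bijection_onto_categories(self, fitted):
        _, model, _, _ = fitted
        assert sorted(model.mapping.values()) == ["GMR", "IRREGULAR", "NONE"]

    def test_deterministic_prediction_and_json_round_trip(self, fitted, tmp_path):
        X, model, _, _ = fitted
        from gastromill.features import ClusterModel
        model.to_json(tmp_path / "model.json")
        back = ClusterModel.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(model.predict(X), back.predict(X))
        assert back.mapping == model.mapping

    def test_all_identical_vectors_rejected(self, cfg):
        X = np.ones((10, N_FEATURES))
        with pytest.raises(ValidationError):
            fit_cluster_model(X, cfg)

    def test_fewer_vectors_than_k_rejected(self, cfg):
        with pytest.raises(ValidationError):
            fit_cluster_model(np.ones((2, N_FEATURES)), cfg)

    def test_embedding_returns_one_point_per_vector(self, fitted):
        X, model, _, _ = fitted
        coords = embed_2d(X[:15], model, AnalysisConfig(rng_seed=1))
        assert coords.shape == (15, 2)
        again = embed_2d(X[:15], model, AnalysisConfig(rng_seed=1))
        np.testing.assert_allclose(coords, again)


def test_map_clusters_orders_by_burst_count():
    labels = np.array([0, 0, 1, 1, 2, 2])
    counts = np.array([14, 12, 0, 0, 3, 4])
    mapping = map_clusters(labels, counts, None, 3)
    assert mapping == {0: "GMR", 1: "NONE", 2: "IRREGULAR"}


class TestRuleBasedCategory:
    def test_full_segments_are_gmr(self, full_recording, cfg):
        rec, _ = full_recording
        assert segment_categories(rec, cfg) == ["GMR"] * 4

    def test_quiescent_segments_are_none(self, none_recording, cfg):
        rec, _ = none_recording
        assert segment_categories(rec, cfg) == ["NONE"] * 4

    def test_irregular_segments(self, irregular_recording, cfg):
        rec, gt = irregular_recording
        assert segment_categories(rec, cfg) == gt.segment_categories


class TestTransitions:
    def test_none_runs_count_self_transitions(self):
        ts = transition_table([["NONE"] * 4])
        assert ts.counts.loc["NONE", "NONE"] == 3
        assert ts.n_persistent_gmr == 0 and ts.n_with_gmr == 0

    def test_persistent_rhythm_flagged(self):
        ts = transition_table([["GMR"] * 4, ["GMR", "IRREGULAR", "GMR", "GMR"]])
        assert ts.n_persistent_gmr == 1 and ts.n_with_gmr == 2

    def test_direct_gmr_none_transition_recorded_not_error(self):
        ts = transition_table([["GMR", "NONE"]])
        assert ts.counts.loc["GMR", "NONE"] == 1
        assert ts.nonadjacent_transitions == [("GMR", "NONE")]
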