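"""Confidence-weighted population decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from constancy import simulate
from constancy.dataset import DecodingWindow, SpikeDataset
from constancy.decoder import InsufficientDataError, locv_decode
from constancy.population import (
    confidence_weight,
    dimension_timing_permutation,
    peak_time,
    population_decode,
    rank_units_by_decoding,
    roving_population_curve,
    sample_populations,
)


def count_dataset(unit_counts, t0=0.02):
    """Dataset where each unit fires a fixed count per trial (single window).

    ``unit_counts`` maps unit -> list of per-trial spike counts.
    """
    spikes = {
        u: {t: t0 + 0.001 * np.arange(k) for t, k in enumerate(counts)}
        for u, counts in unit_counts.items()
    }
    return SpikeDataset(spikes)


class TestConfidenceWeight:
    def test_equidistant_two_classes_gives_half(self):
        est = confidence_weight([1.0, 1.0], rng=np.random.default_rng(0))
        assert est.w == pytest.approx(0.5)  # lower bound 1 - 1/n

    def test_zero_minimum_distance_gives_full_confidence(self):
        est = confidence_weight([0.0, 5.0])
        assert est.w == 1.0 and est.estimate == 0

    def test_direct_evaluation(self):
        assert confidence_weight([1.0, 3.0]).w == pytest.approx(0.75)

    def test_degenerate_all_zero_distances(self):
        est = confidence_weight([0.0, 0.0, 0.0], rng=np.random.default_rng(1))
        assert est.w == pytest.approx(1 - 1 / 3)
        assert est.estimate in (0, 1, 2)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            confidence_weight([-1.0, 2.0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=8))
    def test_weight_bounds_hold_for_any_distances(self, distances):
        est = confidence_weight(distances, rng=np.random.default_rng(2))
        n = len(distances)
        assert 1 - 1 / n - 1e-12 <= est.w <= 1.0 + 1e-12


class TestPopulationDecode:
    labels = np.repeat(["u", "e"], 10)

    def trials(self):
        return list(range(20))

    def test_single_member_population_equals_that_unit(self):
        counts = {"a": [8] * 10 + [1] * 10}
        ds = count_dataset(counts)
        res = population_decode(ds, ["a"], self.trials(), self.labels, seed=0)
        unit = locv_decode(ds.counts("a", self.trials(), DecodingWindow(0.0, 0.1)),
                           self.labels, seed=0, min_trials_per_class=8)
        assert res.percent_correct == unit.percent_correct
        np.testing.assert_array_equal(res.estimates, unit.estimates)

    def test_higher_confidence_unit_wins_disagreements(self):
        # unit "sharp" separates perfectly (w ~ 1), unit "anti" votes the
        # wrong way but weakly: the population follows "sharp"
        counts = {
            "sharp": [20] * 10 + [0] * 10,
            "anti": [5] * 10 + [6] * 10,
        }
        ds = count_dataset(counts)
        res = population_decode(ds, ["sharp", "anti"], self.trials(), self.labels, seed=0)
        assert res.percent_correct >= 95.0

    def test_three_unit_toy_matches_hand_summed_weights(self):
        counts = {
            "a": [6, 6, 6, 6, 6, 6, 6, 6, 7, 5, 1, 1, 1, 1, 1, 1, 1, 1, 2, 0],
            "b": [3, 4, 3, 4, 3, 4, 3, 4, 3, 4, 4, 3, 4, 3, 4, 3, 4, 3, 4, 3],
            "c": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 5, 6, 5, 6, 5, 6, 5, 6, 5, 6],
        }
        ds = count_dataset(counts)
        window = DecodingWindow(0.0, 0.1)
        res = population_decode(ds, ["a", "b", "c"], self.trials(), self.labels,
                                window, seed=0)
        # independent hand computation: LOO templates, sqrt distances, Eq. 1
        classes = np.array(["e", "u"])  # np.unique order
        y = np.array([1] * 10 + [0] * 10)
        expected_weights = np.zeros((20, 2))
        for u in ("a", "b", "c"):
            X = np.array(counts[u], dtype=float)
            for i in range(20):
                d = []
                for ci in range(2):
                    rows = [j for j in range(20) if y[j] == ci and j != i]
                    template = np.mean([X[j] for j in rows])
                    d.append(abs(X[i] - template))
                d = np.array(d)
                w = 1 - d.min() / d.sum() if d.sum() > 0 else 0.5
                expected_weights[i, int(np.argmin(d))] += w
        np.testing.assert_allclose(res.class_weights, expected_weights, atol=1e-12)

    def test_population_of_identical_copies_decodes_as_one_unit(self):
        counts = {f"c{i}": [7] * 10 + [2] * 10 for i in range(3)}
        ds = count_dataset(counts)
        res3 = population_decode(ds, list(counts), self.trials(), self.labels, seed=0)
        res1 = population_decode(ds, ["c0"], self.trials(), self.labels, seed=0)
        assert res3.percent_correct == res1.percent_correct

    def test_trials_per_class_floor_enforced(self):
        counts = {"a": [5] * 7 + [1] * 7}
        ds = count_dataset(counts)
        with pytest.raises(InsufficientDataError):
            population_decode(ds, ["a"], list(range(14)), np.repeat(["u", "e"], 7), seed=0)


class TestSamplePopulations:
    def test_all_combinations_enumerated_when_few(self):
        combos = sample_populations(["a", "b", "c"], 2, n_combos=100, seed=0)
        assert sorted(combos) == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_sampled_combinations_are_unique(self):
        combos = sample_populations(list(range(20)), 5, n_combos=50, seed=1)
        assert len(combos) == 50 and len(set(combos)) == 50
        assert all(len(set(c)) == 5 for c in combos)

    def test_pool_smaller_than_size_rejected(self):
        with pytest.raises(ValueError):
            sample_populations(["a"], 2)


class TestRovingCurve:
    def test_early_kernel_population_peaks_near_onset(self, f0_trials):
        test = f0_trials[f0_trials.trial_type == "test"]
        pop = {f"u{i}": simulate.tuned_unit("vowel", {"u": 25.0, "e": 0.0},
                                           latency=0.01, duration=0.1)
               for i in range(5)}
        ds = simulate.generate_dataset(pop, f0_trials, seed=81)
        curve = roving_population_curve(ds, list(pop), test.trial_id.tolist(),
                                        test.vowel.to_numpy(), seed=0)
        assert peak_time(curve) < 0.3

    def test_flat_null_population_stays_near_chance(self, f0_trials):
        test = f0_trials[f0_trials.trial_type == "test"]
        pop = {f"u{i}": simulate.untuned_unit(10.0) for i in range(5)}
        ds = simulate.generate_dataset(pop, f0_trials, seed=82)
        curve = roving_population_curve(ds, list(pop), test.trial_id.tolist(),
                                        test.vowel.to_numpy(), seed=0)
        assert abs(curve.percent_correct.mean() - 50.0) < 12.0

    def test_peak_time_is_center_of_unique_maximum(self):
        curve = pd.DataFrame({"center": [0.05, 0.10, 0.15],
                              "percent_correct": [60.0, 80.0, 70.0]})
        assert peak_time(curve) == 0.10


class TestDimensionTimingPermutation:
    def test_identical_groups_are_exchangeable(self):
        times = [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]
        dims = ["f0"] * 3 + ["voicing"] * 3
        res = dimension_timing_permutation(times, dims, n_iter=2000, seed=0)
        assert res.p.iloc[0] > 0.5

    def test_strongly_shifted_groups_give_small_p(self):
        rng = np.random.default_rng(1)
        times = np.concatenate([rng.normal(0.1, 0.01, 20), rng.normal(0.5, 0.01, 20)])
        dims = ["f0"] * 20 + ["voicing"] * 20
        res = dimension_timing_permutation(times, dims, n_iter=2000, seed=2)
        assert res.p.iloc[0] <= 1e-3

    def test_all_pairs_reported(self):
        times = np.arange(9, dtype=float)
        dims = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = dimension_timing_permutation(times, dims, n_iter=100, seed=3)
        assert len(res) == 3


class TestRanking:
    def test_ranking_orders_by_single_unit_performance(self):
        counts = {
            "weak": [5, 4, 5, 4, 5, 4, 5, 4, 5, 4, 4, 5, 4, 5, 4, 5, 4, 5, 4, 5],
            "strong": [9] * 10 + [1] * 10,
        }
        ds = count_dataset(counts)
        ranking = rank_units_by_decoding(ds, list(counts), list(range(20)),
                                         np.repeat(["u", "e"], 10), seed=0)
        assert ranking.unit_id.iloc[0] == "strong"
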