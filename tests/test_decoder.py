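"""Unit decoder: binning, LOCV decoding, window grids and surfaces."""

import numpy as np
import pytest

from constancy import simulate
from constancy.dataset import DecodingWindow, SpikeDataset, bin_spikes
from constancy.decoder import (
    InsufficientDataError,
    SurfaceDecoder,
    _TIE_RTOL,
    classify_sound_responsive,
    locv_decode,
    make_window_grid,
)

from conftest import make_dataset


def brute_force_locv(X, labels, rng):
    """Independent enumeration of every leave-one-out distance.

    Follows the decoder's tie contract: trials processed in ascending
    order, each tied trial consuming one rng.integers draw.
    """
    X = np.asarray(X, dtype=float)
    classes = np.unique(labels)
    n = len(labels)
    d2 = np.zeros((n, len(classes)))
    for i in range(n):
        for ci, c in enumerate(classes):
            rows = [j for j in range(n) if labels[j] == c and j != i]
            template = np.mean([X[j] for j in rows], axis=0)
            d2[i, ci] = float(np.sum((X[i] - template) ** 2))
    est = []
    for i in range(n):
        dmin = d2[i].min()
        tol = _TIE_RTOL * max(dmin, 1.0)
        tied = np.flatnonzero(d2[i] <= dmin + tol)
        if len(tied) > 1:
            est.append(classes[tied[rng.integers(len(tied))]])
        else:
            est.append(classes[tied[0]])
    est = np.asarray(est)
    return d2, est, 100.0 * float(np.mean(est == np.asarray(labels)))


class TestBinning:
    def test_counts_per_bin(self):
        w = DecodingWindow(0.0, 0.2)
        np.testing.assert_array_equal(bin_spikes([0.05, 0.15], w, 0.1), [1, 1])

    def test_no_spikes_zero_vector(self):
        np.testing.assert_array_equal(bin_spikes([], DecodingWindow(0.0, 0.2), 0.1), [0, 0])

    def test_half_open_excludes_window_end(self):
        w = DecodingWindow(0.0, 0.2)
        assert bin_spikes([0.2], w, 0.1).sum() == 0
        assert bin_spikes([0.0], w, 0.1).sum() == 1  # start included

    def test_vector_length_rounds(self):
        assert len(bin_spikes([], DecodingWindow(0.0, 0.25), 0.01)) == 25


class TestLocvDecode:
    def test_disjoint_noiseless_responses_are_perfect(self):
        X = np.vstack([np.tile([5.0, 0.0], (5, 1)), np.tile([0.0, 5.0], (5, 1))])
        y = ["a"] * 5 + ["b"] * 5
        assert locv_decode(X, y, seed=0).percent_correct == 100.0

    def test_class_floor_enforced_and_liftable(self):
        X = np.arange(8, dtype=float).reshape(8, 1)
        y = ["a"] * 4 + ["b"] * 4
        with pytest.raises(InsufficientDataError):
            locv_decode(X, y, seed=0)
        locv_decode(X, y, seed=0, min_trials_per_class=4)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            locv_decode(np.empty((6, 0)), ["a", "a", "a", "b", "b", "b"], seed=0)

    def test_confusion_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(2.0, size=(20, 5)).astype(float)
        y = np.repeat(["a", "b"], 10)
        res = locv_decode(X, y, seed=1)
        assert res.confusion.sum(axis=1).tolist() == [10, 10]

    @pytest.mark.parametrize("n_classes,n_per,n_bins", [(2, 3, 1), (2, 4, 3), (3, 3, 2), (3, 4, 3)])
    def test_matches_brute_force_enumeration(self, n_classes, n_per, n_bins):
        """Oracle equivalence on small toys, including tied distances."""
        rng = np.random.default_rng(17 + n_classes * 10 + n_per + n_bins)
        X = rng.poisson(1.5, size=(n_classes * n_per, n_bins)).astype(float)
        y = np.repeat([f"c{i}" for i in range(n_classes)], n_per)
        res = locv_decode(X, y, seed=np.random.default_rng(99), min_trials_per_class=2)
        d2, est, pct = brute_force_locv(X, y, np.random.default_rng(99))
        np.testing.assert_array_equal(res.estimates, est)
        assert res.percent_correct == pct

    def test_hand_worked_three_trials_per_class(self):
        # two classes, one bin: counts a=(0,1,2), b=(4,5,6); all LOO
        # templates keep the classes separated, so every trial is recovered
        X = np.array([[0.0], [1.0], [2.0], [4.0], [5.0], [6.0]])
        y = ["a"] * 3 + ["b"] * 3
        res = locv_decode(X, y, seed=0, min_trials_per_class=3)
        assert res.percent_correct == 100.0

    def test_seeded_decode_is_reproducible(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(0.3, size=(12, 2)).astype(float)  # sparse -> many ties
        y = np.repeat(["a", "b"], 6)
        a = locv_decode(X, y, seed=42)
        b = locv_decode(X, y, seed=42)
        np.testing.assert_array_equal(a.estimates, b.estimates)
        assert a.percent_correct == b.percent_correct

    def test_chance_under_label_shuffling(self):
        """Shuffled labels give ~100/n_classes percent correct."""
        rng = np.random.default_rng(8)
        X2 = rng.poisson(0.15, size=(100, 25)).astype(float)
        vals2 = [
            locv_decode(X2, rng.permutation(np.repeat(["a", "b"], 50)), seed=rng).percent_correct
            for _ in range(60)
        ]
        assert abs(np.mean(vals2) - 50.0) < 4.0
        vals5 = [
            locv_decode(
                X2, rng.permutation(np.repeat(list("abcde"), 20)), seed=rng
            ).percent_correct
            for _ in range(60)
        ]
        assert abs(np.mean(vals5) - 20.0) < 4.0

    def test_duplicated_informative_bin_never_hurts_noiseless_data(self):
        X = np.vstack([np.tile([3.0, 1.0], (5, 1)), np.tile([1.0, 3.0], (5, 1))])
        y = ["a"] * 5 + ["b"] * 5
        base = locv_decode(X, y, seed=0).percent_correct
        X_dup = np.hstack([X, X[:, [0]]])
        assert locv_decode(X_dup, y, seed=0).percent_correct >= base


class TestWindowGrid:
    def test_default_grid_has_1550_windows(self):
        grid = make_window_grid()
        assert len(grid) == 1550
        starts = sorted({w.start for w in grid})
        durs = sorted({w.duration for w in grid})
        assert (starts[0], starts[-1]) == (-0.5, 1.0) and len(starts) == 31
        assert (durs[0], durs[-1]) == (0.01, 0.5) and len(durs) == 50

    def test_coarse_start_step_gives_800(self):
        assert len(make_window_grid(start_step=0.1)) == 800

    def test_degenerate_grid_is_one_window(self):
        assert make_window_grid(0.0, 0.0, 0.1, 0.1, 0.1, 0.1) == [DecodingWindow(0.0, 0.1)]


class TestSurface:
    def test_flat_surface_tie_breaks_to_earliest_shortest(self, reduced_grid):
        # class "a" fires densely everywhere, class "b" is silent: every
        # window separates perfectly, so the tie-break decides
        dense = np.round(np.arange(-0.5, 1.5, 0.002), 6)
        spikes = {t: (dense if t < 5 else []) for t in range(10)}
        ds = make_dataset(spikes)
        surf = SurfaceDecoder(ds, "u0", list(range(10)), reduced_grid, 0.1).decode(
            ["a"] * 5 + ["b"] * 5, seed=0
        )
        assert surf.best_performance == 100.0
        assert surf.best_window == DecodingWindow(-0.1, 0.1)

    def test_best_cell_is_max_of_grid(self, reduced_grid, f0_trials):
        test = f0_trials[f0_trials.trial_type == "test"]
        pop = {"u0": simulate.tuned_unit("vowel", {"u": 20.0, "e": 0.0})}
        ds = simulate.generate_dataset(pop, f0_trials, seed=21)
        surf = SurfaceDecoder(ds, "u0", test.trial_id.tolist(), reduced_grid, 0.01).decode(
            test.vowel.to_numpy(), seed=0
        )
        assert surf.best_performance == surf.table.percent_correct.max()
        assert surf.performance_at(surf.best_window) == surf.best_performance

    def test_early_kernel_unit_best_window_overlaps_kernel(self, reduced_grid, f0_trials):
        test = f0_trials[f0_trials.trial_type == "test"]
        pop = {"u0": simulate.tuned_unit("vowel", {"u": 40.0, "e": 0.0},
                                         latency=0.0, duration=0.1, baseline_rate=2.0)}
        ds = simulate.generate_dataset(pop, f0_trials, seed=22)
        surf = SurfaceDecoder(ds, "u0", test.trial_id.tolist(), reduced_grid, 0.01).decode(
            test.vowel.to_numpy(), seed=0
        )
        w = surf.best_window
        assert w.start < 0.1 and w.end > 0.0  # overlaps the [0, 0.1] s kernel


class TestSoundResponsive:
    def test_strong_onset_unit_is_responsive(self, two_class_trials):
        test = two_class_trials[two_class_trials.trial_type == "test"]
        pop = {"u0": simulate.tuned_unit("vowel", {"u": 30.0, "e": 30.0},
                                         latency=0.0, duration=0.3)}
        ds = simulate.generate_dataset(pop, two_class_trials, seed=31)
        assert classify_sound_responsive(ds, "u0", test.trial_id.tolist())

    def test_identical_windows_not_responsive(self, two_class_trials):
        test = two_class_trials[two_class_trials.trial_type == "test"]
        ds = simulate.generate_dataset({"u0": simulate.untuned_unit(10.0)},
                                       two_class_trials, seed=32)
        w = DecodingWindow(0.0, 0.3)
        assert not classify_sound_responsive(ds, "u0", test.trial_id.tolist(),
                                             baseline_window=w, evoked_window=w)

    def test_null_units_flagged_near_nominal_rate(self):
        """Type-I control of the responsiveness screen on untuned units."""
        rng = np.random.default_rng(7)
        flagged = 0
        n_units = 150
        for _ in range(n_units):
            spikes = {t: np.sort(rng.uniform(-0.5, 1.5, rng.poisson(30))) for t in range(40)}
            ds = make_dataset(spikes)
            flagged += classify_sound_responsive(ds, "u0", list(range(40)))
        assert flagged / n_units <= 0.12
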