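"""Single-unit spike-distance decoding with leave-one-out cross-validation.

The decoder bins each trial's spikes within a response window, builds one
template per stimulus class as the mean PSTH over all *other* trials, and
assigns the test trial to the class whose template lies at the smallest
Euclidean distance.  Equidistant templates are resolved by a seeded random
guess.  Performance is the percentage of trials whose label is recovered.

Window optimization runs the decoder over an exhaustive grid of (start,
duration) windows; ties in best performance go to the earliest start and
then the shortest duration.

Tie-break contract (relied on by brute-force equivalence tests): trials
with tied minimum distance are resolved in increasing trial order, each
consuming one ``rng.integers(n_tied)`` draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DecodingWindow, SpikeDataset

__all__ = [
    "DecodeResult",
    "PerformanceSurface",
    "InsufficientDataError",
    "classify_sound_responsive",
    "locv_decode",
    "decode_window",
    "make_window_grid",
    "decode_surface",
    "SurfaceDecoder",
]

#: relative tolerance for declaring two squared distances tied
_TIE_RTOL = 1e-9


class InsufficientDataError(ValueError):
    """Raised when a class has fewer trials than the decoder floor."""


@dataclass
class DecodeResult:
    """Outcome of one leave-one-out decode."""

    percent_correct: float
    estimates: np.ndarray  # per-trial estimated class labels
    labels: np.ndarray  # true labels, same order
    classes: np.ndarray
    confusion: pd.DataFrame  # rows = true class, cols = estimated class
    n_trials_per_class: dict
    window: DecodingWindow | None = None
    bin_width: float | None = None


@dataclass
class PerformanceSurface:
    """Decoding performance over a window grid, with its best cell."""

    table: pd.DataFrame  # columns: start, duration, percent_correct
    best_window: DecodingWindow
    best_performance: float

    def performance_at(self, window: DecodingWindow) -> float:
        t = self.table
        row = t[(t["start"] == window.start) & (t["duration"] == window.duration)]
        return float(row["percent_correct"].iloc[0])


def classify_sound_responsive(
    dataset: SpikeDataset,
    unit,
    trials: Sequence,
    baseline_window: DecodingWindow = DecodingWindow(-0.3, 0.3),
    evoked_window: DecodingWindow = DecodingWindow(0.0, 0.3),
    alpha: float = 0.05,
) -> bool:
    """Paired sign-rank test of evoked vs baseline per-trial spike counts.

    A unit is sound-responsive when the count in the 300 ms after first-token
    onset differs significantly (p < alpha) from the 300 ms of spontaneous
    activity before it.  All-zero differences (e.g., identical windows) are
    not responsive.
    """
    evoked = dataset.count_in(unit, trials, evoked_window)
    base = dataset.count_in(unit, trials, baseline_window)
    diffs = evoked - base
    if not np.any(diffs):
        return False
    p = stats.wilcoxon(evoked, base).pvalue
    return bool(p < alpha)


def _class_index(labels: np.ndarray):
    classes, y = np.unique(labels, return_inverse=True)
    counts = np.bincount(y, minlength=len(classes))
    return classes, y, counts


def _loo_sqdist(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """(n_trials, n_classes) squared distances to leave-one-out mean templates.

    For the test trial's own class the template excludes that trial; other
    classes use all their trials.
    """
    n, b = X.shape
    counts = np.bincount(y, minlength=n_classes).astype(float)
    sums = np.zeros((n_classes, b))
    np.add.at(sums, y, X)
    base_templates = sums / counts[:, None]
    diff = X[:, None, :] - base_templates[None, :, :]
    d2 = np.einsum("ncb,ncb->nc", diff, diff)
    # replace each trial's own-class column with the held-out template distance
    own_counts = counts[y]
    if np.any(own_counts < 2):
        raise InsufficientDataError("leave-one-out needs >= 2 trials per class")
    own_templates = (sums[y] - X) / (own_counts - 1)[:, None]
    own_diff = X - own_templates
    d2[np.arange(n), y] = np.einsum("nb,nb->n", own_diff, own_diff)
    return d2


def _argmin_with_ties(d2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmin; tied rows resolved in order via one rng draw each."""
    dmin = d2.min(axis=1)
    tol = _TIE_RTOL * np.maximum(dmin, 1.0)
    tied = d2 <= (dmin + tol)[:, None]
    est = np.argmin(d2, axis=1)
    multi = np.flatnonzero(tied.sum(axis=1) > 1)
    for i in multi:
        options = np.flatnonzero(tied[i])
        est[i] = options[rng.integers(len(options))]
    return est


def locv_decode(
    responses: np.ndarray,
    labels: Sequence,
    *,
    seed: int | np.random.Generator | None = None,
    min_trials_per_class: int = 5,
    window: DecodingWindow | None = None,
    bin_width: float | None = None,
) -> DecodeResult:
    """Leave-one-out spike-distance decode of a binned response matrix.

    Parameters
    ----------
    responses
        (n_trials, n_bins) spike counts within the decoding window.
    labels
        Per-trial class labels (same order as rows).
    min_trials_per_class
        Floor on trials per class (the study used 5); pass 1 or 2 to lift it
        for toy problems.
    """
    X = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("responses must be (n_trials, n_bins) matching labels")
    if X.shape[1] == 0:
        raise ValueError("empty decoding window (no bins)")
    classes, y, counts = _class_index(labels)
    if len(classes) < 2:
        raise InsufficientDataError("need at least two classes to decode")
    if counts.min() < max(2, min_trials_per_class):
        bad = classes[int(np.argmin(counts))]
        raise InsufficientDataError(
            f"class {bad!r} has {counts.min()} trials; floor is {min_trials_per_class}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2 = _loo_sqdist(X, y, len(classes))
    est = _argmin_with_ties(d2, rng)
    correct = est == y
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for yi, ei in zip(y, est):
        confusion.iloc[yi, ei] += 1
    return DecodeResult(
        percent_correct=100.0 * float(np.mean(correct)),
        estimates=classes[est],
        labels=labels,
        classes=classes,
        confusion=confusion,
        n_trials_per_class={c: int(n) for c, n in zip(classes, counts)},
        window=window,
        bin_width=bin_width,
    )


def decode_window(
    dataset: SpikeDataset,
    unit,
    trials: Sequence,
    labels: Sequence,
    window: DecodingWindow,
    bin_width: float | None = 0.01,
    seed=None,
    min_trials_per_class: int = 5,
) -> DecodeResult:
    """Convenience wrapper: bin one unit's trials, then LOCV-decode."""
    X = dataset.counts(unit, trials, window, bin_width)
    return locv_decode(
        X,
        labels,
        seed=seed,
        min_trials_per_class=min_trials_per_class,
        window=window,
        bin_width=bin_width,
    )


def make_window_grid(
    start_min: float = -0.5,
    start_max: float = 1.0,
    start_step: float = 0.05,
    dur_min: float = 0.01,
    dur_max: float = 0.5,
    dur_step: float = 0.01,
) -> list[DecodingWindow]:
    """Cartesian grid of decoding windows, inclusive of both endpoints.

    Defaults give 31 start times x 50 durations = 1550 windows.  A 0.1 s
    start step (16 x 50 = 800) is also supported.
    """
    n_starts = int(round((start_max - start_min) / start_step)) + 1
    n_durs = int(round((dur_max - dur_min) / dur_step)) + 1
    starts = np.round(start_min + start_step * np.arange(n_starts), 10)
    durs = np.round(dur_min + dur_step * np.arange(n_durs), 10)
    return [DecodingWindow(float(s), float(d)) for s in starts for d in durs]


class SurfaceDecoder:
    """Grid decoder with cached binned responses.

    Binning every window once and reusing the cache makes label-shuffle
    permutation tests (which re-optimize the window per shuffle) cheap.
    """

    def __init__(
        self,
        dataset: SpikeDataset,
        unit,
        trials: Sequence,
        grid: Sequence[DecodingWindow],
        bin_width: float | None = 0.01,
        min_trials_per_class: int = 5,
    ):
        self.grid = list(grid)
        self.bin_width = bin_width
        self.min_trials_per_class = min_trials_per_class
        self.trials = list(trials)
        self._binned = [dataset.counts(unit, self.trials, w, bin_width) for w in self.grid]

    def decode(self, labels: Sequence, seed=None) -> PerformanceSurface:
        labels = np.asarray(labels)
        classes, y, counts = _class_index(labels)
        if len(classes) < 2:
            raise InsufficientDataError("need at least two classes to decode")
        if counts.min() < max(2, self.min_trials_per_class):
            bad = classes[int(np.argmin(counts))]
            raise InsufficientDataError(
                f"class {bad!r} has {counts.min()} trials; "
                f"floor is {self.min_trials_per_class}"
            )
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perf = np.empty(len(self.grid))
        for k, X in enumerate(self._binned):
            d2 = _loo_sqdist(X, y, len(classes))
            est = _argmin_with_ties(d2, rng)
            perf[k] = 100.0 * float(np.mean(est == y))
        table = pd.DataFrame(
            {
                "start": [w.start for w in self.grid],
                "duration": [w.duration for w in self.grid],
                "percent_correct": perf,
            }
        )
        best = _best_cell(self.grid, perf)
        return PerformanceSurface(table=table, best_window=best, best_performance=float(perf.max()))


def _best_cell(grid: Sequence[DecodingWindow], perf: np.ndarray) -> DecodingWindow:
    """Max performance; ties -> earliest start, then shortest duration."""
    best = perf.max()
    candidates = [w for w, p in zip(grid, perf) if p == best]
    return min(candidates, key=lambda w: (w.start, w.duration))


def decode_surface(
    dataset: SpikeDataset,
    unit,
    trials: Sequence,
    labels: Sequence,
    grid: Sequence[DecodingWindow],
    bin_width: float | None = 0.01,
    seed=None,
    min_trials_per_class: int = 5,
) -> PerformanceSurface:
    """One LOCV decode per grid window; best cell via the lexicographic tie-break."""
    dec = SurfaceDecoder(dataset, unit, trials, grid, bin_width, min_trials_per_class)
    return dec.decode(labels, seed=seed)
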