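"""Confidence-weighted population decoding.

Each unit decodes every trial with the same leave-one-out spike-distance
rule as the single-unit decoder, but additionally reports a confidence
weight

    w = 1 - d_min / sum_j d_j,

where the d_j are the (Euclidean) spike distances from the test trial to
the n class templates and d_min is the smallest.  w is bounded in
[1 - 1/n, 1]: equidistant templates give exactly 1 - 1/n, a zero distance
to the nearest template gives 1.  The population estimate on a trial is
the class with the largest summed weight across member units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import DecodingWindow, SpikeDataset
from .decoder import InsufficientDataError, _class_index, _loo_sqdist

__all__ = [
    "UnitEstimate",
    "PopulationDecodeResult",
    "confidence_weight",
    "population_decode",
    "sample_populations",
    "rank_units_by_decoding",
    "roving_population_curve",
    "dimension_timing_permutation",
]


@dataclass
class UnitEstimate:
    """One unit's estimate on one trial: class index, confidence, distances."""

    estimate: int
    w: float
    distances: np.ndarray
    d_min: float
    n_classes: int


def confidence_weight(distances: Sequence[float], rng=None) -> UnitEstimate:
    """Estimate (argmin distance) and confidence weight for one trial.

    All-zero distances are degenerate: the estimate is a seeded uniform
    draw and w takes its lower bound 1 - 1/n.
    """
    d = np.asarray(distances, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least two class distances")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    total = d.sum()
    if total == 0:
        return UnitEstimate(int(rng.integers(n)), 1 - 1 / n, d, 0.0, n)
    dmin = float(d.min())
    tied = np.flatnonzero(d <= dmin * (1 + 1e-12))
    est = int(tied[rng.integers(len(tied))]) if len(tied) > 1 else int(tied[0])
    return UnitEstimate(est, float(1 - dmin / total), d, dmin, n)


@dataclass
class PopulationDecodeResult:
    percent_correct: float
    estimates: np.ndarray  # per-trial population estimates (labels)
    class_weights: np.ndarray  # (n_trials, n_classes) summed weights
    classes: np.ndarray
    members: list
    window: DecodingWindow


def population_decode(
    dataset: SpikeDataset,
    units: Sequence,
    trials: Sequence,
    labels: Sequence,
    window: DecodingWindow = DecodingWindow(0.0, 0.1),
    bin_width: float | None = None,
    seed=None,
    min_trials_per_class: int = 8,
) -> PopulationDecodeResult:
    """Leave-one-out confidence-weighted population decode of one window.

    Every member unit must have at least ``min_trials_per_class`` trials
    per class (the study floor was 8 per vowel; correct and error trials
    are both included).  Within the window the default response vector is
    the single-bin spike count; pass ``bin_width`` for a time-varying
    pattern.
    """
    labels = np.asarray(labels)
    classes, y, counts = _class_index(labels)
    if counts.min() < min_trials_per_class:
        bad = classes[int(np.argmin(counts))]
        raise InsufficientDataError(
            f"class {bad!r} has {counts.min()} trials; floor is {min_trials_per_class}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = list(trials)
    n, C = len(trials), len(classes)
    weights = np.zeros((n, C))
    for unit in units:
        X = dataset.counts(unit, trials, window, bin_width)
        d = np.sqrt(_loo_sqdist(X, y, C))
        totals = d.sum(axis=1)
        dmin = d.min(axis=1)
        w = np.where(totals > 0, 1 - dmin / np.where(totals > 0, totals, 1.0), 1 - 1 / C)
        # per-unit estimate: argmin distance, seeded guess among ties
        tied = d <= (dmin * (1 + 1e-12) + 1e-15)[:, None]
        est = np.argmin(d, axis=1)
        for i in np.flatnonzero(tied.sum(axis=1) > 1):
            opts = np.flatnonzero(tied[i])
            est[i] = opts[rng.integers(len(opts))]
        degenerate = totals == 0
        for i in np.flatnonzero(degenerate):
            est[i] = rng.integers(C)
        weights[np.arange(n), est] += w
    pop_est = np.empty(n, dtype=int)
    for i in range(n):
        row = weights[i]
        top = np.flatnonzero(row == row.max())
        pop_est[i] = top[rng.integers(len(top))] if len(top) > 1 else top[0]
    pct = 100.0 * float(np.mean(pop_est == y))
    return PopulationDecodeResult(
        percent_correct=pct,
        estimates=classes[pop_est],
        class_weights=weights,
        classes=classes,
        members=list(units),
        window=window,
    )


def rank_units_by_decoding(
    dataset: SpikeDataset,
    units: Sequence,
    trials: Sequence,
    labels: Sequence,
    window: DecodingWindow = DecodingWindow(0.0, 0.1),
    bin_width: float | None = None,
    seed=None,
    min_trials_per_class: int = 8,
) -> pd.DataFrame:
    """Units ranked (descending) by single-unit LOCV performance.

    Used to form the pool of best vowel decoders on correct trials from
    which population combinations are sampled.
    """
    from .decoder import locv_decode

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for unit in units:
        X = dataset.counts(unit, list(trials), window, bin_width)
        res = locv_decode(X, labels, seed=rng, min_trials_per_class=min_trials_per_class)
        rows.append((unit, res.percent_correct))
    df = pd.DataFrame(rows, columns=["unit_id", "percent_correct"])
    return df.sort_values("percent_correct", ascending=False, kind="stable").reset_index(drop=True)


def sample_populations(
    pool: Sequence,
    size: int,
    n_combos: int = 100,
    seed=None,
) -> list[tuple]:
    """Sample unit combinations of a given size from the ranked pool.

    Combinations are drawn without replacement within each combination and
    are unique across combinations where the pool permits (all distinct
    combinations are enumerated when fewer than ``n_combos`` exist).
    """
    pool = list(pool)
    if size > len(pool):
        raise ValueError(f"population size {size} exceeds pool of {len(pool)}")
    total = comb(len(pool), size)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if total <= n_combos:
        return [tuple(pool[i] for i in idx) for idx in combinations(range(len(pool)), size)]
    seen: set = set()
    out: list[tuple] = []
    while len(out) < n_combos:
        idx = tuple(sorted(rng.choice(len(pool), size=size, replace=False)))
        if idx in seen:
            continue
        seen.add(idx)
        out.append(tuple(pool[i] for i in idx))
    return out


def roving_population_curve(
    dataset: SpikeDataset,
    units: Sequence,
    trials: Sequence,
    labels: Sequence,
    window_length: float = 0.1,
    step: float = 0.05,
    t_start: float = -0.1,
    t_end: float = 1.0,
    seed=None,
    min_trials_per_class: int = 8,
) -> pd.DataFrame:
    """Population performance vs roving-window center time.

    The returned frame has columns center and percent_correct; the peak
    time is the center of the first window attaining the maximum.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round((t_end - t_start - window_length) / step)) + 1
    rows = []
    for k in range(max(0, n_steps)):
        w = DecodingWindow(float(t_start + k * step), window_length)
        res = population_decode(
            dataset, units, trials, labels, w, seed=rng,
            min_trials_per_class=min_trials_per_class,
        )
        rows.append((w.center, res.percent_correct))
    return pd.DataFrame(rows, columns=["center", "percent_correct"])


def peak_time(curve: pd.DataFrame) -> float:
    """Center time of the (first) maximum of a roving performance curve."""
    best = curve["percent_correct"].max()
    return float(curve.loc[curve["percent_correct"] == best, "center"].iloc[0])


def dimension_timing_permutation(
    peak_times: Sequence[float],
    dimensions: Sequence,
    n_iter: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Two-sided permutation test on differences of mean peak times.

    For each pair of orthogonal dimensions the statistic is the difference
    of mean peak times; the null shuffles which dimension each population
    was drawn from.  Returns one row per pair with observed difference and p.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(peak_times, dtype=float)
    dims = np.asarray(dimensions)
    rows = []
    for a, b in combinations(pd.unique(dims), 2):
        mask = (dims == a) | (dims == b)
        t = times[mask]
        is_a = (dims[mask] == a)
        n_a = int(is_a.sum())
        observed = t[is_a].mean() - t[~is_a].mean()
        null = np.empty(n_iter)
        for i in range(n_iter):
            perm = rng.permutation(len(t))
            sel = np.zeros(len(t), dtype=bool)
            sel[perm[:n_a]] = True
            null[i] = t[sel].mean() - t[~sel].mean()
        p = float(np.mean(np.abs(null) >= abs(observed)))
        rows.append((a, b, float(observed), p))
    return pd.DataFrame(rows, columns=["dim_a", "dim_b", "mean_diff", "p"])
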