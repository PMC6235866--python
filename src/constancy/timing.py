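"""Temporal multiplexing and engagement analyses.

The timing statistic throughout is the *center time* of the best decoding
window (start + duration/2).  Paired groups (the same units decoded for
two features, or the same units engaged vs passive) are compared with the
Wilcoxon sign-rank test and summarized by the median paired difference;
unpaired groups use the rank-sum test and the difference of medians.
Three or more groups use Kruskal-Wallis with Tukey-Kramer-corrected
post-hoc comparisons on mean ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .dataset import DecodingWindow, SpikeDataset
from .decoder import SurfaceDecoder, decode_surface

__all__ = [
    "TimingComparison",
    "center_time",
    "empirical_cdf",
    "compare_timing",
    "kruskal_tukey",
    "roving_rate",
    "normalize_to_baseline",
    "engaged_passive_contrast",
]


@dataclass
class TimingComparison:
    """Outcome of a timing contrast between feature groups.

    ``delta_t`` follows the convention first group minus second group:
    median paired difference when paired, difference of medians otherwise.
    """

    group_names: tuple
    delta_t: float
    test: str
    p: float
    statistic: float | None = None
    posthoc: pd.DataFrame | None = None


def center_time(window: DecodingWindow) -> float:
    """Center of a decoding window: start + duration/2."""
    return window.center


def empirical_cdf(values: Sequence[float]) -> ECDF:
    """Right-continuous empirical CDF (reaches 1 at the largest value)."""
    return ECDF(np.asarray(values, dtype=float))


def compare_timing(
    groups: Mapping[object, Sequence[float]],
    paired: bool = False,
) -> TimingComparison:
    """Compare center times between groups with the convention-matched test.

    Two paired groups -> sign-rank on differences, delta = median(a - b);
    two unpaired -> rank-sum, delta = median(a) - median(b); three or more
    -> Kruskal-Wallis omnibus with Tukey-Kramer post-hoc on mean ranks
    (delta_t is NaN for the omnibus).
    """
    names = tuple(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if len(arrays) == 2:
        a, b = arrays
        if paired:
            if len(a) != len(b):
                raise ValueError("paired comparison requires identical unit sets")
            diffs = a - b
            delta = float(np.median(diffs))
            if not np.any(diffs):
                return TimingComparison(names, 0.0, "sign-rank", 1.0, 0.0)
            res = stats.wilcoxon(a, b)
            return TimingComparison(names, delta, "sign-rank", float(res.pvalue), float(res.statistic))
        delta = float(np.median(a) - np.median(b))
        res = stats.ranksums(a, b)
        return TimingComparison(names, delta, "rank-sum", float(res.pvalue), float(res.statistic))
    stat, p = stats.kruskal(*arrays)
    posthoc = kruskal_tukey(groups)
    return TimingComparison(names, float("nan"), "kruskal-wallis", float(p), float(stat), posthoc)


def kruskal_tukey(groups: Mapping[object, Sequence[float]]) -> pd.DataFrame:
    """Tukey-Kramer-corrected pairwise comparisons of mean ranks.

    Follows the usual post-hoc after Kruskal-Wallis: the pooled sample is
    ranked, group mean ranks are compared with the studentized-range
    distribution using SE = sqrt(N(N+1)/12 * (1/ni + 1/nj)), infinite
    degrees of freedom.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    k = len(arrays)
    mean_ranks, sizes = [], []
    pos = 0
    for arr in arrays:
        mean_ranks.append(ranks[pos : pos + len(arr)].mean())
        sizes.append(len(arr))
        pos += len(arr)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(n_total * (n_total + 1) / 12 * (1 / sizes[i] + 1 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / (se / np.sqrt(2))
            p = float(stats.studentized_range.sf(q, k, np.inf))
            rows.append((names[i], names[j], mean_ranks[i] - mean_ranks[j], p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_rank_diff", "p"])


def roving_rate(
    dataset: SpikeDataset,
    unit,
    trials: Sequence,
    bin: float = 0.1,
    step: float = 0.05,
    t_start: float = 0.0,
    t_end: float = 1.0,
) -> pd.DataFrame:
    """Mean firing rate (Hz across trials) in roving bins after onset.

    Returns a frame with bin centers and rates; default 100 ms bins at
    50 ms intervals give centers 0.05, 0.10, ...
    """
    n_steps = int(round((t_end - t_start - bin) / step)) + 1
    starts = t_start + step * np.arange(max(0, n_steps))
    rows = []
    for s in starts:
        w = DecodingWindow(float(s), bin)
        rows.append((w.center, float(np.mean(dataset.rate_in(unit, trials, w)))))
    return pd.DataFrame(rows, columns=["center", "rate_hz"])


def normalize_to_baseline(
    rates: Sequence[float],
    baseline: float,
    mode: str = "ratio",
) -> np.ndarray:
    """Rates relative to a pre-stimulus baseline rate.

    ``mode="ratio"`` (default) divides; ``mode="difference"`` subtracts.
    A zero baseline makes the ratio undefined: returns all-NaN so the unit
    can be excluded (and logged) by the caller.
    """
    rates = np.asarray(rates, dtype=float)
    if mode == "ratio":
        if baseline == 0:
            return np.full_like(rates, np.nan)
        return rates / baseline
    if mode == "difference":
        return rates - baseline
    raise ValueError("mode must be 'ratio' or 'difference'")


@dataclass
class EngagedPassiveContrast:
    rate_delta: float  # median engaged - passive rate
    rate_p: float
    rate_z: float
    perf_delta: float  # median engaged - passive percent correct
    perf_p: float
    perf_z: float
    n_units: int


def _paired_signrank(a: np.ndarray, b: np.ndarray):
    if not np.any(a - b):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, method="approx")
    return float(res.zstatistic), float(res.pvalue)


def engaged_passive_contrast(
    engaged_rates: Sequence[float],
    passive_rates: Sequence[float],
    engaged_perf: Sequence[float],
    passive_perf: Sequence[float],
) -> EngagedPassiveContrast:
    """Paired sign-rank contrasts of firing rate and decoding performance.

    Inputs are per-unit values for the same units in both states — either
    a fixed onset window or windows optimized independently per state
    (the caller chooses how the per-state values were obtained).
    """
    er, pr = np.asarray(engaged_rates, float), np.asarray(passive_rates, float)
    ep, pp = np.asarray(engaged_perf, float), np.asarray(passive_perf, float)
    if not (len(er) == len(pr) == len(ep) == len(pp)):
        raise ValueError("paired contrast requires identical unit sets")
    rz, rp_ = _paired_signrank(er, pr)
    pz, pp_ = _paired_signrank(ep, pp)
    return EngagedPassiveContrast(
        rate_delta=float(np.median(er - pr)),
        rate_p=rp_,
        rate_z=rz,
        perf_delta=float(np.median(ep - pp)),
        perf_p=pp_,
        perf_z=pz,
        n_units=len(er),
    )
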