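"""Behavioral constancy and generalization statistics.

Constancy holds when the orthogonal acoustic feature (F0, level, location)
does not affect the probability of a correct response: per-value
performance is tested against chance (binomial vs 50%) and the feature's
effect with a logistic regression of correctness on feature value.
Generalization is measured from first exposure to a novel feature value:
performance over the first L trials is tested against a permutation (or
exact binomial) null, and the reported quantity is the smallest L at which
performance is significant at p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BehaviorSummary",
    "filter_analysis_trials",
    "constancy_summary",
    "generalization_test",
    "longterm_performance_resample",
    "classify_single_unit",
]


@dataclass
class BehaviorSummary:
    """Per-feature-value behavioral performance with constancy statistics."""

    per_value: pd.DataFrame  # value, n, percent_correct, binomial_p
    feature: str
    coefficient: float  # logistic-regression slope for the feature
    coefficient_p: float
    constant: bool  # True when the feature effect is non-significant


def filter_analysis_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop correction trials and no-response trials; keep probe flags."""
    df = trials[trials["trial_type"] != "correction"]
    df = df[df["choice"].notna()]
    if "response_time" in df:
        df = df[df["response_time"] <= 60.0]
    return df.reset_index(drop=True)


def constancy_summary(
    trials: pd.DataFrame,
    feature: str,
    alpha: float = 0.05,
    chance: float = 0.5,
) -> BehaviorSummary:
    """Performance per orthogonal-feature value plus a logistic regression.

    Empty groups are dropped.  Constancy is reported when the feature's
    logistic coefficient is non-significant (p >= alpha).
    """
    df = filter_analysis_trials(trials)
    df = df[df["trial_type"] == "test"]
    rows = []
    for value, grp in df.groupby(feature):
        n = len(grp)
        if n == 0:
            continue
        k = int(grp["correct"].sum())
        p = stats.binomtest(k, n, chance).pvalue
        rows.append((value, n, 100.0 * k / n, float(p)))
    per_value = pd.DataFrame(rows, columns=["value", "n", "percent_correct", "binomial_p"])
    x = pd.to_numeric(df[feature])
    X = sm.add_constant(np.asarray(x, dtype=float))
    model = sm.Logit(df["correct"].astype(float), X).fit(disp=0)
    coef = float(model.params.iloc[1])
    coef_p = float(model.pvalues.iloc[1])
    return BehaviorSummary(
        per_value=per_value,
        feature=feature,
        coefficient=coef,
        coefficient_p=coef_p,
        constant=bool(coef_p >= alpha),
    )


def generalization_test(
    correct: Sequence[bool],
    n_iter: int = 10_000,
    alpha: float = 0.001,
    seed=None,
    mode: str = "permutation",
    chance: float = 0.5,
    windows: str = "nested",
) -> int | None:
    """Minimum trials-from-first-exposure at which performance is significant.

    ``correct`` is the outcome sequence ordered from the first trial with
    the novel feature value.  For each window length L = 1..len, observed
    percent correct over the first L trials (``windows="nested"``; a
    sliding variant moves the L-window along the record and takes its first
    position) is compared one-sided (above chance) against the null:
    ``mode="permutation"`` randomizes the required response on ``n_iter``
    iterations; ``mode="exact"`` uses the binomial tail (0.5^k terms for a
    two-choice task).  Returns the smallest significant L, or None.
    """
    y = np.asarray(correct, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if windows not in ("nested", "sliding"):
        raise ValueError("windows must be 'nested' or 'sliding'")

    def tail_p(k: int, L: int) -> float:
        if mode == "exact":
            return float(stats.binom.sf(k - 1, L, chance))  # P(X >= k)
        if mode == "permutation":
            draws = rng.random((n_iter, L)) < chance
            return float(np.mean(draws.sum(axis=1) >= k))
        raise ValueError("mode must be 'permutation' or 'exact'")

    for L in range(1, len(y) + 1):
        if windows == "nested":
            if tail_p(int(y[:L].sum()), L) < alpha:
                return L
        else:
            # sliding: any L-length window ending by trial L... the earliest
            # end index of a significant window of this length
            for end in range(L, len(y) + 1):
                if tail_p(int(y[end - L : end].sum()), L) < alpha:
                    return end
    return None


def longterm_performance_resample(
    correct: Sequence[bool],
    window_length: int,
    n_iter: int = 10_000,
    seed=None,
) -> np.ndarray:
    """Percent correct over random contiguous trial sequences of fixed length.

    Used as the long-term reference against which first-exposure
    performance is compared.
    """
    y = np.asarray(correct, dtype=bool)
    if window_length > len(y):
        raise ValueError("window longer than the record")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.integers(0, len(y) - window_length + 1, size=n_iter)
    return np.array(
        [100.0 * y[s : s + window_length].mean() for s in starts]
    )


def classify_single_unit(isis: Sequence[float], threshold: float = 0.001, max_fraction: float = 0.01) -> bool:
    """Single unit iff strictly less than 1% of ISIs are shorter than 1 ms."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) == 0:
        return True
    return bool(np.mean(isis < threshold) < max_fraction)
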