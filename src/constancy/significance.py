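"""Permutation significance for decoder performance.

The null distribution of optimized decoding performance is built by
shuffling the decoded labels across trials and re-running the *entire*
decoding procedure, including the window-grid optimization, per shuffle.
Re-optimizing under the null matters: taking a maximum over windows
inflates null performance well above nominal chance, so comparing an
optimized observed value against an unoptimized null would be
anti-conservative.

The null is summarized by a Gaussian fit (mean, sd) and the p-value is the
upper-tail probability of the observed performance under that Gaussian —
this lets 100 shuffles resolve p-values far below 1/100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .decoder import SurfaceDecoder

__all__ = [
    "SignificanceResult",
    "shuffle_null",
    "gaussian_tail_p",
    "classify_informative",
    "significance_test",
    "dual_feature_permutation",
]

#: floor on Gaussian-fit p-values
P_EPSILON = 1e-10


@dataclass
class SignificanceResult:
    observed: float  # optimized percent correct
    null_mean: float
    null_sd: float
    p: float
    informative: bool
    n_shuffles: int
    null_values: np.ndarray | None = None


def shuffle_null(
    decoder: SurfaceDecoder,
    labels: Sequence,
    n_shuffles: int = 100,
    seed=None,
) -> np.ndarray:
    """Best (window-optimized) performance for each label shuffle.

    Only the decoded feature is permuted across trials; anything else
    attached to a trial (its orthogonal feature, spikes) stays in place.
    """
    if n_shuffles < 10:
        raise ValueError("fewer than 10 shuffles gives an unstable Gaussian fit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(labels)
        null[i] = decoder.decode(perm, seed=rng).best_performance
    return null


def gaussian_tail_p(observed: float, null_values: Sequence[float]) -> float:
    """Upper-tail probability of ``observed`` under Normal(null mean, null sd).

    A degenerate null (sd = 0) returns 1 when the observed value does not
    exceed the null, else the clamp floor — conservative either way.
    """
    null = np.asarray(null_values, dtype=float)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    if sd == 0.0:
        p = 1.0 if observed <= mean else P_EPSILON
    else:
        p = float(stats.norm.sf(observed, loc=mean, scale=sd))
    return min(1.0, max(P_EPSILON, p))


def classify_informative(p: float, alpha: float = 0.05) -> bool:
    """Informative iff p strictly below alpha."""
    return bool(p < alpha)


def significance_test(
    decoder: SurfaceDecoder,
    labels: Sequence,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed=None,
    keep_null: bool = False,
) -> SignificanceResult:
    """Observed optimized decode vs Gaussian-fit shuffled null."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = decoder.decode(labels, seed=rng).best_performance
    null = shuffle_null(decoder, labels, n_shuffles=n_shuffles, seed=rng)
    p = gaussian_tail_p(observed, null)
    return SignificanceResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p=p,
        informative=classify_informative(p, alpha),
        n_shuffles=n_shuffles,
        null_values=null if keep_null else None,
    )


def dual_feature_permutation(
    flags_a: Sequence[bool],
    flags_b: Sequence[bool],
    n_iter: int = 10_000,
    seed=None,
    ties: str = "inclusive",
):
    """Unit-identity permutation test for dual-feature units.

    The statistic is the number of units informative about both features.
    Each iteration permutes the unit identity of one flag set; the p-value
    is the fraction of permuted joint counts at least as large as observed
    (``ties="inclusive"``, default) or strictly larger (``ties="strict"``).
    The inclusive rule is conservative and handles the degenerate case
    where every permutation reproduces the observed count (p = 1).

    Returns
    -------
    p : float
    observed : int
    null_counts : np.ndarray of shape (n_iter,)
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag sets must cover the same units")
    if ties not in ("inclusive", "strict"):
        raise ValueError("ties must be 'inclusive' or 'strict'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = int(np.sum(a & b))
    null = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        null[i] = int(np.sum(a & rng.permutation(b)))
    if ties == "inclusive":
        p = float(np.mean(null >= observed))
    else:
        p = float(np.mean(null > observed))
    return p, observed, null
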