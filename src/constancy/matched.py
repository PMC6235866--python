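"""Matched datasets for sound, choice and accuracy decoding; error trials.

In a two-choice task the trial outcome is a deterministic function of
vowel and choice, so of the eight vowel x choice x outcome combinations
only four are feasible (each (vowel, choice) pair fixes correct/error).
Balancing those four cells at N trials each automatically balances all
three variables' marginals and pins behavioral percent correct over the
selected trials at exactly 50%, which is what makes sound, choice and
accuracy decoding mutually unconfounded.

Exclusions before balancing: whispered (probe) trials, levels at or below
the per-subject floor, trials with responses within 1 s of stimulus onset
(the trial outcome would otherwise intrude on the decoding window), and
correction / no-response trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import DecodingWindow, SpikeDataset
from .decoder import (
    DecodeResult,
    InsufficientDataError,
    SurfaceDecoder,
    _argmin_with_ties,
    locv_decode,
)
from .significance import SignificanceResult, significance_test

__all__ = [
    "MatchedDataset",
    "NoErrorTrialsError",
    "build_matched_dataset",
    "decode_sound_choice_accuracy",
    "error_trial_decode",
]


class NoErrorTrialsError(ValueError):
    """Raised when error-trial decoding is requested but no errors exist."""


@dataclass
class MatchedDataset:
    """Trial subsample balanced over the feasible vowel x choice cells."""

    trial_ids: list
    n_per_cell: int
    cells: pd.DataFrame  # vowel, choice, correct, n_available, n_selected
    provenance: dict = field(default_factory=dict)

    def labels(self, trials: pd.DataFrame, column: str) -> np.ndarray:
        sub = trials.set_index("trial_id").loc[self.trial_ids]
        return sub[column].to_numpy()

    def percent_correct(self, trials: pd.DataFrame) -> float:
        return 100.0 * float(np.mean(self.labels(trials, "correct")))


def build_matched_dataset(
    trials: pd.DataFrame,
    level_floor: float = 60.0,
    response_floor: float = 1.0,
    seed=None,
    response_anchor: str = "first_token",
) -> MatchedDataset:
    """Exclude, then balance the feasible vowel x choice (x outcome) cells.

    ``response_floor`` excludes trials with responses within that many
    seconds of first-token onset; ``response_anchor="second_token"`` applies
    the same floor relative to second-token onset (0.5 s later) instead.
    N is the minimum cell count after exclusions; each cell is down-sampled
    to N uniformly at random with the given seed.  N < 5 raises, naming the
    limiting cell.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = trials.copy()
    n0 = len(df)
    df = df[df["trial_type"] != "correction"]
    df = df[df["choice"].notna() & (df["response_time"] <= 60.0)]
    if "voicing" in df:
        df = df[df["voicing"].astype(bool)]
    if "level" in df:
        df = df[df["level"] > level_floor]
    anchor_offset = 0.5 if response_anchor == "second_token" else 0.0
    df = df[df["response_time"] >= response_floor + anchor_offset]

    cells = []
    for (vowel, choice), grp in df.groupby(["vowel", "choice"]):
        outcome = grp["correct"].unique()
        if len(outcome) > 1:
            raise ValueError(
                f"cell ({vowel}, {choice}) mixes correct and error trials; "
                "outcome must be determined by vowel and choice"
            )
        cells.append((vowel, choice, bool(outcome[0]), grp["trial_id"].tolist()))
    if len(cells) < 4:
        raise InsufficientDataError(
            f"only {len(cells)} vowel x choice cells present; need all 4"
        )
    n_min = min(len(ids) for *_, ids in cells)
    if n_min < 5:
        limiting = min(cells, key=lambda c: len(c[3]))
        raise InsufficientDataError(
            f"cell (vowel={limiting[0]}, choice={limiting[1]}, "
            f"correct={limiting[2]}) has {len(limiting[3])} trials; floor is 5"
        )
    selected: list = []
    rows = []
    for vowel, choice, correct, ids in cells:
        take = sorted(rng.choice(len(ids), size=n_min, replace=False))
        chosen = [ids[i] for i in take]
        selected.extend(chosen)
        rows.append((vowel, choice, correct, len(ids), n_min))
    cells_df = pd.DataFrame(
        rows, columns=["vowel", "choice", "correct", "n_available", "n_selected"]
    )
    return MatchedDataset(
        trial_ids=selected,
        n_per_cell=n_min,
        cells=cells_df,
        provenance={
            "n_input_trials": n0,
            "n_after_exclusions": len(df),
            "level_floor": level_floor,
            "response_floor": response_floor,
            "response_anchor": response_anchor,
        },
    )


def decode_sound_choice_accuracy(
    matched: MatchedDataset,
    trials: pd.DataFrame,
    dataset: SpikeDataset,
    unit,
    grid,
    bin_width: float | None = 0.01,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed=None,
) -> dict:
    """Decode vowel, choice and accuracy independently on the matched trials.

    Returns ``{label: (PerformanceSurface, SignificanceResult)}`` for
    labels "vowel", "choice", "correct".
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    decoder = SurfaceDecoder(dataset, unit, matched.trial_ids, grid, bin_width)
    out = {}
    for column in ("vowel", "choice", "correct"):
        labels = matched.labels(trials, column)
        res = significance_test(
            decoder, labels, n_shuffles=n_shuffles, alpha=alpha, seed=rng
        )
        surface = decoder.decode(labels, seed=np.random.default_rng(0))
        out[column] = (surface, res)
    return out


def error_trial_decode(
    dataset: SpikeDataset,
    unit,
    trials: Sequence,
    labels: Sequence,
    correct_mask: Sequence[bool],
    window: DecodingWindow,
    bin_width: float | None = 0.01,
    seed=None,
    min_trials_per_class: int = 5,
) -> tuple[DecodeResult, DecodeResult]:
    """Correct-trial LOCV decode plus fixed-template error-trial decode.

    Templates for error trials are the class-mean responses over *all*
    correct trials (no leave-one-out, since error trials never enter the
    templates).  For a unit driven by choice rather than by the stimulus,
    error-trial vowel decoding falls below chance because choice is
    anti-correlated with vowel identity on errors.
    """
    labels = np.asarray(labels)
    mask = np.asarray(correct_mask, dtype=bool)
    if not np.any(~mask):
        raise NoErrorTrialsError("no error trials available for this unit")
    trials = list(trials)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    correct_trials = [t for t, m in zip(trials, mask) if m]
    error_trials = [t for t, m in zip(trials, mask) if not m]
    Xc = dataset.counts(unit, correct_trials, window, bin_width)
    yc = labels[mask]
    correct_result = locv_decode(
        Xc, yc, seed=rng, min_trials_per_class=min_trials_per_class,
        window=window, bin_width=bin_width,
    )

    classes = correct_result.classes
    templates = np.vstack([Xc[yc == c].mean(axis=0) for c in classes])
    Xe = dataset.counts(unit, error_trials, window, bin_width)
    ye = labels[~mask]
    diff = Xe[:, None, :] - templates[None, :, :]
    d2 = np.einsum("ncb,ncb->nc", diff, diff)
    est_idx = _argmin_with_ties(d2, rng)
    est = classes[est_idx]
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for true, e in zip(ye, est):
        confusion.loc[true, e] += 1
    error_result = DecodeResult(
        percent_correct=100.0 * float(np.mean(est == ye)),
        estimates=est,
        labels=ye,
        classes=classes,
        confusion=confusion,
        n_trials_per_class={c: int(np.sum(ye == c)) for c in classes},
        window=window,
        bin_width=bin_width,
    )
    return correct_result, error_result
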