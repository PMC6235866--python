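"""Trial-aligned spike data.

Spike times are in seconds relative to first-token onset (time zero
everywhere in this package).  The covered epoch defaults to [-0.5, 1.5] s
so the full decoding grid and pre-stimulus baselines are populated.  All
windows are half-open ``[start, start + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DecodingWindow", "SpikeDataset", "bin_spikes"]


@dataclass(frozen=True, order=True)
class DecodingWindow:
    """A half-open response window [start, start + duration)."""

    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("window duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def center(self) -> float:
        return self.start + self.duration / 2


def bin_spikes(spike_times: np.ndarray, window: DecodingWindow, bin_width: float | None) -> np.ndarray:
    """Spike counts in half-open bins tiling the window.

    ``bin_width=None`` gives a single bin spanning the window.  The number
    of bins is ``round(duration / bin_width)``; a spike exactly at the
    window end falls outside the last bin.
    """
    if bin_width is None:
        bin_width = window.duration
    n_bins = max(1, int(round(window.duration / bin_width)))
    edges = window.start + bin_width * np.arange(n_bins + 1)
    spikes = np.asarray(spike_times, dtype=float)
    # searchsorted(side="left") makes every bin half-open [e_i, e_{i+1})
    idx = np.searchsorted(spikes, edges, side="left")
    return np.diff(idx).astype(float)


class SpikeDataset:
    """Per unit x trial spike-time sequences plus unit metadata.

    Parameters
    ----------
    spikes
        Mapping ``unit_id -> {trial_id -> sorted spike-time array}``.
    epoch
        (t_min, t_max) seconds covered by every trial.
    unit_meta
        Optional per-unit metadata dicts (tuning spec id, single/multi flag).
    """

    def __init__(
        self,
        spikes: Mapping[object, Mapping[object, np.ndarray]],
        epoch: tuple[float, float] = (-0.5, 1.5),
        unit_meta: Mapping[object, dict] | None = None,
    ):
        self.epoch = (float(epoch[0]), float(epoch[1]))
        self._spikes: dict = {}
        for unit, trials in spikes.items():
            per_trial = {}
            for trial, times in trials.items():
                arr = np.sort(np.asarray(times, dtype=float))
                if len(arr) and (arr[0] < self.epoch[0] or arr[-1] > self.epoch[1]):
                    raise ValueError(
                        f"unit {unit} trial {trial}: spike outside epoch {self.epoch}"
                    )
                per_trial[trial] = arr
            self._spikes[unit] = per_trial
        self.unit_meta = {u: dict((unit_meta or {}).get(u, {})) for u in self._spikes}

    @property
    def unit_ids(self) -> list:
        return list(self._spikes)

    def trial_ids(self, unit) -> list:
        return list(self._spikes[unit])

    def spike_times(self, unit, trial) -> np.ndarray:
        return self._spikes[unit][trial]

    def counts(
        self,
        unit,
        trials: Sequence,
        window: DecodingWindow,
        bin_width: float | None = None,
    ) -> np.ndarray:
        """(n_trials, n_bins) spike-count matrix for the given trials."""
        rows = [bin_spikes(self._spikes[unit][t], window, bin_width) for t in trials]
        return np.vstack(rows) if rows else np.empty((0, 0))

    def count_in(self, unit, trials: Sequence, window: DecodingWindow) -> np.ndarray:
        """Total spike count per trial in the window."""
        return self.counts(unit, trials, window, bin_width=None)[:, 0]

    def rate_in(self, unit, trials: Sequence, window: DecodingWindow) -> np.ndarray:
        """Firing rate (Hz) per trial in the window."""
        return self.count_in(unit, trials, window) / window.duration

    def isis(self, unit) -> np.ndarray:
        """Pooled within-trial inter-spike intervals for one unit (s)."""
        gaps = [np.diff(t) for t in self._spikes[unit].values() if len(t) > 1]
        return np.concatenate(gaps) if gaps else np.empty(0)

    def subset_trials(self, trials: Iterable) -> "SpikeDataset":
        keep = set(trials)
        return SpikeDataset(
            {
                u: {t: s for t, s in per.items() if t in keep}
                for u, per in self._spikes.items()
            },
            epoch=self.epoch,
            unit_meta=self.unit_meta,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (unit_id, trial_id, spike_time_s)."""
        rows = [
            (u, t, s)
            for u, per in self._spikes.items()
            for t, times in per.items()
            for s in times
        ]
        return pd.DataFrame(rows, columns=["unit_id", "trial_id", "spike_time_s"])

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        epoch: tuple[float, float] = (-0.5, 1.5),
        units: Sequence | None = None,
        trials: Sequence | None = None,
        unit_meta: Mapping | None = None,
    ) -> "SpikeDataset":
        """Build from a long table; ``units``/``trials`` force empty rows to exist."""
        spikes: dict = {u: {} for u in (units or [])}
        for (u, t), grp in df.groupby(["unit_id", "trial_id"], sort=False):
            spikes.setdefault(u, {})[t] = grp["spike_time_s"].to_numpy()
        if trials is not None:
            for u in spikes:
                for t in trials:
                    spikes[u].setdefault(t, np.empty(0))
        return cls(spikes, epoch=epoch, unit_meta=unit_meta)
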