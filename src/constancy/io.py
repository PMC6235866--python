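"""Delimited-text I/O and run configuration.

Trial tables and spike events travel as CSV: diff-able, desk-scale, and
schema-checked on read.  Times are seconds (zero = first-token onset),
levels dB.  Unknown trial-table columns are preserved.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import SpikeDataset

__all__ = [
    "SchemaError",
    "TRIAL_COLUMNS",
    "SPIKE_COLUMNS",
    "read_trials",
    "write_trials",
    "read_spikes",
    "write_spikes",
    "RunConfig",
]

TRIAL_COLUMNS = [
    "trial_id",
    "vowel",
    "choice",
    "correct",
    "response_time",
    "trial_type",
]
SPIKE_COLUMNS = ["unit_id", "trial_id", "spike_time_s"]


class SchemaError(ValueError):
    """A required column is missing from a delimited-text file."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV; unknown columns are preserved."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trial file", stacklevel=2)
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    except pd.errors.ParserError as err:
        raise SchemaError(f"{path}: malformed row ({err})") from err
    _check_columns(df, TRIAL_COLUMNS, path)
    return df


def write_trials(path, trials: pd.DataFrame) -> None:
    _check_columns(trials, TRIAL_COLUMNS, path)
    trials.to_csv(path, index=False)


def read_spikes(path, epoch=(-0.5, 1.5), trials=None, units=None) -> SpikeDataset:
    """Read long-format spike events (unit_id, trial_id, spike_time_s)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty spike file", stacklevel=2)
        return SpikeDataset({}, epoch=epoch)
    except pd.errors.ParserError as err:
        raise SchemaError(f"{path}: malformed row ({err})") from err
    _check_columns(df, SPIKE_COLUMNS, path)
    df = df.sort_values(["unit_id", "trial_id", "spike_time_s"], kind="stable")
    return SpikeDataset.from_frame(df, epoch=epoch, units=units, trials=trials)


def write_spikes(path, dataset: SpikeDataset) -> None:
    dataset.to_frame().to_csv(path, index=False)


@dataclass
class RunConfig:
    """Seeds, grids and thresholds for a full pipeline run.

    Every stochastic stage carries an explicit seed so reruns are
    byte-identical; the config hash ties outputs to their configuration.
    """

    seed_simulation: int = 1
    seed_decode: int = 2
    seed_significance: int = 3
    seed_matched: int = 4
    seed_population: int = 5
    grid_start_step: float = 0.1
    grid_dur_min: float = 0.1
    grid_dur_max: float = 0.5
    grid_dur_step: float = 0.1
    grid_start_min: float = -0.1
    grid_start_max: float = 0.4
    bin_width: float = 0.01
    alpha: float = 0.05
    n_shuffles: int = 100
    level_floor: float = 60.0
    response_floor: float = 1.0
    n_units: int = 12
    n_per_condition: int = 12
    behavior_p_correct: float = 0.8
    probe_rate: float = 0.0
    population_window: float = 0.1
    n_combos: int = 20

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
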