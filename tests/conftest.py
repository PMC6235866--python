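import numpy as np
import pandas as pd
import pytest

from constancy import simulate
from constancy.dataset import SpikeDataset
from constancy.decoder import make_window_grid


@pytest.fixture(scope="session")
def reduced_grid():
    """Coarse 30-window grid (6 starts x 5 durations) for fast surface decodes."""
    return make_window_grid(-0.1, 0.4, 0.1, 0.1, 0.5, 0.1)


@pytest.fixture(scope="session")
def two_class_trials():
    """100 test trials, two vowels at a single F0, engaged, no probes."""
    design = simulate.TrialDesign(
        vowels=("u", "e"), orthogonal_values=(200.0,), n_per_condition=50
    )
    return simulate.generate_trial_table(design, behavior_model=1.0, seed=11)


@pytest.fixture(scope="session")
def f0_trials():
    """Two vowels x five F0 values x 10 repeats (100 test trials)."""
    design = simulate.TrialDesign(n_per_condition=10)
    return simulate.generate_trial_table(design, behavior_model=1.0, seed=12)


def make_dataset(spikes_per_trial, epoch=(-0.5, 1.5)):
    """Build a one-unit SpikeDataset from {trial_id: spike time list}."""
    return SpikeDataset({"u0": {t: np.asarray(s, float) for t, s in spikes_per_trial.items()}},
                        epoch=epoch)
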