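"""Synthetic trial tables and trial-aligned spike trains.

The generator produces the statistical structure the decoding analyses
assume: per-unit inhomogeneous-Poisson spike trains whose rates carry
feature-specific temporal kernels (distinct latencies per feature, the
substrate of temporal multiplexing), optional choice/accuracy modulation,
engagement-dependent suppression of the evoked response, and a two-choice
behavioral trial process with probe (whispered) trials and correction
trials after errors.

Rates are built as

    rate(t) = max(0, baseline + sum_f gain_f(value) * kernel_f(t)
                      + choice/accuracy terms),

where each kernel is a half-cosine bump of unit peak over
[latency, latency + duration].  When the trial is engaged, the evoked
(non-baseline) part is scaled by ``engagement_scale`` during stimulus
presentation [0, 1] s — suppression acts during, not before, the sound.

Spike times are drawn by thinning a homogeneous Poisson process at an
analytic rate bound, which is exact for this rate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import SpikeDataset

__all__ = [
    "FeatureKernel",
    "UnitTuningSpec",
    "TrialDesign",
    "generate_trial_table",
    "rate_profile",
    "rate_bound",
    "sample_spikes",
    "generate_dataset",
    "untuned_unit",
    "tuned_unit",
]

EPOCH = (-0.5, 1.5)
STIM_WINDOW = (0.0, 1.0)  # engagement suppression applies here


@dataclass(frozen=True)
class FeatureKernel:
    """Half-cosine response bump tied to one stimulus/behavioral feature.

    ``gains`` maps feature values to evoked-rate amplitudes (Hz).
    ``passive_latency_shift`` delays the bump under passive listening,
    emulating the engagement-dependent timing of feature information.
    """

    latency: float
    duration: float
    gains: Mapping[object, float] = field(default_factory=dict)
    passive_latency_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("kernel duration must be positive")
        lo = self.latency
        hi = max(self.latency, self.latency + self.passive_latency_shift) + self.duration
        if lo < EPOCH[0] or hi > EPOCH[1]:
            raise ValueError(f"kernel window must lie within {EPOCH}")

    def evaluate(self, t: np.ndarray, passive: bool = False) -> np.ndarray:
        lat = self.latency + (self.passive_latency_shift if passive else 0.0)
        u = (np.asarray(t, dtype=float) - lat) / self.duration
        out = np.zeros_like(u)
        inside = (u >= 0) & (u <= 1)
        out[inside] = np.sin(np.pi * u[inside])
        return out


@dataclass(frozen=True)
class UnitTuningSpec:
    """Rate model of one synthetic unit."""

    baseline_rate: float = 5.0
    kernels: Mapping[str, FeatureKernel] = field(default_factory=dict)
    choice_gain: float = 0.0
    choice_kernel: FeatureKernel | None = None
    choice_pref: str = "left"
    accuracy_gain: float = 0.0
    accuracy_kernel: FeatureKernel | None = None
    engagement_scale: float = 1.0
    is_single_unit: bool = True

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be non-negative")


def untuned_unit(rate: float = 15.0) -> UnitTuningSpec:
    """Homogeneous-Poisson unit with no stimulus, choice or accuracy tuning."""
    return UnitTuningSpec(baseline_rate=rate)


def tuned_unit(
    feature: str,
    gains: Mapping[object, float],
    latency: float = 0.02,
    duration: float = 0.2,
    baseline_rate: float = 10.0,
    **kwargs,
) -> UnitTuningSpec:
    """Unit carrying a single feature kernel (convenience constructor)."""
    return UnitTuningSpec(
        baseline_rate=baseline_rate,
        kernels={feature: FeatureKernel(latency, duration, dict(gains))},
        **kwargs,
    )


@dataclass(frozen=True)
class TrialDesign:
    """Balanced condition grid for one (simulated) test session.

    One orthogonal feature varies per session, mirroring the task; the
    other stimulus features sit at their fixed training values.
    """

    vowels: tuple = ("u", "e")
    orthogonal: str = "f0"
    orthogonal_values: tuple = (149.0, 200.0, 263.0, 330.0, 459.0)
    n_per_condition: int = 10
    contingency: Mapping[str, str] = field(
        default_factory=lambda: {"u": "left", "e": "right"}
    )
    fixed: Mapping[str, object] = field(
        default_factory=lambda: {"f0": 200.0, "level": 70.0, "location": 0.0}
    )
    engagement: str = "engaged"


def _response_time(rng: np.random.Generator) -> float:
    # right-skewed latencies straddling the 1 s exclusion boundary
    return float(0.5 + rng.lognormal(mean=np.log(0.9), sigma=0.5))


def generate_trial_table(
    design: TrialDesign,
    behavior_model: float | Callable[[pd.Series], float] = 0.85,
    probe_rate: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Trial table with balanced conditions, probe trials and corrections.

    ``behavior_model`` is p(correct) — a constant or a callable on the trial
    row.  Condition counts are balanced before correction trials; each error
    on a test trial is followed by a flagged correction trial with the same
    stimulus.  Probe trials are whispered, occur at ``probe_rate`` relative
    to the number of test trials, and any response is rewarded (no
    corrections follow them).
    """
    if not 0.0 <= probe_rate <= 0.2:
        raise ValueError("probe_rate must lie in [0, 0.2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base_rows = []
    for vowel in design.vowels:
        for value in design.orthogonal_values:
            for _ in range(design.n_per_condition):
                row = dict(design.fixed)
                row.update(
                    vowel=vowel,
                    voicing=True,
                    trial_type="test",
                    engagement=design.engagement,
                )
                row[design.orthogonal] = value
                base_rows.append(row)
    n_test = len(base_rows)
    n_probe = int(round(probe_rate * n_test))
    for k in range(n_probe):
        vowel = design.vowels[k % len(design.vowels)]
        row = dict(design.fixed)
        row.update(
            vowel=vowel, voicing=False, trial_type="probe", engagement=design.engagement
        )
        row[design.orthogonal] = row.get(design.orthogonal, design.fixed.get(design.orthogonal))
        if design.orthogonal == "voicing":
            row["voicing"] = False
        base_rows.append(row)
    order = rng.permutation(len(base_rows))

    def p_correct(row: pd.Series) -> float:
        return behavior_model(row) if callable(behavior_model) else float(behavior_model)

    records = []
    trial_id = 0
    for idx in order:
        row = dict(base_rows[idx])
        srow = pd.Series(row)
        correct = bool(rng.random() < p_correct(srow))
        target = design.contingency[row["vowel"]]
        other = "right" if target == "left" else "left"
        choice = target if correct else other
        if row["trial_type"] == "probe":
            correct = True  # any response rewarded on probes
        records.append(
            dict(
                trial_id=trial_id,
                **row,
                choice=choice,
                correct=correct,
                response_time=_response_time(rng),
            )
        )
        trial_id += 1
        if row["trial_type"] == "test" and not correct:
            crow = dict(row, trial_type="correction")
            ccorrect = bool(rng.random() < p_correct(pd.Series(crow)))
            cchoice = target if ccorrect else other
            records.append(
                dict(
                    trial_id=trial_id,
                    **crow,
                    choice=cchoice,
                    correct=ccorrect,
                    response_time=_response_time(rng),
                )
            )
            trial_id += 1
    return pd.DataFrame.from_records(records)


def rate_profile(tuning: UnitTuningSpec, trial: pd.Series) -> Callable[[np.ndarray], np.ndarray]:
    """Rate function (Hz) of time for one unit on one trial."""
    passive = str(trial.get("engagement", "engaged")) == "passive"
    engaged = not passive

    terms = []
    for feature, kernel in tuning.kernels.items():
        gain = float(kernel.gains.get(trial.get(feature), 0.0))
        if gain != 0.0:
            terms.append((gain, kernel))
    if tuning.choice_gain != 0.0 and trial.get("choice") == tuning.choice_pref:
        terms.append((tuning.choice_gain, tuning.choice_kernel or FeatureKernel(0.3, 0.3)))
    if tuning.accuracy_gain != 0.0 and bool(trial.get("correct", False)):
        terms.append((tuning.accuracy_gain, tuning.accuracy_kernel or FeatureKernel(0.3, 0.3)))

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        evoked = np.zeros_like(t)
        for gain, kernel in terms:
            evoked += gain * kernel.evaluate(t, passive=passive)
        if engaged and tuning.engagement_scale != 1.0:
            in_stim = (t >= STIM_WINDOW[0]) & (t < STIM_WINDOW[1])
            evoked = np.where(in_stim, evoked * tuning.engagement_scale, evoked)
        return np.maximum(0.0, tuning.baseline_rate + evoked)

    return rate


def rate_bound(tuning: UnitTuningSpec) -> float:
    """Analytic upper bound on the rate for exact thinning."""
    bound = tuning.baseline_rate
    pos = sum(
        max(0.0, max(k.gains.values(), default=0.0)) for k in tuning.kernels.values()
    )
    pos += max(0.0, tuning.choice_gain) + max(0.0, tuning.accuracy_gain)
    bound += pos * max(1.0, tuning.engagement_scale)
    return bound


def sample_spikes(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    epoch: tuple[float, float] = EPOCH,
    rate_max: float = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on ``epoch`` via thinning.

    ``rate_max`` must bound the rate over the epoch; candidates are drawn
    homogeneously at that rate and accepted with probability
    rate(t)/rate_max, which yields exact Poisson counts in every interval.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if rate_max is None:
        grid = np.linspace(epoch[0], epoch[1], 2001)
        rate_max = float(np.max(rate_fn(grid))) * 1.05
    if rate_max <= 0:
        return np.empty(0)
    t0, t1 = epoch
    n_cand = rng.poisson(rate_max * (t1 - t0))
    times = np.sort(rng.uniform(t0, t1, size=n_cand))
    if n_cand == 0:
        return times
    accept = rng.random(n_cand) < rate_fn(times) / rate_max
    return times[accept]


def generate_dataset(
    population: Mapping[object, UnitTuningSpec] | Sequence[UnitTuningSpec],
    trials: pd.DataFrame,
    seed=None,
    epoch: tuple[float, float] = EPOCH,
) -> SpikeDataset:
    """Sample a full SpikeDataset: every unit on every trial, seeded.

    Units are conditionally independent given the trial; each unit draws
    from its own stream spawned from the top-level seed, so adding units
    does not perturb the others' spikes.
    """
    if not isinstance(population, Mapping):
        population = {i: spec for i, spec in enumerate(population)}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(population))
    spikes: dict = {}
    meta: dict = {}
    for (unit_id, tuning), child in zip(population.items(), children):
        rng = np.random.default_rng(child)
        bound = rate_bound(tuning)
        per_trial = {}
        for _, trial in trials.iterrows():
            fn = rate_profile(tuning, trial)
            per_trial[trial["trial_id"]] = sample_spikes(fn, epoch, bound, rng)
        spikes[unit_id] = per_trial
        meta[unit_id] = {"is_single_unit": tuning.is_single_unit}
    return SpikeDataset(spikes, epoch=epoch, unit_meta=meta)
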