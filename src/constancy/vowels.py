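"""Artificial vowel synthesis.

Vowels are built source-filter style: a glottal click train (voiced) or
broadband noise (whispered) is passed through four parallel two-pole
resonators, one per formant, then cosine-ramped and scaled to a target
level.  Trial stimuli are two identical 250 ms tokens separated by a
250 ms silent gap.

Level uses a purely digital convention: 70 dB "SPL" corresponds to an RMS
of 0.05 full-scale, so printed level differences are preserved exactly
even though absolute calibration is meaningless in software.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "VowelSpec",
    "Waveform",
    "VOWEL_FORMANTS",
    "FORMANT_BANDWIDTHS",
    "vowel_spec",
    "make_source",
    "formant_filter",
    "apply_cosine_ramps",
    "set_level",
    "synthesize_vowel",
    "two_token_stimulus",
    "save_wav",
    "REF_LEVEL_DB",
    "REF_RMS",
]

#: digital level convention: this dB value maps to :data:`REF_RMS` full-scale RMS
REF_LEVEL_DB = 70.0
REF_RMS = 0.05

#: formant center frequencies (F1-F4, Hz) for the four vowels used in the task
VOWEL_FORMANTS = {
    "u": (460.0, 1105.0, 2857.0, 4205.0),
    "e": (730.0, 2058.0, 2857.0, 4205.0),  # /ε/
    "a": (936.0, 1551.0, 2975.0, 4263.0),
    "i": (437.0, 2761.0, 2975.0, 4263.0),
}

#: formant bandwidths (F1-F4, Hz), constant across vowels
FORMANT_BANDWIDTHS = (80.0, 70.0, 160.0, 300.0)


class InvalidSpecError(ValueError):
    """Raised when a stimulus specification is internally inconsistent."""


@dataclass(frozen=True)
class VowelSpec:
    """Parameters of one synthetic vowel token.

    ``f0`` is the fundamental frequency of the voiced source in Hz;
    ``None`` means whispered (noise source).  ``level`` is in dB under the
    digital SPL convention (see module docstring).
    """

    name: str
    formants: tuple[float, float, float, float]
    bandwidths: tuple[float, float, float, float] = FORMANT_BANDWIDTHS
    f0: float | None = 200.0
    duration: float = 0.25
    level: float = REF_LEVEL_DB
    sample_rate: float = 48000.0

    def __post_init__(self) -> None:
        if len(self.formants) != 4 or len(self.bandwidths) != 4:
            raise InvalidSpecError("exactly four formants/bandwidths required")
        if not all(a < b for a, b in zip(self.formants, self.formants[1:])):
            raise InvalidSpecError("formants must be strictly increasing")
        if any(bw <= 0 for bw in self.bandwidths):
            raise InvalidSpecError("bandwidths must be positive")
        if self.duration <= 0:
            raise InvalidSpecError("duration must be positive")
        if self.f0 is not None and self.f0 <= 0:
            raise InvalidSpecError("voiced f0 must be positive")
        if self.sample_rate < 2 * self.formants[-1]:
            raise InvalidSpecError("sample_rate must be at least 2 x F4")

    @property
    def voiced(self) -> bool:
        return self.f0 is not None


@dataclass(frozen=True)
class Waveform:
    """A sampled signal: real-valued samples at a fixed rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def vowel_spec(name: str, **overrides) -> VowelSpec:
    """Look up a named vowel (/u/, /ε/ as "e", /a/, /i/) with optional overrides.

    ``whispered=True`` is shorthand for ``f0=None``.
    """
    key = {"ε": "e", "ɛ": "e"}.get(name, name)
    if key not in VOWEL_FORMANTS:
        raise InvalidSpecError(f"unknown vowel {name!r}; known: {sorted(VOWEL_FORMANTS)}")
    if overrides.pop("whispered", False):
        overrides["f0"] = None
    return VowelSpec(name=key, formants=VOWEL_FORMANTS[key], **overrides)


def make_source(
    voiced: bool,
    f0: float | None,
    duration: float,
    sample_rate: float,
    seed: int | np.random.Generator | None = None,
) -> Waveform:
    """Glottal-like source: a click train (voiced) or white noise (whispered).

    The click train places unit impulses starting at sample 0 with a period
    of ``round(sample_rate / f0)`` samples.  Whispered sources are zero-mean
    unit-variance Gaussian noise from the seeded generator.
    """
    n = int(round(duration * sample_rate))
    if voiced:
        if f0 is None or f0 <= 0:
            raise InvalidSpecError("voiced source requires f0 > 0")
        period = int(round(sample_rate / f0))
        samples = np.zeros(n)
        samples[::period] = 1.0
    else:
        rng = np.random.default_rng(seed)
        samples = rng.standard_normal(n)
    return Waveform(samples, sample_rate)


def _resonator(freq: float, bandwidth: float, sample_rate: float):
    """Biquad two-pole resonator coefficients with unity gain at center."""
    r = np.exp(-np.pi * bandwidth / sample_rate)
    theta = 2 * np.pi * freq / sample_rate
    a = np.array([1.0, -2 * r * np.cos(theta), r * r])
    # normalize so |H(e^{j theta})| = 1 at the formant center
    z = np.exp(1j * theta)
    gain = np.abs(np.polyval(a[::-1], 1 / z))
    b = np.array([gain])
    return b, a


def formant_filter(source: Waveform, spec: VowelSpec) -> Waveform:
    """Sum of four parallel resonators, one per formant, equal weights."""
    nyquist = source.sample_rate / 2
    if spec.formants[-1] >= nyquist:
        raise InvalidSpecError("formant at or above Nyquist frequency")
    if source.sample_rate != spec.sample_rate:
        raise InvalidSpecError("source sample rate does not match spec")
    out = np.zeros_like(source.samples)
    for freq, bw in zip(spec.formants, spec.bandwidths):
        b, a = _resonator(freq, bw, source.sample_rate)
        out += signal.lfilter(b, a, source.samples)
    return Waveform(out, source.sample_rate)


def apply_cosine_ramps(w: Waveform, ramp: float = 0.005) -> Waveform:
    """Raised-cosine onset/offset ramps; endpoints scaled exactly to zero."""
    if ramp < 0:
        raise InvalidSpecError("ramp must be non-negative")
    if ramp == 0:
        return w
    if 2 * ramp > w.duration:
        raise InvalidSpecError("ramps longer than the waveform")
    n_ramp = int(round(ramp * w.sample_rate))
    if n_ramp < 2:
        return w
    env = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / (n_ramp - 1)))
    samples = w.samples.copy()
    samples[:n_ramp] *= env
    samples[-n_ramp:] *= env[::-1]
    return Waveform(samples, w.sample_rate)


def set_level(w: Waveform, level: float) -> Waveform:
    """Scale so RMS equals ``REF_RMS * 10**((level - REF_LEVEL_DB) / 20)``."""
    current = w.rms()
    if current == 0:
        raise InvalidSpecError("cannot set the level of a silent waveform")
    target = REF_RMS * 10 ** ((level - REF_LEVEL_DB) / 20)
    return Waveform(w.samples * (target / current), w.sample_rate)


def synthesize_vowel(spec: VowelSpec, seed: int | None = None) -> Waveform:
    """Full token pipeline: source -> formant filter -> ramps -> level."""
    src = make_source(spec.voiced, spec.f0, spec.duration, spec.sample_rate, seed)
    w = formant_filter(src, spec)
    w = apply_cosine_ramps(w)
    w = set_level(w, spec.level)
    assert len(w.samples) == int(round(spec.duration * spec.sample_rate))
    return w


def two_token_stimulus(w: Waveform, gap: float = 0.25) -> Waveform:
    """Token + silent gap + identical token (the trial stimulus)."""
    silence = np.zeros(int(round(gap * w.sample_rate)))
    return Waveform(np.concatenate([w.samples, silence, w.samples]), w.sample_rate)


def save_wav(path, w: Waveform) -> None:
    wavfile.write(path, int(w.sample_rate), w.samples.astype(np.float32))
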