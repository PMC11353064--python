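"""Synthesis of the entrainment paradigm's audio.

Each trial presents 2 s of amplitude-modulated (AM) white noise — the
entraining stimulus — followed, after a phase-controlled silent delay, by a
brief multitone target whose fundamental the listener later matches.  The
target onset is expressed as the phase (in radians) of the AM envelope had
it continued past the noise offset: 0 and 2*pi fall on a would-be envelope
peak ("in phase"), pi on the opposing phase.

Two AM envelope shapes are supported: a raised cosine (smooth, used with
50 ms targets) and an inverse sawtooth (instant rise, linear decay, used
with 25 ms targets).  Both are generated at 100% modulation depth by
default, so the envelope reaches zero once per cycle.

The cosine envelope starts and ends at its minimum, giving a whole number
of cycles in the 2 s noise (16 at 8 Hz) and a well-defined continued-peak
time of half a period after offset.  The convention is configurable via
``StimulusSpec.am_waveform`` and documented in docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "StimulusSpec",
    "TrialAudio",
    "make_f0_grid",
    "synth_multitone",
    "synth_am_noise",
    "phase_to_onset_delay",
    "assemble_trial_audio",
    "write_wav",
    "read_wav",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the paradigm's audio.

    Defaults reproduce the first experiment's stimuli; ``for_experiment(2)``
    switches to the 25 ms target and inverse-sawtooth AM of the second.
    """

    sample_rate: float = 44_100.0          # Hz
    am_rate: float = 8.0                   # Hz, entrainment rate
    am_depth: float = 1.0                  # modulation depth, 0..1
    am_waveform: str = "cosine"            # "cosine" | "inverse_sawtooth"
    noise_dur: float = 2.0                 # s, entraining noise duration
    target_dur: float = 0.050              # s (0.025 in experiment 2)
    ramp_dur: float = 0.005                # s, cosine on/off ramps
    harmonic_multipliers: tuple[int, ...] = (1, 2, 4, 6, 8, 10)
    harmonic_step_db: float = 3.0          # dB drop per successive component
    noise_level_rel_target_db: float = -8.0  # noise peak re target peak
    target_peak: float = 0.9               # digital peak after normalization

    def __post_init__(self) -> None:
        if self.am_rate <= 0:
            raise ValueError("am_rate must be positive")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must lie in [0, 1]")
        if self.am_waveform not in ("cosine", "inverse_sawtooth"):
            raise ValueError(f"unknown am_waveform {self.am_waveform!r}")
        n_cycles = self.noise_dur * self.am_rate
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError("noise_dur must span an integer number of AM cycles")
        if self.target_dur < 2 * self.ramp_dur:
            raise ValueError("target_dur must be at least twice ramp_dur")
        mult = self.harmonic_multipliers
        if mult[0] != 1 or any(b <= a for a, b in zip(mult, mult[1:])):
            raise ValueError("harmonic_multipliers must be strictly increasing, starting at 1")
        if not 0 < self.target_peak <= 1:
            raise ValueError("target_peak must lie in (0, 1]")

    @property
    def am_period(self) -> float:
        return 1.0 / self.am_rate

    @classmethod
    def for_experiment(cls, experiment: int) -> "StimulusSpec":
        if experiment == 1:
            return cls()
        if experiment == 2:
            return cls(target_dur=0.025, am_waveform="inverse_sawtooth")
        raise ValueError("experiment must be 1 or 2")


@dataclass(frozen=True)
class TrialAudio:
    """Assembled single-trial waveform with its event times."""

    samples: np.ndarray                    # float in [-1, 1]
    sample_rate: float
    am_offset_time: float                  # s, end of the entraining noise
    target_onset_time: float               # s, start of the target complex
    phase_condition: float                 # radians
    f0: float                              # Hz

    def __post_init__(self) -> None:
        if self.target_onset_time <= self.am_offset_time:
            raise ValueError("target must start after the AM noise ends")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("samples clip outside [-1, 1]")

    def event_sidecar(self) -> dict:
        return {
            "sample_rate": self.sample_rate,
            "am_offset_time": self.am_offset_time,
            "target_onset_time": self.target_onset_time,
            "phase_rad": self.phase_condition,
            "f0_hz": self.f0,
        }


def make_f0_grid(low: float = 270.0, high: float = 715.0, n: int = 211) -> np.ndarray:
    """Log-spaced grid of candidate fundamentals, endpoints inclusive.

    The paradigm draws target f0 from 211 log-spaced values between 270 and
    715 Hz; consecutive ratios are constant.
    """
    if low <= 0 or high <= low:
        raise ValueError("require 0 < low < high")
    if n < 2:
        raise ValueError("n must be at least 2")
    return np.geomspace(low, high, n)


def _cosine_ramps(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Unit gate with raised-cosine on/off ramps."""
    gate = np.ones(n_samples)
    if ramp_samples > 0:
        t = np.arange(ramp_samples) / ramp_samples
        ramp = (1.0 - np.cos(np.pi * t)) / 2.0
        gate[:ramp_samples] = ramp
        gate[-ramp_samples:] = ramp[::-1]
    return gate


def synth_multitone(f0: float, spec: StimulusSpec) -> np.ndarray:
    """Harmonic complex at f0 with components at f0 x each multiplier.

    Component k sits k*harmonic_step_db below the fundamental in amplitude
    (20*log10 convention).  Cosine on/off ramps are applied and the result
    is peak-normalized to ``spec.target_peak``.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    nyquist = spec.sample_rate / 2.0
    top = f0 * spec.harmonic_multipliers[-1]
    if top >= nyquist:
        raise ValueError(f"component at {top:.0f} Hz aliases above Nyquist ({nyquist:.0f} Hz)")

    n = round(spec.target_dur * spec.sample_rate)
    t = np.arange(n) / spec.sample_rate
    wave = np.zeros(n)
    for k, mult in enumerate(spec.harmonic_multipliers):
        amp = 10.0 ** (-k * spec.harmonic_step_db / 20.0)
        wave += amp * np.sin(2.0 * np.pi * f0 * mult * t)
    wave *= _cosine_ramps(n, round(spec.ramp_dur * spec.sample_rate))
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= spec.target_peak / peak
    return wave


def am_envelope(t: np.ndarray | float, spec: StimulusSpec) -> np.ndarray | float:
    """AM envelope value at time t (s), unit peak.

    cosine: e(t) = 1 - depth*(1 + cos(2*pi*f*t))/2 — starts/ends each cycle
    at its minimum (0 at full depth), peaks mid-cycle.
    inverse_sawtooth: e(t) = 1 - depth*frac(f*t) — instant rise at each
    cycle start, linear decay to the minimum.
    """
    ft = np.asarray(t, dtype=float) * spec.am_rate
    if spec.am_waveform == "cosine":
        env = 1.0 - spec.am_depth * (1.0 + np.cos(2.0 * np.pi * ft)) / 2.0
    else:
        env = 1.0 - spec.am_depth * (ft - np.floor(ft))
    return env


def synth_am_noise(spec: StimulusSpec, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Seeded Gaussian white noise shaped by the AM envelope, unit peak.

    The enveloped noise is peak-normalized, so level offsets specified
    relative to maximum intensity are exact in the assembled trial.  At
    full modulation depth the envelope still reaches 0 once per cycle.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = round(spec.noise_dur * spec.sample_rate)
    noise = rng.standard_normal(n)
    t = np.arange(n) / spec.sample_rate
    noise = noise * am_envelope(t, spec)
    return noise / np.max(np.abs(noise))


def phase_to_onset_delay(phase: float, spec: StimulusSpec) -> float:
    """Target onset delay (s after AM offset) for a phase condition.

    The delay places the target at ``phase`` radians of the AM cycle
    relative to the next would-be envelope peak after the noise ends:

        delay = t_next_peak + (phase / 2*pi) * period

    For the cosine envelope (ends at its minimum) the continued envelope
    peaks half a period after offset; for the inverse sawtooth (peaks at
    each cycle start, i.e. at the offset itself) the next peak strictly
    after offset is one full period later.
    """
    if not 0.0 <= phase <= 2.0 * math.pi + 1e-12:
        raise ValueError("phase must lie in [0, 2*pi]")
    period = spec.am_period
    t_next_peak = period / 2.0 if spec.am_waveform == "cosine" else period
    return t_next_peak + (phase / (2.0 * math.pi)) * period


def assemble_trial_audio(
    f0: float,
    phase: float,
    spec: StimulusSpec,
    seed: int | np.random.Generator = 0,
    tail_dur: float = 0.050,
) -> TrialAudio:
    """AM noise, silent gap, then the target at its phase-determined onset.

    The target peak exceeds the noise peak by |noise_level_rel_target_db|
    dB (peak-amplitude convention).  Event times are recorded so the
    geometry can be checked or exported as a sidecar.
    """
    noise = synth_am_noise(spec, seed)
    noise = noise * spec.target_peak * 10.0 ** (spec.noise_level_rel_target_db / 20.0)
    target = synth_multitone(f0, spec)

    delay = phase_to_onset_delay(phase, spec)
    onset_time = spec.noise_dur + delay
    onset_idx = round(onset_time * spec.sample_rate)
    total = onset_idx + target.size + round(tail_dur * spec.sample_rate)

    samples = np.zeros(total)
    samples[: noise.size] = noise
    samples[onset_idx : onset_idx + target.size] = target
    return TrialAudio(
        samples=samples,
        sample_rate=spec.sample_rate,
        am_offset_time=spec.noise_dur,
        target_onset_time=onset_time,
        phase_condition=phase,
        f0=f0,
    )


def write_wav(audio: TrialAudio, path: str | Path, sidecar: bool = True) -> Path:
    """Write 16-bit PCM mono WAV plus a JSON sidecar with event times.

    Round-trip read reproduces samples within one quantization step
    (2**-15).
    """
    path = Path(path)
    if np.max(np.abs(audio.samples), initial=0.0) > 1.0:
        raise ValueError("samples must lie in [-1, 1]")
    pcm = np.round(audio.samples * 32767.0).astype(np.int16)
    wavfile.write(path, int(audio.sample_rate), pcm)
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(audio.event_sidecar(), indent=2))
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV back to float samples in [-1, 1]."""
    rate, pcm = wavfile.read(Path(path))
    return pcm.astype(float) / 32767.0, rate


def experiment_spec_variant(spec: StimulusSpec, **overrides) -> StimulusSpec:
    """Return a copy of spec with fields replaced (convenience for drivers)."""
    return replace(spec, **overrides)
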