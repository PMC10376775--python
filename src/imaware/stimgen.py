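"""Informational-masking stimulus synthesis.

A trial is a random multi-tone masker, optionally with a regular target tone
stream embedded in it.  The masker is built from pure tones whose frequencies
are log-spaced between 239 and 5000 Hz and whose inter-onset intervals are
drawn uniformly per frequency track; a protected region of one equivalent
rectangular bandwidth (ERB) on each side of the target frequency is kept free
of masker tones so that masking is informational (central) rather than
energetic (cochlear).

Four spectro-temporal density conditions are available.  Their printed labels
(11, 20, 28, 36 tones/s/octave) are carried as opaque condition labels tied to
the (mean inter-tone interval, frequencies per octave) pairs in their printed
order; they are never recomputed from the pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.io import wavfile

TARGET_FREQUENCIES_HZ = (699.0, 1000.0, 1430.0, 2045.0, 2924.0)

#: density label -> (mean inter-tone interval ms, frequencies per octave)
DENSITY_PAIRS = {11: (200, 32), 20: (400, 64), 28: (600, 96), 36: (800, 128)}


@dataclass(frozen=True)
class TargetSpec:
    """Regular target tone stream."""

    frequency: float = 1000.0      # Hz
    tone_duration: float = 100.0   # ms
    repetition_rate: float = 1.0   # tones per second
    onset: float = 600.0           # ms from masker start
    present: bool = True
    ramp: float = 10.0             # ms raised-cosine on/off ramp


@dataclass(frozen=True)
class MaskerSpec:
    """Random multi-tone masker condition."""

    fpo: int = 32                  # frequencies per octave
    miti: float = 200.0            # mean inter-tone interval, ms
    interval_min: float = 100.0    # ms
    freq_lo: float = 239.0         # Hz
    freq_hi: float = 5000.0        # Hz
    tone_duration: float = 20.0    # ms
    ramp: float = 10.0             # ms
    density_label: int = 11        # s^-1 oct^-1, opaque condition label

    @property
    def interval_max(self) -> float:
        # uniform on [min, max] with mean miti
        return 2.0 * self.miti - self.interval_min

    @classmethod
    def from_density(cls, density: int) -> "MaskerSpec":
        if density not in DENSITY_PAIRS:
            raise ValueError(f"unknown density label {density!r}; "
                             f"expected one of {sorted(DENSITY_PAIRS)}")
        miti, fpo = DENSITY_PAIRS[density]
        return cls(fpo=fpo, miti=float(miti), density_label=density)


@dataclass(frozen=True)
class ToneEvent:
    """One pure-tone element of the masker or target."""

    onset: float       # s
    frequency: float   # Hz
    duration: float    # ms
    amplitude: float = 1.0  # linear; equal for masker and target (0 dB ratio)
    ramp: float = 10.0      # ms


def erb_bandwidth(f_khz: float) -> float:
    """Equivalent rectangular bandwidth in Hz for a frequency in kHz.

    ERB = 24.7 (4.37 F + 1), the Glasberg & Moore approximation of the
    auditory-filter bandwidth.
    """
    if f_khz < 0:
        raise ValueError("frequency must be nonnegative")
    return 24.7 * (4.37 * f_khz + 1.0)


def masker_frequencies(spec: MaskerSpec) -> np.ndarray:
    """Masker tone frequencies, log-spaced with ``fpo`` values per octave.

    Returns a geometric progression starting at ``freq_lo`` with ratio
    2**(1/fpo), truncated at ``freq_hi``.
    """
    if not spec.freq_lo < spec.freq_hi:
        raise ValueError("freq_lo must be below freq_hi")
    if spec.fpo <= 0:
        raise ValueError("fpo must be positive")
    n = math.floor(spec.fpo * math.log2(spec.freq_hi / spec.freq_lo)) + 1
    k = np.arange(n)
    return spec.freq_lo * 2.0 ** (k / spec.fpo)


def sample_tone_sequence(spec: MaskerSpec, trial_duration: float = 10.0,
                         rng: np.random.Generator | None = None) -> list[ToneEvent]:
    """Draw the masker tone events for one trial.

    Each masker frequency runs its own renewal process: the first onset is
    uniform on [0, interval_max] and successive inter-onset gaps are i.i.d.
    uniform on [interval_min, interval_max] (mean = miti).  Tones whose offset
    would exceed the trial duration are dropped.
    """
    if rng is None:
        rng = np.random.default_rng()
    if spec.interval_max < spec.interval_min:
        raise ValueError("interval_max below interval_min; check miti")
    lo, hi = spec.interval_min / 1000.0, spec.interval_max / 1000.0
    dur_s = spec.tone_duration / 1000.0
    events: list[ToneEvent] = []
    for f in masker_frequencies(spec):
        t = rng.uniform(0.0, hi)
        while t + dur_s <= trial_duration:
            events.append(ToneEvent(onset=t, frequency=float(f),
                                    duration=spec.tone_duration, ramp=spec.ramp))
            t += rng.uniform(lo, hi) if hi > lo else lo
    events.sort(key=lambda e: (e.onset, e.frequency))
    return events


def target_tone_sequence(target: TargetSpec, trial_duration: float = 10.0) -> list[ToneEvent]:
    """Regular target tone stream (empty when the target is absent)."""
    if not target.present:
        return []
    events = []
    t = target.onset / 1000.0
    step = 1.0 / target.repetition_rate
    dur_s = target.tone_duration / 1000.0
    while t + dur_s <= trial_duration:
        events.append(ToneEvent(onset=t, frequency=target.frequency,
                                duration=target.tone_duration, ramp=target.ramp))
        t += step
    return events


def apply_protected_region(tones: list[ToneEvent], target_freq: float) -> list[ToneEvent]:
    """Remove masker tones within +/- one ERB of the target frequency.

    The interval is closed on both ends: boundary tones are removed
    (conservative protection against energetic masking).
    """
    if target_freq <= 0:
        raise ValueError("target frequency must be positive")
    erb = erb_bandwidth(target_freq / 1000.0)
    lo, hi = target_freq - erb, target_freq + erb
    return [t for t in tones if not (lo <= t.frequency <= hi)]


def _synth_tone(event: ToneEvent, sr: int) -> np.ndarray:
    n = int(round(event.duration / 1000.0 * sr))
    t = np.arange(n) / sr
    x = event.amplitude * np.sin(2.0 * np.pi * event.frequency * t)
    n_ramp = int(round(event.ramp / 1000.0 * sr))
    if n_ramp > 0:
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= win
        x[-n_ramp:] *= win[::-1]
    return x


def render_waveform(masker_tones: list[ToneEvent], target: TargetSpec | None = None,
                    sr: int = 44100, trial_duration: float = 10.0,
                    peak_dbfs: float = -1.0) -> np.ndarray:
    """Render tone events to a mono float waveform in [-1, 1].

    Each tone is a raised-cosine-gated sine; overlapping tones sum.  The sum
    is peak-normalized to ``peak_dbfs`` so that 16-bit quantization cannot
    clip.  Target tones use the same per-tone amplitude as masker tones
    (0 dB target-to-masker ratio).
    """
    events = list(masker_tones)
    if target is not None:
        events = events + target_tone_sequence(target, trial_duration)
    out = np.zeros(int(round(trial_duration * sr)))
    for ev in events:
        x = _synth_tone(ev, sr)
        i0 = int(round(ev.onset * sr))
        out[i0:i0 + len(x)] += x
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 10.0 ** (peak_dbfs / 20.0) / peak
    if np.max(np.abs(out)) > 1.0:
        raise RuntimeError("normalized waveform exceeds full scale")
    return out


def write_wav(path, waveform: np.ndarray, sr: int = 44100) -> None:
    """Write a [-1, 1] float waveform as 16-bit PCM."""
    q = np.clip(np.round(waveform * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), sr, q)


def render_trial(density: int, target_freq: float | None, seed: int,
                 sr: int = 44100, trial_duration: float = 10.0):
    """Build and render one full trial; returns (waveform, metadata dict)."""
    spec = MaskerSpec.from_density(density)
    rng = np.random.default_rng(seed)
    masker = sample_tone_sequence(spec, trial_duration, rng)
    target = None
    if target_freq is not None:
        masker = apply_protected_region(masker, target_freq)
        target = TargetSpec(frequency=float(target_freq))
    wave = render_waveform(masker, target, sr=sr, trial_duration=trial_duration)
    meta = {
        "seed": seed,
        "sr": sr,
        "trial_duration": trial_duration,
        "masker_spec": asdict(spec) | {"interval_max": spec.interval_max},
        "target_spec": None if target is None else asdict(target),
        "masker_tones": [asdict(t) for t in masker],
    }
    return wave, meta


def write_metadata(path, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)
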