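"""Tone-locked evoked-potential analysis.

The four target tones nearest the time reference (B2, B1 before; A1, A2
after) are epoched from -200 to +500 ms around tone onset, baseline-corrected
on the pre-tone interval, averaged per electrode x tone x detection cell, and
the component peak is extracted as a signed extremum: the minimum in
50-350 ms for the awareness-related negativity (ARN), the maximum in
250-500 ms for the P300.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import signal as sig

TONE_LABELS = ("B2", "B1", "A1", "A2")

SPAN_S = (-0.2, 0.5)
BASELINE_S = (-0.2, 0.0)


@dataclass(frozen=True)
class ErpWindow:
    component: str        # "ARN" | "P300"
    search_s: tuple       # search interval relative to tone onset
    polarity: int         # -1 negative peak, +1 positive peak


ARN = ErpWindow("ARN", (0.050, 0.350), -1)
P300 = ErpWindow("P300", (0.250, 0.500), +1)
COMPONENTS = {"ARN": ARN, "P300": P300}


def label_tones(tone_times: np.ndarray, reference_s: float) -> dict[str, float]:
    """Assign B2/B1/A1/A2 to the tone onsets nearest the reference.

    B1/B2 are the closest and second-closest onsets strictly before the
    reference; A1/A2 the first and second at or after it.
    """
    tt = np.sort(np.asarray(tone_times, float))
    before = tt[tt < reference_s]
    after = tt[tt >= reference_s]
    if len(before) < 2 or len(after) < 2:
        raise ValueError("need two tones on each side of the reference")
    return {"B2": float(before[-2]), "B1": float(before[-1]),
            "A1": float(after[0]), "A2": float(after[1])}


def epoch_tone(signal_1d: np.ndarray, sr: float, tone_onset_s: float,
               span_s: tuple = SPAN_S, baseline_s: tuple = BASELINE_S) -> np.ndarray | None:
    """Baseline-corrected tone-locked waveform (None if out of bounds)."""
    i0 = int(round((tone_onset_s + span_s[0]) * sr))
    i1 = int(round((tone_onset_s + span_s[1]) * sr))
    if i0 < 0 or i1 > len(signal_1d):
        warnings.warn(f"tone at {tone_onset_s:.3f}s outside the epoch; skipped")
        return None
    w = np.asarray(signal_1d[i0:i1], float)
    b0 = int(round((baseline_s[0] - span_s[0]) * sr))
    b1 = int(round((baseline_s[1] - span_s[0]) * sr))
    return w - w[b0:b1].mean()


def grand_average(waveforms: list[np.ndarray]) -> np.ndarray:
    """Pointwise mean of equal-length waveforms."""
    if not waveforms:
        raise ValueError("empty waveform set")
    return np.mean(np.stack(waveforms), axis=0)


def peak_amplitude(avg_waveform: np.ndarray, window: ErpWindow, sr: float,
                   span_s: tuple = SPAN_S) -> float:
    """Signed extremum of the average waveform within the search interval."""
    i0 = int(round((window.search_s[0] - span_s[0]) * sr))
    i1 = int(round((window.search_s[1] - span_s[0]) * sr))
    seg = avg_waveform[i0:i1]
    return float(seg.min() if window.polarity < 0 else seg.max())


ARN_ELECTRODES = ("FT7", "FT8", "T7", "T8", "TP7", "TP8", "C5", "F6", "F7")
P300_ELECTRODES = ("FCz", "Cz", "CPz", "Pz")


def peak_table(epochs: sig.EpochArray, tone_times: np.ndarray,
               subject: str = "S01",
               electrodes: dict[str, tuple] | None = None) -> pd.DataFrame:
    """Per-subject component peak amplitudes.

    Tone-locked waveforms are averaged per electrode x tone x detection over
    the subject's trials, then the component peak is extracted.  Columns:
    subject, electrode, tone, detection, component, amplitude_uv, n_trials.
    """
    if electrodes is None:
        electrodes = {"ARN": ARN_ELECTRODES, "P300": P300_ELECTRODES}
    ref_idx = epochs.reference_index
    name_to_row = {ch: i for i, ch in enumerate(epochs.channel_names)}
    rows = []
    for component, elecs in electrodes.items():
        win = COMPONENTS[component]
        for elec in elecs:
            if elec not in name_to_row:
                continue
            r = name_to_row[elec]
            cells: dict[tuple, list] = {}
            for t in range(epochs.n_trials):
                tones = label_tones(tone_times[t], ref_idx / epochs.sr)
                for tone, onset in tones.items():
                    w = epoch_tone(epochs.data[t, r], epochs.sr, onset)
                    if w is not None:
                        cells.setdefault((tone, epochs.labels[t]), []).append(w)
            for (tone, detection), waves in sorted(cells.items()):
                avg = grand_average(waves)
                rows.append({"subject": subject, "electrode": elec, "tone": tone,
                             "detection": detection, "component": component,
                             "amplitude_uv": peak_amplitude(avg, win, epochs.sr),
                             "n_trials": len(waves)})
    return pd.DataFrame(rows)


def peak_contrast(epochs: sig.EpochArray, tone_times: np.ndarray, electrode: str,
                  component: str, tone: str = "B1",
                  n_jackknife: int | None = None) -> tuple[float, float]:
    """Hit-minus-miss peak contrast at one electrode, with a jackknife SE.

    The contrast is the difference of the peaks of the condition-average
    waveforms; its standard error is estimated by leave-one-trial-out
    jackknife over both conditions.
    """
    win = COMPONENTS[component]
    r = epochs.channel_names.index(electrode)
    ref_s = epochs.reference_index / epochs.sr
    waves = {"hit": [], "miss": []}
    for t in range(epochs.n_trials):
        onset = label_tones(tone_times[t], ref_s)[tone]
        w = epoch_tone(epochs.data[t, r], epochs.sr, onset)
        if w is not None:
            waves[epochs.labels[t]].append(w)
    sums = {k: np.sum(np.stack(v), axis=0) for k, v in waves.items()}
    ns = {k: len(v) for k, v in waves.items()}

    def contrast(sum_h, n_h, sum_m, n_m):
        return (peak_amplitude(sum_h / n_h, win, epochs.sr)
                - peak_amplitude(sum_m / n_m, win, epochs.sr))

    est = contrast(sums["hit"], ns["hit"], sums["miss"], ns["miss"])
    # delete-one jackknife variance, each condition resampled separately
    var = 0.0
    for k in ("hit", "miss"):
        other = "miss" if k == "hit" else "hit"
        loo = []
        for w in waves[k]:
            args = {k: (sums[k] - w, ns[k] - 1), other: (sums[other], ns[other])}
            loo.append(contrast(*args["hit"], *args["miss"]))
        loo = np.asarray(loo)
        var += (ns[k] - 1) / ns[k] * np.sum((loo - loo.mean()) ** 2)
    return float(est), float(np.sqrt(var))
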