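"""EEG preprocessing and topographic geometry.

Holds the epoch container, the 64-channel extended 10/20 montage, the
electrode-to-cluster map (nine cortical areas: eight lateral pairs merged per
area plus the sagittal midline), zero-phase band-pass filtering, average
re-referencing, epoch extraction around a per-trial time reference, Fourier
resampling, and cluster-wise aggregation of per-channel values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

#: 64-channel subset of the extended 10/20 system (mastoids TP9/TP10 serve as
#: the recording reference and Fpz as ground, so neither appears here).
MONTAGE_64 = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2",
)

CLUSTERS = ("AF", "F", "FC", "C", "CP", "P", "PO", "T", "S")

_ASSET = Path(__file__).parent / "data" / "cluster_map.yaml"


@dataclass
class EpochArray:
    """Trials x channels x samples block of epoched EEG (microvolts)."""

    data: np.ndarray
    sr: float
    channel_names: list[str]
    labels: list[str]                       # "hit" | "miss" per trial
    t0: float = -3.0                        # s of first sample w.r.t. reference

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.sr

    @property
    def reference_index(self) -> int:
        return int(round(-self.t0 * self.sr))


def channel_cluster(name: str) -> str:
    """Cluster of one electrode from its 10/20 name.

    Midline (z) electrodes form the sagittal cluster; FT/TP electrodes join
    the temporal cluster with T; Fp joins the antero-frontal cluster and O the
    parieto-occipital one.  This prefix reconstruction of the electrode
    aggregation scheme is shipped as an editable YAML asset for review.
    """
    if name.endswith("z"):
        return "S"
    stem = name.rstrip("0123456789")
    if stem in ("T", "FT", "TP"):
        return "T"
    if stem == "Fp":
        return "AF"
    if stem == "O":
        return "PO"
    if stem in CLUSTERS:
        return stem
    raise KeyError(f"cannot assign electrode {name!r} to a cluster")


def build_cluster_map(channels=MONTAGE_64) -> dict[str, str]:
    """Channel -> cluster mapping for a channel list (prefix rules)."""
    return {ch: channel_cluster(ch) for ch in channels}


def load_cluster_map(path=None) -> dict[str, str]:
    """Load the channel -> cluster map from the shipped (or given) YAML asset."""
    p = Path(path) if path is not None else _ASSET
    with open(p) as fh:
        return yaml.safe_load(fh)


def bandpass(x: np.ndarray, sr: float, lo: float = 1.0, hi: float = 80.0,
             order: int = 4) -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    4th-order Butterworth applied forward and backward (non-causal): the
    1-80 Hz pass band at twice the nominal order and zero phase lag.
    """
    if sr <= 2 * hi:
        raise ValueError(f"sampling rate {sr} too low for {hi} Hz upper edge")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sr, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def rereference_average(data: np.ndarray, channel_axis: int = -2) -> np.ndarray:
    """Subtract the instantaneous mean over channels (average reference)."""
    if data.shape[channel_axis] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return data - data.mean(axis=channel_axis, keepdims=True)


def extract_epoch(cont: np.ndarray, sr: float, reference_time: float,
                  half_width: float = 3.0) -> np.ndarray | None:
    """Cut one channels x samples epoch around a time reference.

    Returns exactly ``2 * half_width * sr`` samples with the reference at the
    center; hit trials use the press time, miss trials the fixed 3.4 s
    group-average detection time.  Returns None (and warns) when the
    recording does not cover the span.
    """
    cont = np.atleast_2d(cont)
    n = int(round(2 * half_width * sr))
    i0 = int(round((reference_time - half_width) * sr))
    if i0 < 0 or i0 + n > cont.shape[-1]:
        warnings.warn(f"epoch at reference {reference_time:.3f}s out of bounds; dropped")
        return None
    return cont[..., i0:i0 + n]


MISS_REFERENCE_S = 3.4


def resample(x: np.ndarray, sr_in: float, sr_out: float) -> np.ndarray:
    """Fourier-method resampling along the last axis.

    The epochs span an integer number of seconds, so the output length
    ``n * sr_out / sr_in`` is exact; scipy's FFT resampler provides the
    implicit anti-alias filtering on decimation.
    """
    if sr_out <= 0:
        raise ValueError("sr_out must be positive")
    n_out = x.shape[-1] * sr_out / sr_in
    if abs(n_out - round(n_out)) > 1e-9:
        raise ValueError("non-integer output length; choose commensurate rates")
    return sps.resample(x, int(round(n_out)), axis=-1)


def cluster_aggregate(values: dict[str, float] | "pd.Series",
                      cluster_map: dict[str, str] | None = None) -> dict[str, float]:
    """Unweighted mean of per-channel values within each cluster."""
    if cluster_map is None:
        cluster_map = build_cluster_map(list(values.keys()))
    unknown = [ch for ch in values if ch not in cluster_map]
    if unknown:
        raise KeyError(f"channels missing from cluster map: {unknown}")
    sums: dict[str, list[float]] = {}
    for ch, v in dict(values).items():
        sums.setdefault(cluster_map[ch], []).append(v)
    return {c: float(np.mean(v)) for c, v in sums.items()}


def read_edf(path, picks=None):
    """Read a real EDF recording into (data uV, sr, channel names) via MNE.

    Provided as the entry point for re-analysis of real data; the synthetic
    pipeline never needs it.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if picks is not None:
        raw.pick(picks)
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def clean_epochs_hook(epochs: EpochArray) -> EpochArray:
    """Artifact-repair pass-through.

    Real recordings would be cleaned with ICA ocular correction and
    autoreject-style repair before this stage; synthetic data are
    artifact-free, so the hook returns its input unchanged.
    """
    return epochs
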