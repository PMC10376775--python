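"""Windowed signal-entropy estimators.

Five estimators quantify the information content of short EEG windows:
spectral entropy (SpEn, Shannon entropy of the normalized power spectrum),
approximate entropy (ApEn, Pincus' self-inclusive template statistic), sample
entropy (SaEn, Richman-Moorman, self-matches excluded), permutation entropy
(PeEn, entropy of ordinal patterns) and singular-value-decomposition entropy
(SvEn, entropy of the normalized singular spectrum of the delay embedding).

Each 6-s epoch is oversampled to 4 kHz and split into 24 contiguous windows
of 1000 samples (12 per side of the time reference); by default the two
epoch-edge windows are dropped as filter-edge guards, leaving the 11+11
windows that enter the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial, lgamma

import numpy as np
import pandas as pd

from . import signal as sig

try:  # fast O(N^2) template counting
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

ENTROPY_SR = 4000.0
WINDOW_SAMPLES = 1000
N_WINDOWS = 24
MEASURES = ("SpEn", "ApEn", "SaEn", "PeEn", "SvEn")


@dataclass(frozen=True)
class EntropyParams:
    m: int = 2            # ApEn/SaEn embedding length
    r: float = 0.2        # ApEn/SaEn tolerance, fraction of the window SD
    order: int = 3        # PeEn/SvEn embedding order
    delay: int = 1        # PeEn/SvEn embedding delay, samples
    normalize: bool = True          # SpEn / PeEn / SvEn in [0, 1]
    spectrum: str = "periodogram"   # or "welch"

    def __post_init__(self):
        if self.m < 1 or self.order < 2 or self.delay < 1 or self.r <= 0:
            raise ValueError("invalid entropy parameters")


def window_epoch(epoch: np.ndarray) -> np.ndarray:
    """Split one 24000-sample (6 s at 4 kHz) vector into 24 x 1000 windows."""
    epoch = np.asarray(epoch)
    if epoch.shape[-1] != N_WINDOWS * WINDOW_SAMPLES:
        raise ValueError(f"expected {N_WINDOWS * WINDOW_SAMPLES} samples, "
                         f"got {epoch.shape[-1]}")
    return epoch.reshape(*epoch.shape[:-1], N_WINDOWS, WINDOW_SAMPLES)


def analysis_windows(drop_edges: bool = True) -> list[int]:
    """Indices of the windows entering the statistics (11 before + 11 after)."""
    return list(range(1, 23)) if drop_edges else list(range(24))


def window_condition(index: int) -> str:
    """'before' or 'after' the time reference for a window index (0..23)."""
    return "before" if index < N_WINDOWS // 2 else "after"


def spectral_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Shannon entropy of the power spectrum as a probability distribution.

    Raw-periodogram bins by default (Welch with 8 segments switchable);
    normalized by log of the number of bins.
    """
    x = np.asarray(x, float)
    if params.spectrum == "welch":
        from scipy.signal import welch
        _, psd = welch(x, nperseg=max(len(x) // 8, 16))
    else:
        X = np.fft.rfft(x - x.mean())
        psd = np.abs(X) ** 2
    total = psd.sum()
    if total == 0:
        warnings.warn("all-zero window: spectral entropy defined as 0")
        return 0.0
    p = psd / total
    p = p[p > 0]
    h = -np.sum(p * np.log(p))
    if params.normalize:
        h /= np.log(len(psd))
    return float(h)


def _template_stats_py(x, m, r):
    """Shared template counts for ApEn and SaEn (one O(N^2) distance pass).

    Returns (c_m, c_m1, A, B): per-template self-inclusive match counts of
    lengths m and m+1 over their Pincus template sets, and the SaEn pair
    counts (self-matches excluded) over the common N-m template set.
    """
    n = x.shape[0]
    n_m = n - m + 1       # ApEn templates of length m
    n_m1 = n - m          # ApEn templates of length m+1 / SaEn templates
    c_m = np.ones(n_m)    # self-matches included
    c_m1 = np.ones(n_m1)
    a = 0
    b = 0
    for i in range(n_m):
        for j in range(i + 1, n_m):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                c_m[i] += 1.0
                c_m[j] += 1.0
                if i < n_m1 and j < n_m1:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
                        c_m1[i] += 1.0
                        c_m1[j] += 1.0
    return c_m, c_m1, a, b


if _HAVE_NUMBA:
    _template_stats = njit(cache=False)(_template_stats_py)
else:  # pragma: no cover - numba is available in the supported environment
    _template_stats = _template_stats_py


def _apen_from_counts(c_m, c_m1) -> float:
    phi_m = float(np.mean(np.log(c_m / len(c_m))))
    phi_m1 = float(np.mean(np.log(c_m1 / len(c_m1))))
    return phi_m - phi_m1


def approximate_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Pincus approximate entropy with self-inclusive Chebyshev matching.

    ApEn = Phi_m - Phi_{m+1}; tolerance r is taken relative to the window SD,
    making the estimate invariant to affine rescaling of the input.
    """
    x = np.asarray(x, float)
    if len(x) <= params.m + 1:
        raise ValueError("series too short for the embedding length")
    sd = x.std()
    if sd == 0:
        return 0.0
    c_m, c_m1, _, _ = _template_stats(x, params.m, params.r * sd)
    return _apen_from_counts(c_m, c_m1)


def sample_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Richman-Moorman sample entropy, -log(A/B).

    A and B count length-(m+1) and length-m template pairs within Chebyshev
    distance r over the same N-m templates, self-matches excluded.  Returns
    NaN with a warning when either count is zero.
    """
    x = np.asarray(x, float)
    if len(x) <= params.m + 1:
        raise ValueError("series too short for the embedding length")
    sd = x.std()
    if sd == 0:
        return 0.0
    _, _, a, b = _template_stats(x, params.m, params.r * sd)
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined (no template matches)")
        return float("nan")
    return float(-np.log(a / b))


def _ordinal_patterns(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    n = len(x) - (order - 1) * delay
    idx = np.arange(order) * delay + np.arange(n)[:, None]
    # stable argsort: tied values rank in order of occurrence
    return np.argsort(x[idx], axis=1, kind="stable")


def permutation_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Shannon entropy of the ordinal-pattern distribution.

    Ties are broken by order of occurrence (earlier sample ranks lower), so a
    constant series yields a single pattern and zero entropy.  Normalized by
    log(order!).
    """
    x = np.asarray(x, float)
    if len(x) < params.order * params.delay + 1:
        raise ValueError("series too short for the ordinal embedding")
    pats = _ordinal_patterns(x, params.order, params.delay)
    _, counts = np.unique(pats, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    if params.normalize:
        h /= np.log(factorial(params.order))
    return float(h)


def svd_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Shannon entropy of the normalized singular-value spectrum.

    The delay-embedding matrix (order columns) is decomposed; singular values
    are normalized to sum to one.  Normalized by log(order).
    """
    x = np.asarray(x, float)
    n = len(x) - (params.order - 1) * params.delay
    if n < 1:
        raise ValueError("series too short for the embedding")
    idx = np.arange(params.order) * params.delay + np.arange(n)[:, None]
    emb = x[idx]
    s = np.linalg.svd(emb, compute_uv=False)
    total = s.sum()
    if total == 0:
        warnings.warn("all-zero window: SVD entropy defined as 0")
        return 0.0
    p = s / total
    p = p[p > 1e-15]
    h = -np.sum(p * np.log(p))
    if params.normalize:
        h /= np.log(params.order)
    return float(h)


_FUNCS = {
    "SpEn": spectral_entropy,
    "ApEn": approximate_entropy,
    "SaEn": sample_entropy,
    "PeEn": permutation_entropy,
    "SvEn": svd_entropy,
}


def window_measures(window: np.ndarray, measures=MEASURES,
                    params: EntropyParams = EntropyParams()) -> dict[str, float]:
    out = {}
    if "ApEn" in measures and "SaEn" in measures:
        # share the O(N^2) template-distance pass between the two estimators
        x = np.asarray(window, float)
        sd = x.std()
        if sd == 0:
            out["ApEn"] = out["SaEn"] = 0.0
        else:
            c_m, c_m1, a, b = _template_stats(x, params.m, params.r * sd)
            out["ApEn"] = _apen_from_counts(c_m, c_m1)
            if a == 0 or b == 0:
                warnings.warn("sample entropy undefined (no template matches)")
                out["SaEn"] = float("nan")
            else:
                out["SaEn"] = float(-np.log(a / b))
    for m in measures:
        if m not in out:
            out[m] = _FUNCS[m](window, params)
    return out


def epoch_features(epoch_1khz: np.ndarray, sr: float = 1000.0, measures=MEASURES,
                   params: EntropyParams = EntropyParams(),
                   drop_edges: bool = True) -> pd.DataFrame:
    """Entropy features of one channels x samples epoch.

    The epoch is oversampled to 4 kHz, cut into 1000-sample windows, and every
    measure is computed per channel and window.  Returns a long table with
    columns channel, window_index, condition, measure, value.
    """
    x4 = sig.resample(np.asarray(epoch_1khz, float), sr, ENTROPY_SR)
    wins = window_epoch(x4)  # channels x 24 x 1000
    keep = analysis_windows(drop_edges)
    rows = []
    for ch in range(wins.shape[0]):
        for w in keep:
            vals = window_measures(wins[ch, w], measures, params)
            for m, v in vals.items():
                rows.append((ch, w, window_condition(w), m, v))
    return pd.DataFrame(rows, columns=["channel", "window_index", "condition",
                                       "measure", "value"])


def compute_features(epochs: sig.EpochArray, subject: str = "S01",
                     measures=MEASURES, params: EntropyParams = EntropyParams(),
                     cluster_map: dict[str, str] | None = None,
                     drop_edges: bool = True) -> pd.DataFrame:
    """Long-format feature table for a set of epochs.

    Per-channel window entropies are aggregated to the nine topographic
    clusters by unweighted averaging.  Columns: subject, trial, detection,
    condition, cluster, window_index, measure, value.
    """
    if cluster_map is None:
        cluster_map = sig.build_cluster_map(epochs.channel_names)
    ch_cluster = np.array([cluster_map[ch] for ch in epochs.channel_names])
    out = []
    for t in range(epochs.n_trials):
        feats = epoch_features(epochs.data[t], epochs.sr, measures, params, drop_edges)
        feats["cluster"] = ch_cluster[feats["channel"].to_numpy()]
        agg = (feats.groupby(["window_index", "condition", "measure", "cluster"],
                             observed=True)["value"].mean().reset_index())
        agg.insert(0, "detection", epochs.labels[t])
        agg.insert(0, "trial", t)
        agg.insert(0, "subject", subject)
        out.append(agg)
    return pd.concat(out, ignore_index=True)
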