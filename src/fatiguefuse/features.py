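"""Time- and frequency-domain feature suites and the 6x60 fusion map.

Per sEMG channel 42 features are computed: 8 wavelet marginals, a
20-bin amplitude histogram, RMS, ZC, SSC, WL, MAV, MAVS, WAMP, 5
autoregressive coefficients, MNF and PSR.  Per accelerometer channel 6
features: MEAN, VAR, RMS, WL, MAV, MAVS.  The 18x6 ACC map is
transposed and appended to the 6x42 sEMG map, giving the fused 6x60
grid that feeds the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from statsmodels.regression.linear_model import yule_walker

from .preprocess import bandpass_semg
from .records import (
    Epoch,
    FeatureMap,
    N_ACC_CHANNELS,
    N_SEMG_CHANNELS,
    SEMG_RATE,
    SignalRecord,
    default_channel_labels,
)


@dataclass
class FeatureConfig:
    """Tunable knobs of the feature suite (defaults used throughout)."""

    eps_zc: float = 0.0  #: zero-crossing hysteresis threshold, amplitude units
    eps_ssc: float = 0.0  #: slope-sign-change threshold, amplitude^2 units
    wamp_sigma_factor: float = 0.1  #: eps_wamp = factor x per-channel std
    wavelet: str = "db2"
    dwt_levels: int = 7
    hist_bins: int = 20
    ar_order: int = 5
    mavs_segments: int = 2
    psr_halfwidth_hz: float = 10.0
    semg_fs: float = SEMG_RATE


_DEFAULT = FeatureConfig()


# ---------------------------------------------------------------- basic time

def basic_time_features(x: np.ndarray) -> dict[str, float]:
    """MEAN, population VAR, RMS, MAV and waveform length of one channel."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return {
        "MEAN": float(np.mean(x)),
        "VAR": float(np.var(x)),  # population (1/N)
        "RMS": float(np.sqrt(np.mean(x**2))),
        "MAV": float(np.mean(np.abs(x))),
        "WL": float(np.sum(np.abs(np.diff(x)))),
    }


def threshold_counts(
    x: np.ndarray,
    eps_zc: float = 0.0,
    eps_ssc: float = 0.0,
    eps_wamp: float = 0.0,
) -> dict[str, int]:
    """Zero crossings, slope sign changes and Willison amplitude counts.

    ZC counts consecutive pairs of opposite sign whose jump exceeds
    ``eps_zc``; SSC counts interior extrema whose two-sided slope
    product exceeds ``eps_ssc``; WAMP counts consecutive jumps larger
    than ``eps_wamp``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if min(eps_zc, eps_ssc, eps_wamp) < 0:
        raise ValueError("thresholds must be nonnegative")
    d = np.abs(np.diff(x))
    zc = int(np.sum((x[:-1] * x[1:] < 0) & (d > eps_zc)))
    ssc = int(np.sum((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > eps_ssc))
    wamp = int(np.sum(d > eps_wamp))
    return {"ZC": zc, "SSC": ssc, "WAMP": wamp}


def mav_slope(x: np.ndarray, n_seg: int = 2) -> np.ndarray:
    """Differences of mean absolute value between consecutive equal segments.

    With ``n_seg=2`` (the default used in the feature maps) this is the
    single scalar MAV(second half) - MAV(first half).
    """
    x = np.asarray(x, dtype=float).ravel()
    if n_seg < 2:
        raise ValueError("n_seg must be >= 2")
    seg_len = x.size // n_seg
    if seg_len < 1:
        raise ValueError("segments would be empty")
    segs = x[: seg_len * n_seg].reshape(n_seg, seg_len)
    mavs = np.mean(np.abs(segs), axis=1)
    return np.diff(mavs)


def spectral_features(
    x: np.ndarray, fs: float, psr_halfwidth_hz: float = 10.0
) -> dict[str, float]:
    """Mean frequency and power-spectrum ratio from a Hann periodogram.

    MNF is the power-weighted mean frequency; PSR is the fraction of
    total power within ``psr_halfwidth_hz`` of the spectral peak.  An
    all-zero signal yields MNF = PSR = 0 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 256:
        raise ValueError("need at least 256 samples for spectral features")
    if fs <= 0:
        raise ValueError("fs must be positive")
    f, p = sps.periodogram(x, fs=fs, window="hann")
    total = float(np.sum(p))
    if total <= 0:
        warnings.warn("zero-power signal: MNF and PSR undefined, returning 0")
        return {"MNF": 0.0, "PSR": 0.0}
    mnf = float(np.sum(f * p) / total)
    peak = f[int(np.argmax(p))]
    band = np.abs(f - peak) <= psr_halfwidth_hz
    psr = float(np.sum(p[band]) / total)
    return {"MNF": mnf, "PSR": psr}


def mdwt_marginals(x: np.ndarray, wavelet: str = "db2", levels: int = 7) -> np.ndarray:
    """Marginals (sum of |coefficients|) of a multi-level DWT.

    Returns ``levels + 1`` values: the approximation marginal first,
    then detail marginals coarse-to-fine.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2**levels:
        raise ValueError(f"signal too short for {levels}-level decomposition")
    coeffs = pywt.wavedec(x, wavelet, level=levels)  # [cA_L, cD_L, ..., cD_1]
    return np.array([float(np.sum(np.abs(c))) for c in coeffs])


def amplitude_histogram(x: np.ndarray, bins: int = 20) -> np.ndarray:
    """Normalized amplitude histogram over the mean +/- 3 sigma range.

    Out-of-range samples are clipped into the end bins; the returned
    frequencies sum to 1.  A zero-variance channel puts all mass in the
    central bin.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    mu, sigma = float(np.mean(x)), float(np.std(x))
    freqs = np.zeros(bins)
    if sigma == 0:
        freqs[bins // 2] = 1.0
        return freqs
    lo, hi = mu - 3 * sigma, mu + 3 * sigma
    clipped = np.clip(x, lo, hi)
    counts, _ = np.histogram(clipped, bins=bins, range=(lo, hi))
    return counts / x.size


def ar_coefficients(x: np.ndarray, order: int = 5) -> np.ndarray:
    """Yule-Walker AR coefficients of the mean-removed signal.

    Convention: x[t] = a1 x[t-1] + ... + a_order x[t-order] + e[t].
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= 10 * order:
        raise ValueError("signal too short for a stable AR fit")
    if np.var(x) == 0:
        raise ValueError("degenerate (constant) signal: AR model undefined")
    rho, _sigma = yule_walker(x - np.mean(x), order=order, method="mle")
    return np.asarray(rho, dtype=float)


# ---------------------------------------------------------------- map builders

def semg_feature_names(config: FeatureConfig = _DEFAULT) -> list[str]:
    """The 42 sEMG column names in their fixed order."""
    L = config.dwt_levels
    names = [f"mDWT_cA{L}"] + [f"mDWT_cD{k}" for k in range(L, 0, -1)]
    names += [f"HIST_{i + 1:02d}" for i in range(config.hist_bins)]
    names += ["RMS", "ZC", "SSC", "WL", "MAV", "MAVS", "WAMP"]
    names += [f"ARC_{i + 1}" for i in range(config.ar_order)]
    names += ["MNF", "PSR"]
    return names


ACC_FEATURE_NAMES = ["MEAN", "VAR", "RMS", "WL", "MAV", "MAVS"]


def _as_samples(epoch, expected_channels: int) -> np.ndarray:
    x = epoch.samples if isinstance(epoch, SignalRecord) else np.asarray(epoch, dtype=float)
    if x.ndim != 2 or x.shape[0] != expected_channels:
        raise ValueError(f"expected a {expected_channels}-channel segment, got shape {x.shape}")
    return x


def _semg_channel_features(x: np.ndarray, config: FeatureConfig) -> np.ndarray:
    basic = basic_time_features(x)
    eps_wamp = config.wamp_sigma_factor * float(np.std(x))
    counts = threshold_counts(x, config.eps_zc, config.eps_ssc, eps_wamp)
    spec = spectral_features(x, config.semg_fs, config.psr_halfwidth_hz)
    row = np.concatenate(
        [
            mdwt_marginals(x, config.wavelet, config.dwt_levels),
            amplitude_histogram(x, config.hist_bins),
            [
                basic["RMS"],
                counts["ZC"],
                counts["SSC"],
                basic["WL"],
                basic["MAV"],
                float(mav_slope(x, config.mavs_segments)[0]),
                counts["WAMP"],
            ],
            ar_coefficients(x, config.ar_order),
            [spec["MNF"], spec["PSR"]],
        ]
    )
    return row


def build_semg_map(epoch, config: FeatureConfig = _DEFAULT) -> FeatureMap:
    """6x42 feature map of a preprocessed sEMG epoch."""
    x = _as_samples(epoch, N_SEMG_CHANNELS)
    rows = (
        epoch.channels
        if isinstance(epoch, SignalRecord)
        else default_channel_labels("sEMG")
    )
    values = np.stack([_semg_channel_features(ch, config) for ch in x])
    return FeatureMap(rows=rows, columns=semg_feature_names(config), values=values, modality_tag="sEMG")


def build_acc_map(epoch, config: FeatureConfig = _DEFAULT) -> FeatureMap:
    """18x6 feature map of an accelerometer epoch."""
    x = _as_samples(epoch, N_ACC_CHANNELS)
    rows = (
        epoch.channels
        if isinstance(epoch, SignalRecord)
        else default_channel_labels("ACC")
    )
    values = np.empty((N_ACC_CHANNELS, len(ACC_FEATURE_NAMES)))
    for c, ch in enumerate(x):
        basic = basic_time_features(ch)
        values[c] = [
            basic["MEAN"],
            basic["VAR"],
            basic["RMS"],
            basic["WL"],
            basic["MAV"],
            float(mav_slope(ch, config.mavs_segments)[0]),
        ]
    return FeatureMap(rows=rows, columns=ACC_FEATURE_NAMES, values=values, modality_tag="ACC")


def fuse_feature_maps(semg_map: FeatureMap, acc_map: FeatureMap) -> FeatureMap:
    """Concatenate the sEMG map with the transposed ACC map -> 6x60.

    Row i of the fused map carries sEMG channel i's 42 features followed
    by ACC feature i evaluated on each of the 18 ACC channels, i.e.
    ``fused[i, 42 + j] == acc_map[j, i]``.
    """
    if semg_map.shape != (N_SEMG_CHANNELS, 42):
        raise ValueError(f"sEMG map must be 6x42, got {semg_map.shape}")
    if acc_map.shape != (N_ACC_CHANNELS, len(ACC_FEATURE_NAMES)):
        raise ValueError(f"ACC map must be 18x6, got {acc_map.shape}")
    values = np.hstack([semg_map.values, acc_map.values.T])
    columns = list(semg_map.columns) + [f"ACCT_{lab}" for lab in acc_map.rows]
    return FeatureMap(rows=semg_map.rows, columns=columns, values=values, modality_tag="fused")


def build_fused_map(epoch: Epoch, config: FeatureConfig = _DEFAULT) -> FeatureMap:
    """Fused 6x60 map of one aligned (sEMG, ACC) epoch."""
    return fuse_feature_maps(
        build_semg_map(epoch.semg, config), build_acc_map(epoch.acc, config)
    )


def fused_maps_from_dataset(
    triples,
    config: FeatureConfig = _DEFAULT,
    bandpass: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Run filtering + feature extraction over (sEMG, ACC, label) triples.

    Returns ``(X, y)`` with ``X`` of shape (n, 6, 60) and ``y`` the
    label strings.  Band-pass filtering of the sEMG records (20-500 Hz)
    is applied before feature extraction unless disabled.
    """
    maps, labels = [], []
    for semg, acc, label in triples:
        if bandpass:
            semg = bandpass_semg(semg)
        fused = fuse_feature_maps(build_semg_map(semg, config), build_acc_map(acc, config))
        maps.append(fused.values)
        labels.append(label)
    return np.stack(maps), np.asarray(labels)
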