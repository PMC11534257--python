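"""The three attention mechanisms: envelope (LFAM), SENet, simAM.

LFAM (local feature attention) standardizes each row of a map and
re-weights it by its normalized Hilbert amplitude envelope, amplifying
local bursts while leaving stationary rows essentially unchanged.

SENet channel attention squeezes each channel to its global average and
passes the vector through a two-layer bottleneck gate
``sigmoid(W2 . relu(W1 . x_sq))`` whose output rescales the channels.

simAM neuron attention is parameter-free: each neuron q in a channel is
scored by the closed-form minimum of a linear-separability energy,

    e*(q) = 4 (sigma^2 + lambda) / ((q - mu)^2 + 2 sigma^2 + 2 lambda),

with mu, sigma^2 the channel's pooled mean and population variance.
Distinctive neurons (far from the channel mean) get low energy, hence a
large weight sigmoid(1/e*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import zscore


@dataclass
class EnvelopeSequence:
    """Amplitude envelope A(t) and instantaneous phase of a sequence."""

    envelope: np.ndarray
    phase: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.envelope.shape != (self.source_length,):
            raise ValueError("envelope length must equal source length")
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be nonnegative")


def hilbert_envelope(x: np.ndarray) -> EnvelopeSequence:
    """Amplitude envelope via the analytic signal.

    A(t) = sqrt(x(t)^2 + H[x](t)^2) where H is the discrete Hilbert
    transform (frequency-domain analytic-signal construction).  The
    modulus of the analytic signal bounds |x| from above at every
    sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    analytic = hilbert(x)
    return EnvelopeSequence(
        envelope=np.abs(analytic),
        phase=np.angle(analytic),
        source_length=x.size,
    )


def lfam_apply(x: np.ndarray) -> np.ndarray:
    """Envelope-weighted standardization of each row of a map.

    Per row: z = zscore(row); w = A(z) / mean(A(z)); output = z * w.
    The normalization by the mean envelope makes the weights hover
    around 1 for stationary rows, so quiet signals pass through nearly
    unchanged while localized bursts are amplified.  Constant rows
    standardize to zero and stay zero.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    rows = np.atleast_2d(x)
    out = np.empty_like(rows, dtype=float)
    for i, row in enumerate(rows):
        z = zscore(row)
        if not np.any(z):
            out[i] = 0.0
            continue
        env = hilbert_envelope(z).envelope
        out[i] = z * (env / env.mean())
    return out[0] if squeeze else out


@dataclass
class SENetParams:
    """Bottleneck gate weights of one squeeze-and-excitation block."""

    W1: np.ndarray  # (C_reduced, C)
    W2: np.ndarray  # (C, C_reduced)
    r: int

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        if self.W1.ndim != 2 or self.W2.ndim != 2:
            raise ValueError("W1 and W2 must be matrices")
        h, c = self.W1.shape
        if self.W2.shape != (c, h):
            raise ValueError(f"W2 must be {(c, h)}, got {self.W2.shape}")
        if self.r < 1:
            raise ValueError("reduction factor must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.W1.shape[1]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.W2.size

    @classmethod
    def init(cls, n_channels: int, r: int, rng: np.random.Generator) -> "SENetParams":
        """Glorot-uniform initialization; reduced width is ``n_channels // r``."""
        h = max(1, n_channels // r)
        lim1 = np.sqrt(6.0 / (n_channels + h))
        lim2 = np.sqrt(6.0 / (h + n_channels))
        return cls(
            W1=rng.uniform(-lim1, lim1, size=(h, n_channels)),
            W2=rng.uniform(-lim2, lim2, size=(n_channels, h)),
            r=r,
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def senet_squeeze(x: np.ndarray) -> np.ndarray:
    """Global average pooling per channel: x_sq[c] = mean_n X[c, n]."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (channels, length) map")
    return x.mean(axis=1)


def senet_excite(x_sq: np.ndarray, params: SENetParams) -> np.ndarray:
    """Two-layer gate: s = sigmoid(W2 . relu(W1 . x_sq)), each s in (0, 1)."""
    x_sq = np.asarray(x_sq, dtype=float).ravel()
    if x_sq.size != params.n_channels:
        raise ValueError(
            f"expected {params.n_channels} channel values, got {x_sq.size}"
        )
    return _sigmoid(params.W2 @ np.maximum(params.W1 @ x_sq, 0.0))


def senet_apply(x: np.ndarray, params: SENetParams) -> np.ndarray:
    """Rescale each channel by its excitation weight."""
    x = np.asarray(x, dtype=float)
    s = senet_excite(senet_squeeze(x), params)
    return s[:, None] * x


@dataclass
class SimamConfig:
    """simAM regularization strength (lambda > 0 keeps energies finite)."""

    lam: float = 1e-4

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def simam_energy(x: np.ndarray, config: SimamConfig | None = None) -> np.ndarray:
    """Closed-form minimum energy of every neuron, per channel.

    Uses pooled channel statistics (mean and population variance over
    all N neurons).  A neuron exactly at the channel mean has energy 2
    for any lambda and variance; constant channels give energy 2
    everywhere.
    """
    config = config or SimamConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (channels, length) map")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 neurons per channel")
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)  # population convention
    return 4.0 * (var + config.lam) / ((x - mu) ** 2 + 2.0 * var + 2.0 * config.lam)


def simam_apply(x: np.ndarray, config: SimamConfig | None = None) -> np.ndarray:
    """Weight each neuron by sigmoid(1/e*): output in (0.5, 1) times input."""
    x = np.asarray(x, dtype=float)
    e = simam_energy(x, config)
    return _sigmoid(1.0 / e) * x
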