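"""Synthetic labeled sEMG + accelerometer recordings.

The generator emulates the qualitative physiology of cycling-induced
muscle fatigue: as the muscle tires, motor-fiber conduction slows, so
the mean power frequency (MNF) of the surface EMG drifts downward while
its amplitude grows (more fibers recruited to hold the same power);
simultaneously limb motion becomes more variable around the pedalling
cadence.  Each fatigue state therefore gets a narrowband sEMG spectral
center (decreasing Relax → Transition → Tired), an sEMG gain
(increasing), and an accelerometer tremor amplitude (increasing) on top
of a fixed-cadence sinusoid.

Everything is driven by integer seeds; identical configuration yields
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .records import (
    ACC_RATE,
    CLASSES,
    N_ACC_CHANNELS,
    N_SEMG_CHANNELS,
    SEMG_RATE,
    SignalRecord,
    default_channel_labels,
)

_MODALITY_STREAM = {"sEMG": 0, "ACC": 1}


@dataclass
class SynthConfig:
    """Parameters of the synthetic recordings.

    Per-class values are mappings keyed by the fatigue state. Spectral
    centers must decrease and gains/tremor amplitudes increase over
    Relax → Transition → Tired; these orderings are what make the
    classes separable in the directions real fatigue moves.
    """

    #: narrowband sEMG spectral center per class, Hz
    semg_center_hz: dict = field(
        default_factory=lambda: {"Relax": 120.0, "Transition": 95.0, "Tired": 70.0}
    )
    #: sEMG RMS gain per class (dimensionless)
    semg_gain: dict = field(
        default_factory=lambda: {"Relax": 1.0, "Transition": 1.3, "Tired": 1.7}
    )
    #: width of the narrowband sEMG component, Hz
    semg_bandwidth_hz: float = 60.0
    #: pedalling cadence, Hz (1.2 Hz ~ 72 rpm)
    cadence_hz: float = 1.2
    #: amplitude of the cadence sinusoid in every ACC channel
    cadence_amplitude: float = 1.0
    #: white tremor amplitude per class on ACC channels
    acc_tremor: dict = field(
        default_factory=lambda: {"Relax": 0.1, "Transition": 0.2, "Tired": 0.4}
    )
    #: broadband noise floor added to every channel of both modalities
    noise_floor: float = 0.05
    #: length of each generated record, seconds
    duration: float = 10.0
    #: records generated per class by :func:`generate_dataset`
    epochs_per_class: int = 100
    #: master seed
    seed: int = 0

    def __post_init__(self) -> None:
        c = [self.semg_center_hz[s] for s in CLASSES]
        g = [self.semg_gain[s] for s in CLASSES]
        a = [self.acc_tremor[s] for s in CLASSES]
        if not (c[0] > c[1] > c[2]):
            raise ValueError("sEMG centers must strictly decrease Relax→Tired")
        if not (g[0] < g[1] < g[2]):
            raise ValueError("sEMG gains must strictly increase Relax→Tired")
        if min(g) < 0 or min(a) < 0 or self.noise_floor < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.cadence_hz <= 0 or self.semg_bandwidth_hz <= 0:
            raise ValueError("frequencies must be positive")


def _check_state(state: str) -> int:
    if state not in CLASSES:
        raise ValueError(f"unknown state label {state!r}; expected one of {CLASSES}")
    return CLASSES.index(state)


def _rng(seed: int, state_idx: int, modality: str) -> np.random.Generator:
    # independent, reproducible stream per (seed, state, modality)
    ss = np.random.SeedSequence([int(seed), state_idx, _MODALITY_STREAM[modality]])
    return np.random.default_rng(ss)


def generate_semg(state: str, config: SynthConfig | None = None, seed: int = 0) -> SignalRecord:
    """Generate one 6-channel sEMG record at 2000 Hz for a fatigue state.

    Each channel is white Gaussian noise shaped by a 4th-order
    Butterworth band-pass centered on the class spectral center
    (bandwidth ``semg_bandwidth_hz``), normalized to unit RMS and scaled
    by the class gain, plus a broadband noise floor.  The periodogram
    mean frequency of a channel is therefore close to the configured
    center, and its RMS tracks the class gain.
    """
    config = config or SynthConfig()
    state_idx = _check_state(state)
    if config.duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed, state_idx, "sEMG")
    n = int(round(config.duration * SEMG_RATE))
    fc = config.semg_center_hz[state]
    half_bw = config.semg_bandwidth_hz / 2.0
    lo, hi = fc - half_bw, fc + half_bw
    if lo <= 0 or hi >= SEMG_RATE / 2:
        raise ValueError("class band extends outside (0, Nyquist)")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=SEMG_RATE, output="sos")
    white = rng.standard_normal((N_SEMG_CHANNELS, n))
    shaped = signal.sosfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    gain = config.semg_gain[state]
    samples = gain * shaped / rms + config.noise_floor * rng.standard_normal((N_SEMG_CHANNELS, n))
    return SignalRecord(
        modality="sEMG",
        sample_rate=SEMG_RATE,
        channels=default_channel_labels("sEMG"),
        samples=samples,
    )


def generate_acc(state: str, config: SynthConfig | None = None, seed: int = 0) -> SignalRecord:
    """Generate one 18-channel accelerometer record at 20 Hz.

    Each channel is a unit sinusoid at the pedalling cadence (random
    phase per channel, drawn once per epoch) plus class-scaled white
    tremor and the broadband noise floor; variance grows with fatigue.
    """
    config = config or SynthConfig()
    state_idx = _check_state(state)
    if config.duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed, state_idx, "ACC")
    n = int(round(config.duration * ACC_RATE))
    t = np.arange(n) / ACC_RATE
    phases = rng.uniform(0.0, 2.0 * np.pi, size=N_ACC_CHANNELS)
    base = config.cadence_amplitude * np.sin(
        2.0 * np.pi * config.cadence_hz * t[None, :] + phases[:, None]
    )
    tremor = config.acc_tremor[state] * rng.standard_normal((N_ACC_CHANNELS, n))
    floor = config.noise_floor * rng.standard_normal((N_ACC_CHANNELS, n))
    return SignalRecord(
        modality="ACC",
        sample_rate=ACC_RATE,
        channels=default_channel_labels("ACC"),
        samples=base + tremor + floor,
    )


def generate_dataset(config: SynthConfig | None = None) -> list[tuple[SignalRecord, SignalRecord, str]]:
    """Balanced labeled dataset of time-aligned (sEMG, ACC, label) triples.

    ``epochs_per_class`` records are generated per state.  The master
    seed deterministically derives one seed per triple (``seed + i`` for
    the i-th triple), so any epoch can be regenerated in isolation.
    """
    config = config or SynthConfig()
    if config.epochs_per_class < 1:
        raise ValueError("epochs_per_class must be >= 1")
    triples: list[tuple[SignalRecord, SignalRecord, str]] = []
    i = 0
    for state in CLASSES:
        for _ in range(config.epochs_per_class):
            epoch_seed = config.seed + i
            semg = generate_semg(state, config, seed=epoch_seed)
            acc = generate_acc(state, config, seed=epoch_seed)
            triples.append((semg, acc, state))
            i += 1
    return triples
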