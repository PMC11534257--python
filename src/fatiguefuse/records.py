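"""Core data containers shared across the pipeline.

The pipeline moves three kinds of objects around: raw multichannel time
series (:class:`SignalRecord`), per-epoch feature grids
(:class:`FeatureMap`), and multichannel activation maps inside the
network (plain ``(C, N)`` arrays, wrapped as :class:`TensorMap` where a
typed container helps).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Ordered fatigue states, from rested to exhausted.
CLASSES: tuple[str, ...] = ("Relax", "Transition", "Tired")

SEMG_RATE = 2000.0  #: sEMG sampling rate, Hz
ACC_RATE = 20.0  #: accelerometer sampling rate, Hz
N_SEMG_CHANNELS = 6
N_ACC_CHANNELS = 18

_EXPECTED_CHANNELS = {"sEMG": N_SEMG_CHANNELS, "ACC": N_ACC_CHANNELS}


def default_channel_labels(modality: str) -> list[str]:
    """Standard channel labels, e.g. ``sEMG_ch01`` … or ``ACC_ch01`` …"""
    n = _EXPECTED_CHANNELS[modality]
    return [f"{modality}_ch{i + 1:02d}" for i in range(n)]


@dataclass
class SignalRecord:
    """One modality's multichannel recording.

    Parameters
    ----------
    modality : {"sEMG", "ACC"}
    sample_rate : float
        Samples per second; 2000 for sEMG, 20 for ACC in this study.
    channels : sequence of str
        Ordered channel labels; length must match ``samples.shape[0]``.
    samples : ndarray, shape (n_channels, n_samples)
    start_time : float
        Offset of the first sample, seconds.
    """

    modality: str
    sample_rate: float
    channels: Sequence[str]
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in _EXPECTED_CHANNELS:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) grid")
        self.channels = list(self.channels)
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel labels do not match sample rows")
        expected = _EXPECTED_CHANNELS[self.modality]
        if len(self.channels) != expected:
            raise ValueError(
                f"{self.modality} records carry {expected} channels, "
                f"got {len(self.channels)}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "SignalRecord":
        """Copy of this record carrying new samples of the same shape."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def slice_time(self, t0: float, t1: float) -> "SignalRecord":
        """Sub-record covering ``[t0, t1)`` seconds relative to start."""
        i0 = int(round(t0 * self.sample_rate))
        i1 = int(round(t1 * self.sample_rate))
        return replace(
            self,
            samples=self.samples[:, i0:i1].copy(),
            start_time=self.start_time + t0,
        )


@dataclass
class FeatureMap:
    """2-D grid of named scalar features (rows = channels/rows, cols = features)."""

    rows: Sequence[str]
    columns: Sequence[str]
    values: np.ndarray
    modality_tag: str = "fused"  # {"sEMG", "ACC", "fused"}

    def __post_init__(self) -> None:
        self.rows = list(self.rows)
        self.columns = list(self.columns)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.rows)} rows x {len(self.columns)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.columns)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, modality_tag: str = "fused") -> "FeatureMap":
        return cls(
            rows=list(frame.index),
            columns=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            modality_tag=modality_tag,
        )


@dataclass
class Epoch:
    """One aligned (sEMG, ACC) window with its fatigue label."""

    semg: SignalRecord
    acc: SignalRecord
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class EpochSet:
    """Ordered collection of labeled, time-aligned 10-s windows."""

    epochs: list[Epoch]
    epoch_duration: float = 10.0
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i):
        return self.epochs[i]

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]


@dataclass
class TensorMap:
    """Multichannel 1-D activation map, ``(channels, length)``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("TensorMap is a (channels, length) grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite activations")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]
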