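"""Filtering, epoch segmentation and standardization of raw records.

sEMG is band-passed to the physiological 20-500 Hz band with a
zero-phase 4th-order Butterworth (forward-backward), optionally notched
at 50 Hz mains, then both modalities are cut into non-overlapping 10-s
windows.  Standardization uses the population (1/N) convention
throughout the package.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .records import CLASSES, Epoch, EpochSet, SignalRecord


def bandpass_semg(
    record: SignalRecord, low: float = 20.0, high: float = 500.0, order: int = 4
) -> SignalRecord:
    """Zero-phase Butterworth band-pass of an sEMG record.

    Applied forward-backward per channel (``sosfiltfilt``) so waveform
    timing is preserved for later envelope work.
    """
    if record.modality != "sEMG":
        raise ValueError("bandpass_semg expects an sEMG record")
    nyq = record.sample_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < {low} < {high} < Nyquist ({nyq})")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=record.sample_rate, output="sos")
    return record.with_samples(signal.sosfiltfilt(sos, record.samples, axis=1))


def notch_50hz(record: SignalRecord, enabled: bool = True, q: float = 30.0) -> SignalRecord:
    """Optional 50 Hz mains notch (2nd-order IIR, zero phase).

    Identity when ``enabled`` is false.
    """
    if not enabled:
        return record
    if record.sample_rate <= 100.0:
        raise ValueError("sample rate too low for a 50 Hz notch")
    b, a = signal.iirnotch(50.0, q, fs=record.sample_rate)
    return record.with_samples(signal.filtfilt(b, a, record.samples, axis=1))


def _label_at(label_track, t: float) -> str:
    """Label in force at time ``t``; track is a label or (time, label) steps."""
    if isinstance(label_track, str):
        label = label_track
    else:
        steps = sorted(label_track, key=lambda p: p[0])
        if not steps or t < steps[0][0]:
            raise ValueError(f"no label defined at t={t}")
        label = steps[0][1]
        for t0, lab in steps:
            if t0 <= t:
                label = lab
            else:
                break
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}")
    return label


def segment_epochs(
    semg: SignalRecord,
    acc: SignalRecord,
    label_track,
    epoch_s: float = 10.0,
    provenance: str = "",
) -> EpochSet:
    """Cut aligned sEMG/ACC recordings into non-overlapping labeled windows.

    ``label_track`` is either a single class label applying throughout,
    or a sequence of ``(start_time, label)`` steps; each window takes
    the label in force at its start.  A trailing partial window is
    discarded.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    slack = 1.0 / acc.sample_rate  # one ACC sample of tolerance
    if abs(semg.duration - acc.duration) > slack + 1e-9:
        raise ValueError(
            f"records span unequal durations: sEMG {semg.duration:.3f}s vs ACC {acc.duration:.3f}s"
        )
    duration = min(semg.duration, acc.duration)
    n_epochs = int(np.floor(duration / epoch_s + 1e-9))
    epochs = []
    for k in range(n_epochs):
        t0, t1 = k * epoch_s, (k + 1) * epoch_s
        epochs.append(
            Epoch(
                semg=semg.slice_time(t0, t1),
                acc=acc.slice_time(t0, t1),
                label=_label_at(label_track, semg.start_time + t0),
            )
        )
    return EpochSet(epochs=epochs, epoch_duration=epoch_s, provenance=provenance)


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Standardize to mean 0, population (1/N) standard deviation 1.

    Constant slices map to all zeros rather than dividing by zero.
    Accepts a single channel (1-D) or a channels x time grid.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot standardize empty input")
    if x.shape[axis] < 2:
        raise ValueError("need at least 2 samples per channel")
    mean = x.mean(axis=axis, keepdims=True)
    std = x.std(axis=axis, keepdims=True)  # population convention
    out = x - mean
    np.divide(out, std, out=out, where=std > 0)
    out[np.broadcast_to(std == 0, out.shape)] = 0.0
    return out
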