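import numpy as np
import pytest

from fatiguefuse.preprocess import bandpass_semg
from fatiguefuse.records import SignalRecord, default_channel_labels
from fatiguefuse.synthgen import SynthConfig, generate_acc, generate_semg


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def semg_epoch():
    """One band-passed 6-channel, 10-s sEMG epoch (Relax, seed 3)."""
    return bandpass_semg(generate_semg("Relax", seed=3))


@pytest.fixture(scope="session")
def acc_epoch():
    """One 18-channel, 10-s accelerometer epoch (Relax, seed 3)."""
    return generate_acc("Relax", seed=3)


def make_semg_record(samples_1ch: np.ndarray) -> SignalRecord:
    """6-channel sEMG record repeating one channel's samples."""
    return SignalRecord(
        modality="sEMG",
        sample_rate=2000.0,
        channels=default_channel_labels("sEMG"),
        samples=np.tile(np.asarray(samples_1ch, dtype=float), (6, 1)),
    )


def make_acc_record(samples_1ch: np.ndarray) -> SignalRecord:
    return SignalRecord(
        modality="ACC",
        sample_rate=20.0,
        channels=default_channel_labels("ACC"),
        samples=np.tile(np.asarray(samples_1ch, dtype=float), (18, 1)),
    )
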