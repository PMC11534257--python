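"""File I/O and run configuration.

Signals travel as plain CSV (header row = channel labels, one sample
per row, UTF-8, ``.`` decimal separator) with a JSON sidecar
(``<file>.meta.json``) carrying the sample rate, modality and start
time.  Feature maps travel as TSV with row and column headers at full
numeric precision.  Run configuration is a YAML document validated
strictly against the dataclass schemas: unknown keys are rejected with
their field paths.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureConfig
from .model import ModelConfig
from .records import FeatureMap, SignalRecord
from .synthgen import SynthConfig

log = logging.getLogger("fatiguefuse")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )


# ------------------------------------------------------------ signal CSV


def write_signal_csv(record: SignalRecord, path) -> None:
    """Write a record as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    frame = pd.DataFrame(record.samples.T, columns=record.channels)
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "modality": record.modality,
        "sample_rate": record.sample_rate,
        "start_time": record.start_time,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_signal_csv(
    path, sample_rate: float | None = None, modality: str | None = None
) -> SignalRecord:
    """Read a signal CSV; metadata from the sidecar unless overridden.

    Malformed rows (ragged length, non-numeric cells) are rejected with
    their 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    sample_rate = sample_rate if sample_rate is not None else meta.get("sample_rate")
    modality = modality if modality is not None else meta.get("modality")
    if sample_rate is None or modality is None:
        raise ValueError(f"{path}: sample rate/modality not in sidecar and not given")

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        n_cols = len(header)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} cells, expected {n_cols})"
                )
            try:
                rows.append([float(cell) for cell in row])
            except ValueError:
                raise ValueError(f"{path}: non-numeric cell at line {lineno}") from None
    if not rows:
        raise ValueError(f"{path}: no samples")
    samples = np.asarray(rows, dtype=float).T
    return SignalRecord(
        modality=modality,
        sample_rate=float(sample_rate),
        channels=header,
        samples=samples,
        start_time=float(meta.get("start_time", 0.0)),
    )


# ------------------------------------------------------------ feature TSV


def write_feature_tsv(fmap: FeatureMap, path) -> None:
    """Write a feature map as TSV with row/column headers, full precision."""
    frame = fmap.to_frame()
    frame.index.name = "channel"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_tsv(path, modality_tag: str = "fused") -> FeatureMap:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return FeatureMap.from_frame(frame, modality_tag=modality_tag)


# ------------------------------------------------------------ run config


@dataclass
class PreprocessConfig:
    band_low_hz: float = 20.0
    band_high_hz: float = 500.0
    notch_50hz: bool = False
    epoch_s: float = 10.0
    gain: float = 1.0  # stand-in for the hardware amplification stages


@dataclass
class RobustnessSettings:
    weights: tuple = (0.1, 0.2, 0.5)
    cv_folds: int = 10

    def __post_init__(self) -> None:
        self.weights = tuple(float(w) for w in self.weights)
        if any(w < 0 for w in self.weights):
            raise ValueError("robustness weights must be nonnegative")


@dataclass
class RunConfig:
    """Fully-resolved configuration of an end-to-end run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    robustness: RobustnessSettings = field(default_factory=RobustnessSettings)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # one global seed fans out to every stage
        self.synth.seed = int(self.seed) if self.synth.seed == 0 else self.synth.seed
        self.model.seed = int(self.seed) if self.model.seed == 0 else self.model.seed


_SECTION_TYPES = {
    "synth": SynthConfig,
    "preprocess": PreprocessConfig,
    "features": FeatureConfig,
    "model": ModelConfig,
    "robustness": RobustnessSettings,
}


def _build_section(cls, mapping: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid config at {where}: {err}") from err


def load_config(path_or_mapping) -> RunConfig:
    """Parse and validate a YAML run configuration.

    An empty document yields all defaults.  Unknown keys anywhere are
    rejected, naming the offending field path; section invariants
    (e.g. monotone class parameters, 1 <= senet_r <= filters) are
    enforced by the section dataclasses.
    """
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text()) or {}
        where = str(path_or_mapping)
    else:
        raw = dict(path_or_mapping or {})
        where = "<mapping>"
    if not isinstance(raw, dict):
        raise ValueError(f"{where}: config document must be a mapping")

    top_valid = set(_SECTION_TYPES) | {"seed", "log_level"}
    unknown = set(raw) - top_valid
    if unknown:
        raise ValueError(f"unknown config key(s) at {where}: {sorted(unknown)}")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        body = raw.get(name, {})
        if not isinstance(body, dict):
            raise ValueError(f"{where}:{name} must be a mapping")
        sections[name] = _build_section(cls, body, f"{where}:{name}")
    config = RunConfig(
        **sections,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    log.debug("resolved config: %s", config)
    return config


# ------------------------------------------------------------ model store


def save_model(result, out_dir) -> None:
    """Persist a fit result: architecture/config, weights, history."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = result.model
    desc = {
        "ablation": model.ablation,
        "classes": list(model.classes_),
        "config": dataclasses.asdict(model.config),
        "n_params": model.n_params,
        "param_breakdown": model.param_breakdown(),
    }
    (out_dir / "model.json").write_text(json.dumps(desc, indent=1))
    np.savez(
        out_dir / "weights.npz",
        scaler_mean=model._scaler_mean,
        scaler_std=model._scaler_std,
        **{f"w{i}": w for i, w in enumerate(model.network.get_weights())},
    )
    pd.DataFrame(
        {k: pd.Series(v) for k, v in result.history.items()}
    ).to_csv(out_dir / "history.tsv", sep="\t", index_label="epoch")


def load_model(model_dir):
    """Rebuild a trained classifier saved by :func:`save_model`."""
    from .model import FatigueCNN, ModelConfig

    model_dir = Path(model_dir)
    desc = json.loads((model_dir / "model.json").read_text())
    model = FatigueCNN(ModelConfig(**desc["config"]), ablation=desc["ablation"])
    data = np.load(model_dir / "weights.npz")
    model._scaler_mean = data["scaler_mean"]
    model._scaler_std = data["scaler_std"]
    model._input_shape = model._scaler_mean.shape
    weights = [data[f"w{i}"] for i in range(len(model.network.params()))]
    model.network.set_weights(weights)
    return model
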