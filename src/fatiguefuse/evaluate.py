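"""Classification metrics and the pseudo-artifact robustness protocol.

Metrics follow the one-vs-rest reading: for each class, TP/TN/FP/FN are
tallied against all other classes pooled, giving per-class accuracy
(TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN) and the F1
harmonic mean, plus support-weighted averages.  Weighted recall is
algebraically identical to overall multiclass accuracy.

The robustness protocol deliberately cross-contaminates the modalities:
standardized accelerometer motion is added into the sEMG channels (or
decimated sEMG into the ACC channels) at weights 0.1 / 0.2 / 0.5, and
the whole feature-extraction + cross-validation pipeline is re-run per
condition to measure how classification degrades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .preprocess import zscore
from .records import (
    ACC_RATE,
    CLASSES,
    N_ACC_CHANNELS,
    N_SEMG_CHANNELS,
    SEMG_RATE,
    SignalRecord,
)


@dataclass
class ConfusionMatrix:
    """Counts grid, rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be a square classes x classes grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> dict[str, int]:
        """TP/TN/FP/FN for one class against the rest pooled."""
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(truth, predicted, classes: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label vectors."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) == 0:
        raise ValueError("empty label vectors")
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    classes = tuple(classes) if classes is not None else CLASSES
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in idx or p not in idx:
            unknown = t if t not in idx else p
            raise ValueError(f"unknown label {unknown!r}")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus support-weighted averages."""

    classes: tuple[str, ...]
    per_class: dict  # class -> {"accuracy","precision","recall","f1","support"}
    weighted: dict  # {"accuracy","precision","recall","f1"}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.per_class).T
        frame.index.name = "class"
        return frame


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (0/0): returning 0 by convention")
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall and F1 per class and support-weighted."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for i, cls in enumerate(cm.classes):
        t = cm.one_vs_rest(cls)
        tp, tn, fp, fn = t["TP"], t["TN"], t["FP"], t["FN"]
        precision = _safe_div(tp, tp + fp, f"precision[{cls}]")
        recall = _safe_div(tp, tp + fn, f"recall[{cls}]")
        f1 = _safe_div(2 * precision * recall, precision + recall, f"F1[{cls}]") if (
            precision + recall
        ) > 0 else 0.0
        per_class[cls] = {
            "accuracy": (tp + tn) / cm.total,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": tp + fn,
        }
    supports = np.array([per_class[c]["support"] for c in cm.classes], dtype=float)
    weights = supports / supports.sum()
    weighted = {
        key: float(
            np.sum(weights * np.array([per_class[c][key] for c in cm.classes]))
        )
        for key in ("accuracy", "precision", "recall", "f1")
    }
    return MetricsReport(classes=cm.classes, per_class=per_class, weighted=weighted)


# ------------------------------------------------------------ contamination


@dataclass
class ArtifactMixSpec:
    """Direction and weight of cross-modal contamination."""

    direction: str  # {"semg_contaminated", "acc_contaminated"}
    weight: float
    resample: str = "poly"  # tag of the rate-conversion method

    def __post_init__(self) -> None:
        if self.direction not in ("semg_contaminated", "acc_contaminated"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


def _upsample_linear(x: np.ndarray, factor: int) -> np.ndarray:
    """Linear-interpolation upsampling of each channel by an integer factor."""
    n = x.shape[1]
    t_lo = np.arange(n)
    t_hi = np.arange(n * factor) / factor
    return np.stack([np.interp(t_hi, t_lo, ch) for ch in x])


def inject_artifact(
    semg: SignalRecord, acc: SignalRecord, spec: ArtifactMixSpec
) -> tuple[SignalRecord, SignalRecord]:
    """Add weighted cross-modal artifact to one modality.

    ``semg_contaminated``: every ACC channel is upsampled to 2000 Hz by
    linear interpolation, standardized, the 18 channels averaged in
    groups of 3, and each group added (times ``weight``) to its sEMG
    channel.  ``acc_contaminated``: each sEMG channel is anti-alias
    filtered and decimated to 20 Hz (polyphase), standardized, mapped
    cyclically onto the 18 ACC channels, and added with ``weight``.
    The other modality is returned unchanged; weight 0 is the identity.
    """
    if abs(semg.duration - acc.duration) > 1.0 / acc.sample_rate + 1e-9:
        raise ValueError("records must cover the same time span")
    if spec.weight == 0:
        return semg, acc

    if spec.direction == "semg_contaminated":
        factor = int(round(semg.sample_rate / acc.sample_rate))
        up = _upsample_linear(acc.samples, factor)[:, : semg.n_samples]
        if up.shape[1] < semg.n_samples:  # pad the interpolation tail
            pad = semg.n_samples - up.shape[1]
            up = np.pad(up, ((0, 0), (0, pad)), mode="edge")
        up = zscore(up)
        grouped = up.reshape(N_SEMG_CHANNELS, 3, -1).mean(axis=1)
        return semg.with_samples(semg.samples + spec.weight * grouped), acc

    factor = int(round(semg.sample_rate / acc.sample_rate))
    down = resample_poly(semg.samples, up=1, down=factor, axis=1)[:, : acc.n_samples]
    down = zscore(down)
    artifact = np.stack([down[j % N_SEMG_CHANNELS] for j in range(N_ACC_CHANNELS)])
    return semg, acc.with_samples(acc.samples + spec.weight * artifact)


# ------------------------------------------------------------ robustness


@dataclass
class RobustnessConfig:
    """Problem sizes of the 7-condition pseudo-artifact suite."""

    weights: tuple[float, ...] = (0.1, 0.2, 0.5)
    cv_folds: int = 10
    ablation: str = "full"
    seed: int = 0
    model_config: object = None  # ModelConfig; resolved lazily
    feature_config: object = None  # FeatureConfig


def condition_names(weights=(0.1, 0.2, 0.5)) -> list[str]:
    """The 7 evaluation conditions: clean plus both contamination directions."""
    names = ["sEMG-ACC"]
    names += [f"sEMG-{w:g}*AR" for w in weights]
    names += [f"ACC-{w:g}*AR" for w in weights]
    return names


def robustness_suite(dataset, config: RobustnessConfig | None = None) -> pd.DataFrame:
    """Re-run features + cross-validation under each contamination condition.

    ``dataset`` is a list of raw (sEMG, ACC, label) triples.  Returns a
    tidy frame with columns condition, class, accuracy, precision,
    recall, f1, support — 7 conditions x 3 classes.
    """
    from .features import FeatureConfig, fused_maps_from_dataset
    from .model import ModelConfig, cross_validate

    config = config or RobustnessConfig()
    model_config = config.model_config or ModelConfig()
    feature_config = config.feature_config or FeatureConfig()

    conditions: list[tuple[str, ArtifactMixSpec | None]] = [("sEMG-ACC", None)]
    for w in config.weights:
        conditions.append((f"sEMG-{w:g}*AR", ArtifactMixSpec("semg_contaminated", w)))
    for w in config.weights:
        conditions.append((f"ACC-{w:g}*AR", ArtifactMixSpec("acc_contaminated", w)))

    rows = []
    for name, spec in conditions:
        if spec is None:
            triples = dataset
        else:
            triples = [
                (*inject_artifact(semg, acc, spec), label)
                for semg, acc, label in dataset
            ]
        X, y = fused_maps_from_dataset(triples, feature_config)
        cv = cross_validate(
            X, y, model_config, k=config.cv_folds,
            ablation=config.ablation, seed=config.seed,
        )
        # pool per-fold reports by averaging per-class metrics over folds
        for cls in cv.classes:
            entry = {"condition": name, "class": cls}
            for key in ("accuracy", "precision", "recall", "f1"):
                entry[key] = float(
                    np.mean([r.per_class[cls][key] for r in cv.fold_reports])
                )
            entry["support"] = int(
                np.sum([r.per_class[cls]["support"] for r in cv.fold_reports])
            )
            rows.append(entry)
    return pd.DataFrame(rows)
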