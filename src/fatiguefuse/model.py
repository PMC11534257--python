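"""The fatigue classifier: an 8-layer 1-D CNN with hierarchical attention.

Architecture (``full`` variant), operating on fused 6x60 feature maps
whose 6 rows are the input channels:

    LFAM -> [conv(k=2, f=100) -> ReLU -> SENet] x 7
         -> conv -> ReLU -> simAM -> flatten -> dense(16, ReLU)
         -> dense(3, softmax)

Channel attention (SENet) gates the shallow layers where feature-space
structure is diffuse; the parameter-free neuron attention (simAM) sits
after the final convolution where activations carry the most semantic
contrast.  No pooling layers are used, preserving the temporal axis at
length 60 throughout.  Ablation variants drop mechanisms individually.

Usage follows the model/results convention::

    model = FatigueCNN(ModelConfig(max_epochs=20), ablation="full")
    res = model.fit(X, y)          # X: (n, 6, 60), y: labels
    probs = res.predict_proba(X)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .attention import lfam_apply
from .records import CLASSES

ABLATIONS = {
    "full": dict(lfam=True, senet=True, simam=True),
    "lfam_only": dict(lfam=True, senet=False, simam=False),
    "senet_only": dict(lfam=False, senet=True, simam=False),
    "simam_only": dict(lfam=False, senet=False, simam=True),
    "none": dict(lfam=False, senet=False, simam=False),
}


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults mirror the reference architecture: 8 convolutional layers
    of 100 filters, kernel 2, stride 1; SENet reduction 16; simAM
    lambda 1e-4; a 16-unit dense head.  The optimizer is Adam with
    early stopping on validation loss.
    """

    n_conv: int = 8
    filters: int = 100
    kernel: int = 2
    stride: int = 1
    senet_r: int = 16
    simam_lambda: float = 1e-4
    dense_hidden: int = 16
    n_classes: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 8
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.kernel < 1 or self.stride != 1:
            raise ValueError("kernel must be >= 1 and stride fixed at 1")
        if not (1 <= self.senet_r <= self.filters):
            raise ValueError("senet_r must satisfy 1 <= r <= filters")
        if self.simam_lambda <= 0:
            raise ValueError("simam_lambda must be positive")
        if not (0.0 <= self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in [0, 0.5)")


def _encode_labels(y, classes: tuple[str, ...]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([idx[label] for label in y])
    except KeyError as err:
        raise ValueError(f"unknown class label {err.args[0]!r}") from err


class FatigueCNN:
    """Untrained fatigue classifier; :meth:`fit` returns a :class:`FitResult`."""

    def __init__(self, config: ModelConfig | None = None, ablation: str = "full"):
        if ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {ablation!r}; choose from {sorted(ABLATIONS)}")
        self.config = config or ModelConfig()
        self.ablation = ablation
        self.uses = ABLATIONS[ablation]
        self.classes_: tuple[str, ...] = CLASSES[: self.config.n_classes]
        self._rng = np.random.default_rng(self.config.seed)
        self.network = self._build_network()
        self._scaler_mean: np.ndarray | None = None
        self._scaler_std: np.ndarray | None = None
        self._input_shape: tuple[int, int] | None = None

    # ------------------------------------------------------------ building

    def _build_network(self) -> nn.Sequential:
        # the 6 rows of the fused 6x60 map are the input channels of conv 1
        return self._materialize(in_channels=6)

    def _materialize(self, in_channels: int) -> nn.Sequential:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        layers: list[nn.Layer] = []
        c = in_channels
        for i in range(cfg.n_conv):
            layers.append(nn.Conv1D(c, cfg.filters, cfg.kernel, rng))
            layers.append(nn.ReLU())
            c = cfg.filters
            last = i == cfg.n_conv - 1
            if not last and self.uses["senet"]:
                layers.append(nn.SENetBlock(c, cfg.senet_r, rng))
            if last and self.uses["simam"]:
                layers.append(nn.SimAM(cfg.simam_lambda))
        layers.append(nn.Flatten())
        self._flat_dim_factor = c
        layers.append(nn.Dense(c * 60, cfg.dense_hidden, rng, relu_init=True))
        layers.append(nn.ReLU())
        layers.append(nn.Dense(cfg.dense_hidden, cfg.n_classes, rng, relu_init=False))
        return nn.Sequential(layers)

    # ------------------------------------------------------------ accounting

    @property
    def n_params(self) -> int:
        """Total trainable parameters."""
        return self.network.n_params

    def param_breakdown(self) -> dict[str, int]:
        """Trainable parameters by layer family (attention audit)."""
        out = {"conv": 0, "senet": 0, "simam": 0, "dense": 0, "lfam": 0}
        for layer in self.network.layers:
            if isinstance(layer, nn.Conv1D):
                out["conv"] += layer.n_params
            elif isinstance(layer, nn.SENetBlock):
                out["senet"] += layer.n_params
            elif isinstance(layer, nn.SimAM):
                out["simam"] += layer.n_params
            elif isinstance(layer, nn.Dense):
                out["dense"] += layer.n_params
        return out

    # ------------------------------------------------------------ pipeline

    def _transform(self, X: np.ndarray, fit_scaler: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_examples, rows, length)")
        if self._input_shape is not None and X.shape[1:] != self._input_shape:
            raise ValueError(f"expected inputs of shape {self._input_shape}, got {X.shape[1:]}")
        if fit_scaler:
            self._input_shape = X.shape[1:]
            self._scaler_mean = X.mean(axis=0)
            std = X.std(axis=0)
            std[std == 0] = 1.0
            self._scaler_std = std
        if self._scaler_mean is None:
            raise RuntimeError("model must be fitted before prediction")
        Z = (X - self._scaler_mean) / self._scaler_std
        if self.uses["lfam"]:
            Z = np.stack([lfam_apply(m) for m in Z])
        return Z.astype(nn.DTYPE)

    # ------------------------------------------------------------ training

    def fit(self, X, y, validation_data=None) -> "FitResult":
        """Train with Adam on categorical cross-entropy.

        ``y`` may be label strings or integer codes.  A stratified
        ``val_fraction`` of the training data is held out for early
        stopping when no explicit ``validation_data`` is given; the
        weights of the best validation epoch are restored.
        """
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y_idx = _encode_labels(y, self.classes_) if not np.issubdtype(
            np.asarray(y).dtype, np.integer
        ) else np.asarray(y, dtype=int)
        counts = np.bincount(y_idx, minlength=cfg.n_classes)
        if np.any(counts < 2):
            missing = [self.classes_[i] for i in np.where(counts < 2)[0]]
            raise ValueError(f"need at least 2 training examples per class; short: {missing}")

        Z = self._transform(X, fit_scaler=True)
        if validation_data is not None:
            Xv, yv = validation_data
            Zv = self._transform(np.asarray(Xv, dtype=float))
            yv_idx = _encode_labels(yv, self.classes_)
            Ztr, ytr = Z, y_idx
        elif cfg.val_fraction > 0 and cfg.patience > 0:
            Ztr, Zv, ytr, yv_idx = train_test_split(
                Z, y_idx, test_size=cfg.val_fraction, stratify=y_idx,
                random_state=cfg.seed % (2**32),
            )
        else:
            Ztr, ytr = Z, y_idx
            Zv, yv_idx = None, None

        onehot_tr = np.eye(cfg.n_classes, dtype=nn.DTYPE)[ytr]
        opt = nn.Adam(self.network.params(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
        best_val = np.inf
        best_weights = self.network.get_weights()
        since_best = 0
        n = Ztr.shape[0]

        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                xb, tb = Ztr[sel], onehot_tr[sel]
                self.network.zero_grad()
                logits = self.network.forward(xb)
                probs = nn.softmax(logits)
                ep_loss += nn.cross_entropy(probs, tb) * len(sel)
                ep_correct += int(np.sum(np.argmax(probs, axis=1) == ytr[sel]))
                dlogits = (probs - tb) / len(sel)
                self.network.backward(dlogits.astype(nn.DTYPE))
                opt.step()
            history["loss"].append(ep_loss / n)
            history["accuracy"].append(ep_correct / n)

            if Zv is not None:
                probs_v = nn.softmax(self.network.forward(Zv))
                val_loss = nn.cross_entropy(probs_v, np.eye(cfg.n_classes)[yv_idx])
                history["val_loss"].append(val_loss)
                history["val_accuracy"].append(
                    float(np.mean(np.argmax(probs_v, axis=1) == yv_idx))
                )
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = self.network.get_weights()
                    since_best = 0
                else:
                    since_best += 1
                    if cfg.patience > 0 and since_best >= cfg.patience:
                        break

        if Zv is not None and cfg.patience > 0:
            self.network.set_weights(best_weights)
        return FitResult(model=self, history=history, n_train=int(n))

    # ------------------------------------------------------------ inference

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, one row per example, rows summing to 1."""
        Z = self._transform(np.asarray(X, dtype=float))
        return nn.softmax(self.network.forward(Z)).astype(float)

    def predict(self, X) -> np.ndarray:
        """Predicted class labels."""
        idx = np.argmax(self.predict_proba(X), axis=1)
        return np.array([self.classes_[i] for i in idx])


@dataclass
class FitResult:
    """Trained-model results: learned weights live on ``model``;
    ``history`` records per-epoch train/validation loss and accuracy."""

    model: FatigueCNN
    history: dict
    n_train: int

    @property
    def n_epochs(self) -> int:
        return len(self.history["loss"])

    def predict_proba(self, X) -> np.ndarray:
        return self.model.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.model.predict(X)

    def summary(self) -> str:
        m = self.model
        lines = [
            "FatigueCNN fit results",
            "=" * 54,
            f"ablation:            {m.ablation}",
            f"trainable params:    {m.n_params}",
            f"param breakdown:     {m.param_breakdown()}",
            f"training examples:   {self.n_train}",
            f"epochs run:          {self.n_epochs}",
            f"final train loss:    {self.history['loss'][-1]:.4f}",
            f"final train acc:     {self.history['accuracy'][-1]:.4f}",
        ]
        if self.history["val_loss"]:
            lines.append(f"best val loss:       {min(self.history['val_loss']):.4f}")
            lines.append(f"final val acc:       {self.history['val_accuracy'][-1]:.4f}")
        return "\n".join(lines)


# ------------------------------------------------------------ functional API


def build_model(config: ModelConfig | None = None, ablation: str = "full") -> FatigueCNN:
    """Construct an untrained classifier for the given ablation variant."""
    return FatigueCNN(config, ablation)


def train_model(model: FatigueCNN, X, y, validation_data=None) -> FitResult:
    return model.fit(X, y, validation_data=validation_data)


def predict(model, X) -> np.ndarray:
    """Per-example class probabilities from a model or fit result."""
    return model.predict_proba(X)


@dataclass
class CVResult:
    """Per-fold metric reports and their mean +/- sd aggregate."""

    fold_reports: list
    fold_accuracies: list[float]
    fold_assignments: np.ndarray  # validation-fold index of each example
    classes: tuple[str, ...]
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    @property
    def mean_weighted_f1(self) -> float:
        return float(np.mean([r.weighted["f1"] for r in self.fold_reports]))

    def summary(self) -> str:
        k = len(self.fold_accuracies)
        return (
            f"{k}-fold cross-validation (seed {self.seed})\n"
            f"accuracy:    {self.mean_accuracy:.4f} +/- {self.sd_accuracy:.4f}\n"
            f"weighted F1: {self.mean_weighted_f1:.4f}"
        )


def cross_validate(
    X,
    y,
    config: ModelConfig | None = None,
    k: int = 10,
    ablation: str = "full",
    seed: int | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the classifier.

    Folds come from a seeded stratified shuffle; every example is
    validated exactly once.  Each fold trains a fresh model whose
    weight initialization derives from the fold index.
    """
    from .evaluate import confusion, metrics_from_confusion  # local: avoids cycle

    config = config or ModelConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    seed = config.seed if seed is None else seed
    classes = CLASSES[: config.n_classes]
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("each class needs at least k examples for stratified folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    assignments = np.full(len(y), -1, dtype=int)
    reports, accuracies = [], []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        assignments[va] = fold
        fold_cfg = ModelConfig(**{**asdict(config), "seed": seed + fold})
        model = FatigueCNN(fold_cfg, ablation)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[va])
        cm = confusion(y[va], pred, classes=classes)
        report = metrics_from_confusion(cm)
        reports.append(report)
        accuracies.append(float(np.mean(pred == y[va])))
    return CVResult(
        fold_reports=reports,
        fold_accuracies=accuracies,
        fold_assignments=assignments,
        classes=classes,
        seed=seed,
    )
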