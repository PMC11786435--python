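"""Training loop and confusion-matrix metrics.

The network is trained with mini-batch stochastic gradient descent
(learning rate 0.001, momentum 0.9) on the softmax cross-entropy, for a
fixed number of epochs — no schedules, early stopping or validation-based
selection.  Evaluation tallies a binary confusion matrix with *malignant as
the positive class* and derives

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    F1          = 2·P·R / (P + R)    (harmonic mean)

Zero-denominator cases are reported as 0 with a logged warning.  Optional
augmentation applies random rotation (±30°) and isotropic scaling
(0.8–1.2×) per training image.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rescale, rotate

from . import engine
from .arch import GraphModel, NetworkGraph
from .data import DatasetManifest, load_images
from .exceptions import ConfigurationError, DivergenceError, EmptyDatasetError

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "ConfusionMatrix",
    "MetricsReport",
    "train",
    "fit",
    "evaluate",
    "evaluate_arrays",
    "precision",
    "recall",
    "specificity",
    "accuracy",
    "f1_score",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and loop settings.

    Defaults follow the published configuration: SGD with learning rate
    0.001 for 100 epochs; batch size 32 and momentum 0.9 are this package's
    defaults where the publication is silent.
    """

    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0
    augment_rotation: bool = False
    augment_scaling: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch loss and accuracy on train and (optional) held-out data."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    @property
    def final(self) -> dict:
        return self.epochs[-1]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = malignant."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def precision(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")


def recall(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")


def specificity(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tn, cm.tn + cm.fp, "specificity")


def accuracy(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp + cm.tn, cm.total, "accuracy")


def f1_score(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both inputs are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass(frozen=True)
class MetricsReport:
    """The five scalar rates, as proportions in [0, 1]."""

    precision: float
    recall: float
    specificity: float
    f1: float
    accuracy: float

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricsReport":
        p, r = precision(cm), recall(cm)
        return cls(p, r, specificity(cm), f1_score(p, r), accuracy(cm))

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.__dict__.items()}


def _augment_batch(xb: np.ndarray, cfg: TrainConfig,
                   rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(xb)
    side = xb.shape[1]
    for i, img in enumerate(xb):
        if cfg.augment_rotation:
            img = rotate(img, rng.uniform(-30.0, 30.0), mode="edge",
                         preserve_range=True)
        if cfg.augment_scaling:
            s = rng.uniform(0.8, 1.2)
            scaled = rescale(img, s, channel_axis=-1, mode="edge",
                             preserve_range=True, anti_aliasing=False)
            if s >= 1.0:  # center crop
                off = (scaled.shape[0] - side) // 2
                img = scaled[off:off + side, off:off + side]
            else:  # pad back to size with edge values
                pad = side - scaled.shape[0]
                lo, hi = pad // 2, pad - pad // 2
                img = np.pad(scaled, ((lo, hi), (lo, hi), (0, 0)), mode="edge")
        out[i] = img.astype(xb.dtype)
    return out


def fit(model: GraphModel, X: np.ndarray, y: np.ndarray, config: TrainConfig,
        X_val: np.ndarray | None = None, y_val: np.ndarray | None = None
        ) -> TrainHistory:
    """Train ``model`` in place on an array batch; returns the history.

    Fully deterministic for a fixed config seed on one device: shuffling,
    dropout and augmentation all draw from one seeded generator.
    """
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    opt = engine.SGD(model.parameters(), config.learning_rate, config.momentum)
    history = TrainHistory()
    n = len(X)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X[idx], y[idx]
            if config.augment_rotation or config.augment_scaling:
                xb = _augment_batch(xb, config, rng)
            acts = model.forward(xb, training=True, rng=rng)
            loss, dlogits = engine.softmax_cross_entropy(acts["Fc3"], yb)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}; try a lower "
                    f"learning rate")
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss * len(idx))
            hits += int((acts["Fc3"].argmax(axis=1) == yb).sum())
        row = {"epoch": epoch, "train_loss": sum(losses) / n,
               "train_accuracy": hits / n}
        if X_val is not None:
            cm = evaluate_arrays(model, X_val, y_val)
            row["val_accuracy"] = accuracy(cm)
        history.append(**row)
        logger.info("epoch %d/%d loss=%.4f acc=%.3f", epoch, config.epochs,
                    row["train_loss"], row["train_accuracy"])
    return history


def train(graph: NetworkGraph, train_set: DatasetManifest, config: TrainConfig,
          eval_set: DatasetManifest | None = None
          ) -> tuple[GraphModel, TrainHistory]:
    """Build a model for ``graph`` and train it on a manifest's images.

    Uses the manifest's ``train`` split if assigned, otherwise all records.
    """
    split = "train" if (train_set.frame["split"] == "train").any() else None
    X, y = load_images(train_set, graph.input_size, split)
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(train_set.frame).values.tobytes()
    ).hexdigest()[:12]
    logger.info("training: seed=%d config=%s dataset_fingerprint=%s n=%d",
                config.seed, config, digest, len(X))
    Xv = yv = None
    if eval_set is not None:
        vsplit = "test" if (eval_set.frame["split"] == "test").any() else None
        Xv, yv = load_images(eval_set, graph.input_size, vsplit)
    model = GraphModel(graph, seed=config.seed)
    history = fit(model, X, y, config, Xv, yv)
    return model, history


def evaluate_arrays(model: GraphModel, X: np.ndarray, y: np.ndarray,
                    batch_size: int = 64) -> ConfusionMatrix:
    """Confusion matrix of argmax-probability predictions on arrays."""
    if len(X) == 0:
        raise EmptyDatasetError("cannot evaluate on an empty set")
    preds = np.concatenate([
        model.predict(X[i:i + batch_size])
        for i in range(0, len(X), batch_size)])
    y = np.asarray(y)
    return ConfusionMatrix(
        tp=int(np.sum((preds == 1) & (y == 1))),
        fp=int(np.sum((preds == 1) & (y == 0))),
        fn=int(np.sum((preds == 0) & (y == 1))),
        tn=int(np.sum((preds == 0) & (y == 0))),
    )


def evaluate(model: GraphModel, test_set: DatasetManifest,
             split: str | None = None) -> ConfusionMatrix:
    """Confusion matrix on a manifest's images (``test`` split if assigned)."""
    if split is None and (test_set.frame["split"] == "test").any():
        split = "test"
    X, y = load_images(test_set, model.graph.input_size, split)
    return evaluate_arrays(model, X, y)
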