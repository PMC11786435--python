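"""Multi-dataset feature fusion for bias reduction.

Two complementary modes are provided:

* **feature-level fusion** — deep features are extracted at the global
  average pooling layer (the 1×1×1024 representation in the full network),
  per-image vectors from several source models/datasets are concatenated,
  and a softmax (multinomial logistic) head is trained on the fused vectors
  after per-dimension standardization;
* **dataset pooling** — several manifests are merged into one training pool
  (retaining source tags) and the network is trained end-to-end on the
  union.

Both widen the data distribution a classifier sees, which dilutes
dataset-specific artifacts (vignette, hair) that would otherwise act as
shortcut features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .arch import GraphModel
from .data import DatasetManifest
from .exceptions import ConfigurationError, ShapeError
from .training import ConfusionMatrix, MetricsReport

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "FusedFeatureSet",
    "extract_features",
    "fuse_concat",
    "merge_datasets",
    "save_fused_features",
    "load_fused_features",
    "train_fused_classifier",
]


@dataclass
class FeatureSet:
    """Per-image feature vectors from one (model, dataset) source."""

    values: np.ndarray  # (N, C)
    source_model: str = ""
    source_dataset: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ShapeError("feature values must be (n_images, n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FusedFeatureSet:
    """Concatenated features with provenance spans.

    ``provenance`` lists ``(source_model, source_dataset, offset, length)``
    tuples that tile the fused vector exactly.
    """

    values: np.ndarray
    provenance: list[tuple[str, str, int, int]]

    def component(self, index: int) -> np.ndarray:
        _, _, off, length = self.provenance[index]
        return self.values[:, off:off + length]


def extract_features(model: GraphModel, images: np.ndarray,
                     layer: str = "GlobalAvgPool", *,
                     source_model: str = "", source_dataset: str = "",
                     batch_size: int = 64) -> FeatureSet:
    """Deterministic deep features for a batch of images.

    ``layer`` must yield a flat vector (the global average pool) or a
    spatial feature map, which is then averaged over space to one vector
    per image.
    """
    if layer not in model.graph.names():
        raise ConfigurationError(
            f"unknown layer {layer!r}; graph layers: {model.graph.names()}")
    chunks = []
    for i in range(0, len(images), batch_size):
        acts = model.forward(images[i:i + batch_size], training=False)
        feat = acts[layer]
        if feat.ndim == 4:
            feat = feat.mean(axis=(1, 2))
        elif feat.ndim != 2:
            raise ShapeError(f"layer {layer!r} yields shape {feat.shape}")
        chunks.append(feat)
    return FeatureSet(np.concatenate(chunks), source_model, source_dataset)


def fuse_concat(sets: list[FeatureSet]) -> FusedFeatureSet:
    """Concatenate aligned feature sets along the feature axis."""
    if not sets:
        raise ConfigurationError("need at least one feature set")
    n = len(sets[0])
    for i, s in enumerate(sets):
        if len(s) != n:
            raise ConfigurationError(
                f"feature set {i} ({s.source_model}/{s.source_dataset}) has "
                f"{len(s)} images, expected {n}")
    provenance = []
    offset = 0
    for s in sets:
        length = s.values.shape[1]
        provenance.append((s.source_model, s.source_dataset, offset, length))
        offset += length
    return FusedFeatureSet(
        np.concatenate([s.values for s in sets], axis=1), provenance)


def merge_datasets(manifests: list[DatasetManifest]) -> DatasetManifest:
    """Union of several manifests, retaining source tags.

    Duplicate paths across sources are kept (with their distinct tags) and
    logged; all manifests must share the binary label space, which the
    manifest type itself enforces.
    """
    if not manifests:
        raise ConfigurationError("need at least one manifest")
    frame = pd.concat([m.frame for m in manifests], ignore_index=True)
    dup = frame["path"].duplicated().sum()
    if dup:
        logger.warning("%d duplicate paths across merged sources", dup)
    for source, group in frame.groupby("source"):
        logger.info("merged source %r: %d records", source, len(group))
    return DatasetManifest(frame)


def save_fused_features(fused: FusedFeatureSet, path) -> None:
    """Store a fused feature matrix as .npy with a JSON provenance sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    np.save(path, fused.values)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "provenance": [list(p) for p in fused.provenance]}, indent=2))


def load_fused_features(path) -> FusedFeatureSet:
    """Inverse of :func:`save_fused_features`."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    values = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    provenance = [tuple(p) for p in meta["provenance"]]
    return FusedFeatureSet(values, provenance)


def train_fused_classifier(fused: FusedFeatureSet, labels: np.ndarray,
                           train_idx: np.ndarray | None = None,
                           test_idx: np.ndarray | None = None,
                           seed: int = 0
                           ) -> tuple[Pipeline, MetricsReport]:
    """Fit a standardized softmax head on fused features.

    When no explicit index split is given, a deterministic stratified 80/20
    split is drawn from ``seed``.  Returns the fitted scikit-learn pipeline
    (standardizer + multinomial logistic regression) and the metrics of the
    held-out predictions.
    """
    labels = np.asarray(labels)
    if len(labels) != len(fused.values):
        raise ConfigurationError("labels and fused features are misaligned")
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("labels must contain both classes")
    if train_idx is None or test_idx is None:
        rng = np.random.default_rng(seed)
        train_parts, test_parts = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            order = rng.permutation(len(idx))
            n_train = int(np.floor(0.8 * len(idx) + 0.5))
            train_parts.append(idx[order[:n_train]])
            test_parts.append(idx[order[n_train:]])
        train_idx = np.concatenate(train_parts)
        test_idx = np.concatenate(test_parts)
    clf = Pipeline([
        ("scale", StandardScaler()),
        ("head", LogisticRegression(max_iter=2000, random_state=seed)),
    ])
    clf.fit(fused.values[train_idx], labels[train_idx])
    preds = clf.predict(fused.values[test_idx])
    y = labels[test_idx]
    cm = ConfusionMatrix(
        tp=int(np.sum((preds == 1) & (y == 1))),
        fp=int(np.sum((preds == 1) & (y == 0))),
        fn=int(np.sum((preds == 0) & (y == 1))),
        tn=int(np.sum((preds == 0) & (y == 0))),
    )
    return clf, MetricsReport.from_confusion(cm)
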