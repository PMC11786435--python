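"""Dataset ingestion: folder-per-class loading, HAM10000 relabeling,
resizing, and deterministic stratified train/test splits.

A dataset is described by a :class:`DatasetManifest` — a thin wrapper around
a pandas DataFrame with one row per image (``path``, ``label``, ``source``,
``split``).  Labels are always the binary pair ``"benign"`` / ``"malignant"``
(encoded 0/1 for training, malignant positive).  The HAM10000 seven-way
diagnosis codes are collapsed onto this pair with the fixed rule
nv/bkl/df → benign and mel/bcc/ak/akiec → malignant; any other code raises
rather than guessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .exceptions import (
    ConfigurationError,
    EmptyDatasetError,
    StratificationError,
    UnmappedCodeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "LABELS",
    "DatasetManifest",
    "load_folder_dataset",
    "ham10000_relabel",
    "load_ham10000_metadata",
    "build_ham10000_manifest",
    "resize_image",
    "split_dataset",
    "load_images",
]

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)

#: HAM10000 dx code → binary label.  "vasc" is deliberately absent.
HAM10000_BENIGN_CODES = frozenset({"nv", "bkl", "df"})
HAM10000_MALIGNANT_CODES = frozenset({"mel", "bcc", "ak", "akiec"})

_IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}
_MANIFEST_COLUMNS = ["path", "label", "source", "split"]


@dataclass
class DatasetManifest:
    """Image records with binary labels, source tags and split assignment."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"manifest missing columns {missing}")
        bad = set(self.frame["label"]) - set(LABELS)
        if bad:
            raise ConfigurationError(f"non-binary labels in manifest: {sorted(bad)}")
        # duplicate paths are tolerated across sources (fusion keeps them
        # with distinct tags) but not within one source
        if self.frame.duplicated(subset=["path", "source"]).any():
            raise ConfigurationError("duplicate paths within a single source")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(cls, records: list[dict]) -> "DatasetManifest":
        frame = pd.DataFrame(records)
        if "split" not in frame.columns:
            frame["split"] = "unassigned"
        return cls(frame[_MANIFEST_COLUMNS].reset_index(drop=True))

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            self.frame[self.frame["split"] == split].reset_index(drop=True))

    def class_counts(self) -> dict[str, int]:
        return self.frame["label"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path)[_MANIFEST_COLUMNS])


def load_folder_dataset(root, source_tag: str) -> DatasetManifest:
    """Scan a folder-per-class tree (``Benign/``, ``Malignant/`` — matched
    case-insensitively) for JPEG/PNG files.

    Unreadable images are logged and skipped; an empty tree raises
    :class:`EmptyDatasetError`.
    """
    root = Path(root)
    records = []
    skipped = 0
    for sub in sorted(root.iterdir()) if root.is_dir() else []:
        if not sub.is_dir() or sub.name.lower() not in LABELS:
            continue
        label = sub.name.lower()
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() not in _IMAGE_EXTENSIONS:
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
            except Exception:
                skipped += 1
                logger.warning("skipping unreadable image %s", f)
                continue
            records.append({"path": str(f), "label": label,
                            "source": source_tag, "split": "unassigned"})
    if skipped:
        logger.warning("skipped %d unreadable images under %s", skipped, root)
    if not records:
        raise EmptyDatasetError(f"no labeled images found under {root}")
    return DatasetManifest.from_records(records)


def ham10000_relabel(dx_code: str) -> str:
    """Collapse a HAM10000 ``dx`` diagnosis code to benign/malignant.

    nv, bkl, df → benign; mel, bcc, ak, akiec → malignant.  Any other code
    (HAM10000 also contains "vasc", which has no assignment in this rule)
    raises :class:`UnmappedCodeError`.
    """
    code = str(dx_code).strip().lower()
    if code in HAM10000_BENIGN_CODES:
        return BENIGN
    if code in HAM10000_MALIGNANT_CODES:
        return MALIGNANT
    raise UnmappedCodeError(
        f"dx code {dx_code!r} has no benign/malignant assignment "
        f"(known: {sorted(HAM10000_BENIGN_CODES | HAM10000_MALIGNANT_CODES)})")


def load_ham10000_metadata(path) -> pd.DataFrame:
    """Read the HAM10000 metadata table (CSV or XLSX) with columns
    ``image_id`` and ``dx``."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    missing = {"image_id", "dx"} - set(frame.columns)
    if missing:
        raise ConfigurationError(f"metadata missing columns {sorted(missing)}")
    return frame


def build_ham10000_manifest(image_root, metadata, source_tag: str = "ham10000"
                            ) -> DatasetManifest:
    """Label a flat folder of HAM10000 images via the metadata table.

    ``metadata`` may be a DataFrame or a CSV/XLSX path.  Images whose stem
    has no metadata row are skipped with a warning; codes outside the
    seven-way rule raise.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = load_ham10000_metadata(metadata)
    dx_by_id = dict(zip(metadata["image_id"].astype(str), metadata["dx"]))
    root = Path(image_root)
    records = []
    for f in sorted(root.rglob("*")):
        if f.suffix.lower() not in _IMAGE_EXTENSIONS:
            continue
        dx = dx_by_id.get(f.stem)
        if dx is None:
            logger.warning("no metadata row for image %s; skipping", f.name)
            continue
        records.append({"path": str(f), "label": ham10000_relabel(dx),
                        "source": source_tag, "split": "unassigned"})
    if not records:
        raise EmptyDatasetError(f"no metadata-matched images under {root}")
    return DatasetManifest.from_records(records)


def resize_image(image: np.ndarray, side: int = 224) -> np.ndarray:
    """Resize to ``side``×``side``×3 with bilinear interpolation and scale
    pixel values to [0, 1].

    Non-RGB inputs (grayscale, RGBA) are converted with a logged warning.
    Already-correctly-sized inputs pass through unchanged apart from the
    [0, 1] scaling, so the operation is idempotent at the target size.
    """
    image = np.asarray(image)
    if image.ndim < 2 or image.size == 0:
        raise ConfigurationError("image must have at least one pixel")
    if image.ndim == 2:
        logger.warning("grayscale input converted to RGB")
        image = np.stack([image] * 3, axis=-1)
    elif image.shape[-1] == 4:
        logger.warning("RGBA input: alpha channel dropped")
        image = image[..., :3]
    elif image.shape[-1] != 3:
        raise ConfigurationError(f"cannot interpret image shape {image.shape} as RGB")
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float32) / 255.0
    else:
        image = image.astype(np.float32)
    if image.shape[:2] == (side, side):
        return image
    out = _sk_resize(image, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def split_dataset(manifest: DatasetManifest, train_fraction: float = 0.8,
                  seed: int = 0) -> DatasetManifest:
    """Deterministic stratified train/test split.

    Per class, ``round-half-up(train_fraction · n)`` records go to train and
    the rest to test; the same seed always yields the same assignment.
    Classes with fewer than 2 records cannot be stratified and raise.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(
            f"train_fraction must be in (0,1), got {train_fraction}")
    frame = manifest.frame.reset_index(drop=True).copy()
    rng = np.random.default_rng(seed)
    split = pd.Series("test", index=frame.index)
    for label in sorted(frame["label"].unique()):
        idx = frame.index[frame["label"] == label].to_numpy()
        n = len(idx)
        if n < 2:
            raise StratificationError(
                f"class {label!r} has only {n} record(s); cannot stratify")
        n_train = int(np.floor(train_fraction * n + 0.5))  # round half up
        order = rng.permutation(n)
        split.loc[idx[order[:n_train]]] = "train"
    frame["split"] = split
    return DatasetManifest(frame)


def load_images(manifest: DatasetManifest, side: int, split: str | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Load the manifest's images into a channels-last float batch.

    Returns ``(X, y)`` with ``X`` of shape (N, side, side, 3) in [0, 1] and
    ``y`` the 0/1 label vector (malignant = 1).
    """
    frame = manifest.frame
    if split is not None:
        frame = frame[frame["split"] == split]
    if frame.empty:
        raise EmptyDatasetError(
            f"no records{f' with split={split!r}' if split else ''} in manifest")
    images, labels = [], []
    for _, row in frame.iterrows():
        with Image.open(row["path"]) as im:
            arr = np.asarray(im.convert("RGB"))
        images.append(resize_image(arr, side))
        labels.append(LABELS.index(row["label"]))
    return np.stack(images), np.asarray(labels, dtype=np.int64)
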