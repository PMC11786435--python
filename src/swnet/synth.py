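"""Synthetic dermoscopy-like image generator with controllable confounds.

Real dermoscopy datasets couple the diagnostic signal (lesion morphology)
with acquisition artifacts: a dark circular vignette from the dermatoscope
optics, hair strokes crossing the field, and varying skin tones.  A
classifier can shortcut on these artifacts instead of the lesion.  This
module renders labeled lesion images where *the class signal lives purely in
morphology* — malignant lesions get irregular, sinusoidally perturbed
borders and several color patches (variegation), benign lesions stay round
and uniform — while the artifacts are applied with per-class probabilities
chosen by the caller.  That makes the label↔artifact correlation a dial
(measured by the phi coefficient), so shortcut learning can be induced,
detected and mitigated on purpose in tests.

Images are stylized, not photorealistic: no attempt is made to match real
dermoscopy intensity statistics.  Everything is deterministic given the
spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk, polygon

from .data import BENIGN, LABELS, MALIGNANT, DatasetManifest
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "LesionParams",
    "SyntheticSpec",
    "GeneratedRecord",
    "generate_dataset",
    "add_vignette",
    "add_hair",
    "confound_association",
    "records_metadata",
    "records_to_arrays",
]

#: Fitzpatrick-inspired base skin colors (RGB in [0,1]); a recorded
#: covariate only, never a label signal.
SKIN_TONES = (
    (0.96, 0.84, 0.76),
    (0.91, 0.75, 0.64),
    (0.80, 0.60, 0.48),
    (0.62, 0.44, 0.32),
    (0.45, 0.31, 0.22),
)

#: base lesion pigment (uniform brown)
_BASE_PIGMENT = (0.45, 0.30, 0.22)

#: high-contrast variegation pigments — the distinct colors (black,
#: blue-gray, red, dark brown) that clinical color variegation refers to
_VARIEGATED_PIGMENTS = (
    (0.10, 0.08, 0.08),
    (0.25, 0.32, 0.45),
    (0.55, 0.12, 0.12),
    (0.22, 0.12, 0.08),
)


@dataclass(frozen=True)
class LesionParams:
    """Per-class lesion morphology ranges.

    ``irregularity`` is the amplitude of the sinusoidal boundary
    perturbation relative to the mean radius; ``n_patches`` the number of
    pigment patches (variegation); ``diameter_range`` the lesion diameter as
    a fraction of the image side.
    """

    irregularity: tuple[float, float]
    n_patches: tuple[int, int]
    diameter_range: tuple[float, float] = (0.30, 0.48)


#: defaults: benign = round and uniform, malignant = irregular and variegated
BENIGN_LESION = LesionParams(irregularity=(0.02, 0.08), n_patches=(1, 1))
MALIGNANT_LESION = LesionParams(irregularity=(0.25, 0.45), n_patches=(3, 4))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative configuration for one synthetic dataset.

    Confound probabilities are per-class ``(benign, malignant)`` pairs; the
    defaults produce clean, confound-free images.
    """

    n_images: int = 200
    image_size: int = 224
    class_balance: float = 0.5  # proportion malignant
    benign: LesionParams = BENIGN_LESION
    malignant: LesionParams = MALIGNANT_LESION
    vignette_prob: tuple[float, float] = (0.0, 0.0)
    vignette_inner_radius: float = 0.70
    hair_prob: tuple[float, float] = (0.0, 0.0)
    hair_strokes: tuple[int, int] = (8, 16)
    skin_tones: tuple = SKIN_TONES
    seed: int = 0

    def __post_init__(self):
        if self.n_images <= 0:
            raise ConfigurationError("n_images must be positive")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be at least 16")
        for name in ("class_balance",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        for name in ("vignette_prob", "hair_prob"):
            pb, pm = getattr(self, name)
            if not (0.0 <= pb <= 1.0 and 0.0 <= pm <= 1.0):
                raise ConfigurationError(f"{name} entries must be in [0,1]")
        if not 0.0 < self.vignette_inner_radius <= 1.0:
            raise ConfigurationError("vignette_inner_radius must be in (0,1]")
        for lp in (self.benign, self.malignant):
            if lp.diameter_range[1] >= 1.0:
                raise ConfigurationError(
                    "lesion diameter must stay below the image size")


@dataclass
class GeneratedRecord:
    """One rendered image plus its generative metadata."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    label: str
    has_vignette: bool
    has_hair: bool
    skin_tone: int  # index into the spec's skin-tone anchors
    irregularity: float
    variegation: int
    filename: str = ""


def _lesion_mask_and_colors(size: int, rng: np.random.Generator,
                            params: LesionParams):
    """Render an irregular radial polygon lesion; returns (mask, patches).

    The boundary is r(θ) = R·(1 + a·Σ_k c_k sin(kθ + φ_k)) with the
    harmonic amplitudes normalized so ``a`` is the overall perturbation
    amplitude (the irregularity).
    """
    irregularity = rng.uniform(*params.irregularity)
    diameter = rng.uniform(*params.diameter_range) * size
    radius = diameter / 2.0
    cy, cx = rng.uniform(0.42, 0.58, size=2) * size
    theta = np.linspace(0.0, 2.0 * np.pi, 128, endpoint=False)
    harmonics = rng.integers(2, 7, size=3)
    coeffs = rng.uniform(0.4, 1.0, size=3)
    coeffs /= coeffs.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    wobble = sum(c * np.sin(k * theta + p)
                 for k, c, p in zip(harmonics, coeffs, phases))
    r = np.clip(radius * (1.0 + irregularity * wobble), 2.0, size / 2 - 1)
    rows = np.clip(cy + r * np.sin(theta), 0, size - 1)
    cols = np.clip(cx + r * np.cos(theta), 0, size - 1)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = polygon(rows, cols, shape=(size, size))
    mask[rr, cc] = True

    # Variegation: benign lesions get a single low-contrast patch near the
    # base pigment; multi-patch (malignant) lesions draw from the distinct
    # clinical variegation colors (black / blue-gray / red / dark brown).
    n_patches = int(rng.integers(params.n_patches[0], params.n_patches[1] + 1))
    patches = []
    pigment_idx = rng.permutation(len(_VARIEGATED_PIGMENTS))
    for i in range(n_patches):
        pr = radius * rng.uniform(0.30, 0.55)
        pcy = cy + rng.uniform(-0.45, 0.45) * radius
        pcx = cx + rng.uniform(-0.45, 0.45) * radius
        prr, pcc = disk((pcy, pcx), pr, shape=(size, size))
        pmask = np.zeros((size, size), dtype=bool)
        pmask[prr, pcc] = True
        if n_patches == 1:
            color = np.array(_BASE_PIGMENT) * rng.uniform(0.85, 1.0)
        else:
            color = np.array(
                _VARIEGATED_PIGMENTS[pigment_idx[i % len(_VARIEGATED_PIGMENTS)]])
            color = np.clip(color + rng.uniform(-0.04, 0.04, size=3), 0, 1)
        patches.append((pmask & mask, color))
    return mask, patches, irregularity, n_patches


def _render_image(size: int, rng: np.random.Generator, params: LesionParams,
                  skin_tone_idx: int, tones) -> tuple[np.ndarray, float, int]:
    base = np.array(tones[skin_tone_idx], dtype=np.float32)
    img = np.empty((size, size, 3), dtype=np.float32)
    img[:] = base
    img += rng.normal(0.0, 0.012, size=img.shape).astype(np.float32)
    mask, patches, irregularity, n_patches = \
        _lesion_mask_and_colors(size, rng, params)
    lesion_color = np.clip(
        np.array(_BASE_PIGMENT) + rng.uniform(-0.06, 0.06, size=3), 0, 1)
    img[mask] = 0.35 * img[mask] + 0.65 * lesion_color.astype(np.float32)
    for pmask, color in patches:
        img[pmask] = 0.12 * img[pmask] + 0.88 * color.astype(np.float32)
    return np.clip(img, 0.0, 1.0), irregularity, n_patches


def add_vignette(image: np.ndarray, inner_radius_fraction: float = 0.70
                 ) -> np.ndarray:
    """Apply a dark circular vignette, emulating dermatoscope optics.

    Pixels inside ``inner_radius_fraction`` of the inscribed-circle radius
    are untouched; outside, brightness falls off smoothly (cosine ramp) to
    near-black.  The image must be square.
    """
    if not 0.0 < inner_radius_fraction <= 1.0:
        raise ConfigurationError(
            f"inner_radius_fraction must be in (0,1], got {inner_radius_fraction}")
    image = np.asarray(image, dtype=np.float32)
    if image.shape[0] != image.shape[1]:
        raise ConfigurationError("vignette requires a square image")
    size = image.shape[0]
    half = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - half + 0.5, xx - half + 0.5)
    r0 = inner_radius_fraction * half
    ramp = max(0.18 * size, 2.0)
    t = np.clip((r - r0) / ramp, 0.0, 1.0)
    floor = 0.03
    gain = floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(np.pi * t))
    return (image * gain[..., None].astype(np.float32)).clip(0.0, 1.0)


def add_hair(image: np.ndarray, n_strokes: int, seed: int = 0) -> np.ndarray:
    """Overlay dark curved hair strokes (1–3 px wide quadratic arcs).

    Strokes are placed one-per-cell on a jittered grid, so distinct strokes
    occupy disjoint regions of the canvas; ``n_strokes=0`` is the identity.
    """
    if n_strokes < 0:
        raise ConfigurationError("n_strokes must be >= 0")
    image = np.asarray(image, dtype=np.float32)
    if n_strokes == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    size = image.shape[0]
    out = image.copy()
    g = int(np.ceil(np.sqrt(n_strokes)))
    cell = size / g
    cells = [(i, j) for i in range(g) for j in range(g)]
    order = rng.permutation(len(cells))
    for k in range(n_strokes):
        ci, cj = cells[order[k]]
        margin = max(2.0, 0.12 * cell)
        lo_y, hi_y = ci * cell + margin, (ci + 1) * cell - margin
        lo_x, hi_x = cj * cell + margin, (cj + 1) * cell - margin
        p0 = np.array([rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)])
        p2 = np.array([rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)])
        mid = (p0 + p2) / 2
        perp = rng.uniform(-0.4, 0.4) * (hi_y - lo_y)
        p1 = np.clip(mid + perp, [lo_y, lo_x], [hi_y, hi_x])
        width = rng.integers(1, 4)  # 1-3 px
        shade = rng.uniform(0.05, 0.20)
        color = np.array([shade, shade * 0.85, shade * 0.7], dtype=np.float32)
        t = np.linspace(0.0, 1.0, 64)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        for py, px in pts:
            rr, cc = disk((py, px), max(width / 2.0, 0.6), shape=(size, size))
            out[rr, cc] = color
    return out


def confound_association(metadata: pd.DataFrame, flag_column: str = "has_vignette",
                         label_column: str = "label") -> float:
    """Phi coefficient between the binary label and a binary artifact flag.

    Computed from the 2×2 contingency table; a degenerate margin (all-same
    flag or label) is reported as 0 with a warning.
    """
    y = (metadata[label_column] == MALIGNANT).to_numpy() \
        if metadata[label_column].dtype == object \
        else metadata[label_column].astype(bool).to_numpy()
    f = metadata[flag_column].astype(bool).to_numpy()
    n11 = int(np.sum(y & f))
    n10 = int(np.sum(y & ~f))
    n01 = int(np.sum(~y & f))
    n00 = int(np.sum(~y & ~f))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        logger.warning("degenerate margin in phi computation; returning 0")
        return 0.0
    return float((n11 * n00 - n10 * n01) / np.sqrt(denom))


def generate_dataset(spec: SyntheticSpec, out_dir=None
                     ) -> tuple[list[GeneratedRecord], DatasetManifest]:
    """Render a labeled synthetic dataset.

    Class counts are allocated deterministically (``round(balance·n)``
    malignant).  When ``out_dir`` is given, images are written as PNGs in
    ``Benign``/``Malignant`` subfolders next to a ``metadata.csv`` and the
    returned manifest points at the files; otherwise the manifest carries
    virtual ``synthetic://`` paths and consumers should use the in-memory
    records.
    """
    rng = np.random.default_rng(spec.seed)
    n_mal = int(round(spec.class_balance * spec.n_images))
    labels = [MALIGNANT] * n_mal + [BENIGN] * (spec.n_images - n_mal)
    rng.shuffle(labels)

    records: list[GeneratedRecord] = []
    for i, label in enumerate(labels):
        is_mal = label == MALIGNANT
        params = spec.malignant if is_mal else spec.benign
        tone = int(rng.integers(0, len(spec.skin_tones)))
        img, irregularity, n_patches = _render_image(
            spec.image_size, rng, params, tone, spec.skin_tones)
        p_vig = spec.vignette_prob[1 if is_mal else 0]
        p_hair = spec.hair_prob[1 if is_mal else 0]
        has_vig = bool(rng.random() < p_vig)
        has_hair = bool(rng.random() < p_hair)
        if has_vig:
            img = add_vignette(img, spec.vignette_inner_radius)
        if has_hair:
            n_strokes = int(rng.integers(spec.hair_strokes[0],
                                         spec.hair_strokes[1] + 1))
            img = add_hair(img, n_strokes, seed=int(rng.integers(2 ** 31)))
        records.append(GeneratedRecord(
            image=img.astype(np.float32), label=label, has_vignette=has_vig,
            has_hair=has_hair, skin_tone=tone, irregularity=irregularity,
            variegation=n_patches, filename=f"{label}_{i:05d}.png"))

    if out_dir is not None:
        out_dir = Path(out_dir)
        for sub in ("Benign", "Malignant"):
            (out_dir / sub).mkdir(parents=True, exist_ok=True)
        paths = []
        for rec in records:
            sub = "Malignant" if rec.label == MALIGNANT else "Benign"
            path = out_dir / sub / rec.filename
            Image.fromarray(
                (rec.image * 255.0).round().astype(np.uint8)).save(path)
            paths.append(str(path))
        meta = pd.DataFrame({
            "filename": [r.filename for r in records],
            "label": [r.label for r in records],
            "has_vignette": [r.has_vignette for r in records],
            "has_hair": [r.has_hair for r in records],
            "skin_tone": [r.skin_tone for r in records],
            "irregularity": [r.irregularity for r in records],
            "variegation": [r.variegation for r in records],
        })
        meta.to_csv(out_dir / "metadata.csv", index=False)
    else:
        paths = [f"synthetic://{r.filename}" for r in records]

    manifest = DatasetManifest.from_records([
        {"path": p, "label": r.label, "source": "synthetic",
         "split": "unassigned"}
        for p, r in zip(paths, records)])
    return records, manifest


def records_metadata(records: list[GeneratedRecord]) -> pd.DataFrame:
    """Metadata table for in-memory records (same columns as metadata.csv)."""
    return pd.DataFrame({
        "filename": [r.filename for r in records],
        "label": [r.label for r in records],
        "has_vignette": [r.has_vignette for r in records],
        "has_hair": [r.has_hair for r in records],
        "skin_tone": [r.skin_tone for r in records],
        "irregularity": [r.irregularity for r in records],
        "variegation": [r.variegation for r in records],
    })


def records_to_arrays(records: list[GeneratedRecord]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack in-memory records into (X, y) with malignant encoded 1."""
    X = np.stack([r.image for r in records])
    y = np.array([LABELS.index(r.label) for r in records], dtype=np.int64)
    return X, y
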