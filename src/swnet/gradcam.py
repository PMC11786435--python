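"""Grad-CAM saliency maps and region-mass statistics for bias auditing.

Grad-CAM weights each channel of a convolutional feature map by the spatial
average of the gradient of a class score (taken on the *pre-softmax* logit)
with respect to that channel, rectifies the weighted sum, upsamples it
bilinearly to the input size and max-normalizes it to [0, 1].  A model that
shortcuts on an acquisition artifact (dark vignette ring, hair) concentrates
saliency inside the artifact region; :func:`saliency_mass` turns that visual
impression into a scalar — the fraction of total saliency falling inside a
boolean region mask — so bias can be compared across models numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .arch import GraphModel, NetworkGraph
from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "Heatmap",
    "grad_cam",
    "overlay",
    "saliency_mass",
    "save_heatmap",
    "default_gradcam_layers",
    "vignette_ring_mask",
]

#: node kinds that produce spatial feature maps Grad-CAM can target
_FEATURE_KINDS = ("conv", "batchnorm", "relu", "concat")


@dataclass
class Heatmap:
    """Nonnegative saliency map aligned to an input image.

    ``values`` is H×W, max-normalized to [0, 1] unless the raw rectified
    map was identically zero (then ``is_zero`` is set and values stay 0).
    """

    values: np.ndarray
    target_layer: str
    target_class: int
    is_zero: bool = False


def default_gradcam_layers(graph: NetworkGraph) -> list[str]:
    """The nine-layer audit set: the stem convolution, the last convolution
    of each stage, and the four post-concatenation batch norms."""
    names = set(graph.names())
    layers = ["Conv1", "Conv9", "Conv17", "Conv25", "Conv33",
              "BNConcat1", "BNConcat2", "BNConcat3", "BNConcat4"]
    return [l for l in layers if l in names]


def grad_cam(model: GraphModel, image: np.ndarray,
             target_layer: str | None = None,
             target_class: int | None = None) -> Heatmap:
    """Compute a Grad-CAM heatmap for one image.

    Parameters
    ----------
    image
        (H, W, 3) array sized for the network.
    target_layer
        Name of a convolution/batch-norm/ReLU/concatenation node; defaults
        to the last post-concatenation batch norm.
    target_class
        Class index to explain; defaults to the predicted class.
    """
    graph = model.graph
    if target_layer is None:
        target_layer = "BNConcat4"
    try:
        node = graph.node(target_layer)
    except KeyError:
        valid = [n.name for n in graph.nodes if n.kind in _FEATURE_KINDS]
        raise ConfigurationError(
            f"unknown layer {target_layer!r}; valid feature layers: {valid}"
        ) from None
    if node.kind not in _FEATURE_KINDS:
        raise ConfigurationError(
            f"layer {target_layer!r} ({node.kind}) has no spatial feature "
            f"map; choose a convolution/batch-norm/ReLU/concat node")
    image = np.asarray(image, dtype=np.float32)
    x = image[None]
    acts = model.forward(x, training=False)
    logits = acts["Fc3"]
    if target_class is None:
        target_class = int(logits[0].argmax())
    dscore = np.zeros_like(logits)
    dscore[0, target_class] = 1.0
    dacts = model.backward(dscore)
    fmap = acts[target_layer][0]       # (h, w, C)
    grad = dacts[target_layer][0]
    weights = grad.mean(axis=(0, 1))   # spatial average per channel
    cam = np.maximum((fmap * weights).sum(axis=-1), 0.0)
    cam = _sk_resize(cam, image.shape[:2], order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    peak = cam.max()
    if peak <= 0.0:
        return Heatmap(np.zeros(image.shape[:2], dtype=np.float32),
                       target_layer, target_class, is_zero=True)
    return Heatmap((cam / peak).astype(np.float32), target_layer, target_class)


def overlay(image: np.ndarray, heatmap: Heatmap, alpha: float = 0.4,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a color-mapped heatmap onto an RGB image in [0, 1]."""
    image = np.asarray(image, dtype=np.float32)
    if image.shape[:2] != heatmap.values.shape:
        raise ShapeError(
            f"image {image.shape[:2]} and heatmap {heatmap.values.shape} "
            f"dims differ")
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in [0,1], got {alpha}")
    colored = colormaps[cmap](heatmap.values)[..., :3].astype(np.float32)
    return ((1.0 - alpha) * image + alpha * colored).clip(0.0, 1.0)


def saliency_mass(heatmap: Heatmap, mask: np.ndarray) -> float:
    """Fraction of total heatmap mass inside a boolean region mask.

    Returns 0 for an identically-zero map.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != heatmap.values.shape:
        raise ShapeError(
            f"mask {mask.shape} and heatmap {heatmap.values.shape} dims differ")
    total = float(heatmap.values.sum())
    if total == 0.0:
        return 0.0
    return float(heatmap.values[mask].sum()) / total


def save_heatmap(heatmap: Heatmap, path, mask: np.ndarray | None = None) -> None:
    """Persist a heatmap as 16-bit grayscale PNG plus a JSON sidecar.

    The sidecar records the target layer/class, the zero flag, and — when a
    region mask is supplied — the saliency mass inside it.
    """
    import json
    from pathlib import Path

    from PIL import Image

    path = Path(path)
    quantized = np.round(heatmap.values * 65535.0).astype(np.uint16)
    Image.fromarray(quantized).save(path)  # uint16 → 16-bit grayscale PNG
    meta = {
        "target_layer": heatmap.target_layer,
        "target_class": int(heatmap.target_class),
        "is_zero": bool(heatmap.is_zero),
    }
    if mask is not None:
        meta["mask_saliency_mass"] = saliency_mass(heatmap, mask)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def vignette_ring_mask(size: int, inner_radius_fraction: float = 0.70
                       ) -> np.ndarray:
    """Boolean mask of the vignette-affected ring (pixels outside the inner
    radius of :func:`swnet.synth.add_vignette`'s untouched disc)."""
    half = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - half + 0.5, xx - half + 0.5)
    return r > inner_radius_fraction * half
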