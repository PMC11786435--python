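"""Shared fixtures.

The heavy fixtures (anything that trains a network) are session-scoped and
deliberately small: the tiny network uses width multiplier 1/8 at 64×64
input, which keeps one full 15-epoch training run around a minute on one
CPU while preserving the four-stage architecture end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

from swnet import arch, synth
from swnet import training as T

TINY_SIDE = 64
TINY_MULT = 1 / 8


@pytest.fixture(scope="session")
def tiny_graph():
    return arch.build_swnet(input_size=TINY_SIDE, width_multiplier=TINY_MULT)


@pytest.fixture(scope="session")
def clean_dataset():
    """200 confound-free synthetic lesion images (balanced, seed-fixed)."""
    spec = synth.SyntheticSpec(n_images=200, image_size=TINY_SIDE, seed=7)
    records, manifest = synth.generate_dataset(spec)
    X, y = synth.records_to_arrays(records)
    return {"records": records, "manifest": manifest, "X": X, "y": y}


@pytest.fixture(scope="session")
def clean_testset():
    """Separate confound-free held-out set (different generator seed)."""
    spec = synth.SyntheticSpec(n_images=60, image_size=TINY_SIDE, seed=13)
    records, _ = synth.generate_dataset(spec)
    return synth.records_to_arrays(records)


@pytest.fixture(scope="session")
def trained_tiny(tiny_graph, clean_dataset):
    """Tiny SWNet trained 15 epochs on the 200 separable images."""
    model = arch.GraphModel(tiny_graph, seed=0)
    config = T.TrainConfig(epochs=15, seed=0)
    history = T.fit(model, clean_dataset["X"], clean_dataset["y"], config)
    return {"model": model, "history": history, "config": config}


@pytest.fixture(scope="session")
def bias_experiment(tiny_graph, clean_testset):
    """Two-source shortcut-learning experiment.

    Source A couples the vignette artifact perfectly with the malignant
    label; source B couples it with the benign label.  The confounded model
    trains on A alone, the pooled model on A∪B (where the coupling cancels).
    Both are evaluated on a confound-free test set and probed with Grad-CAM
    on vignetted images against the vignette-ring mask.
    """
    from swnet import gradcam

    spec_a = synth.SyntheticSpec(n_images=100, image_size=TINY_SIDE,
                                 vignette_prob=(0.0, 1.0), seed=11)
    spec_b = synth.SyntheticSpec(n_images=100, image_size=TINY_SIDE,
                                 vignette_prob=(1.0, 0.0), seed=12)
    recs_a, _ = synth.generate_dataset(spec_a)
    recs_b, _ = synth.generate_dataset(spec_b)
    Xa, ya = synth.records_to_arrays(recs_a)
    Xb, yb = synth.records_to_arrays(recs_b)
    Xt, yt = clean_testset

    config = T.TrainConfig(epochs=15, seed=1)
    confounded = arch.GraphModel(tiny_graph, seed=1)
    T.fit(confounded, Xa, ya, config)
    pooled = arch.GraphModel(tiny_graph, seed=1)
    T.fit(pooled, np.concatenate([Xa, Xb]), np.concatenate([ya, yb]), config)

    ring = gradcam.vignette_ring_mask(TINY_SIDE, spec_a.vignette_inner_radius)
    probes = [synth.add_vignette(img, spec_a.vignette_inner_radius)
              for img in Xt[:24]]
    masses = {}
    for name, model in (("confounded", confounded), ("pooled", pooled)):
        masses[name] = float(np.mean([
            gradcam.saliency_mass(
                gradcam.grad_cam(model, p, target_layer="BNConcat4"), ring)
            for p in probes]))
    return {
        "confounded": confounded,
        "pooled": pooled,
        "records_a": recs_a,
        "acc_confounded": T.accuracy(T.evaluate_arrays(confounded, Xt, yt)),
        "acc_pooled": T.accuracy(T.evaluate_arrays(pooled, Xt, yt)),
        "mass_confounded": masses["confounded"],
        "mass_pooled": masses["pooled"],
        "n_probes": len(probes),
    }
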