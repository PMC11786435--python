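"""Grad-CAM: finite-difference oracle, map properties, bias statistic."""

import numpy as np
import pytest
from skimage.transform import resize as sk_resize

from swnet import arch, gradcam
from swnet.exceptions import ConfigurationError, ShapeError


def _toy_graph(size=8, channels=4):
    """Input → Conv → ReLU → GAP → FC: the smallest DAG Grad-CAM applies to."""
    nodes = [
        arch.LayerNode("Input", "input", {"channels": 3, "size": size}),
        arch.LayerNode("Conv1", "conv",
                       {"in_channels": 3, "out_channels": channels,
                        "kernel": 3, "stride": 1, "padding": 1}),
        arch.LayerNode("ReLU1", "relu", {}),
        arch.LayerNode("GlobalAvgPool", "gap", {"channels": channels}),
        arch.LayerNode("Fc3", "fc",
                       {"in_features": channels, "out_features": 2}),
        arch.LayerNode("Softmax", "softmax", {}),
    ]
    edges = [("Input", "Conv1"), ("Conv1", "ReLU1"),
             ("ReLU1", "GlobalAvgPool"), ("GlobalAvgPool", "Fc3"),
             ("Fc3", "Softmax")]
    return arch.NetworkGraph(nodes, edges, size, 2)


@pytest.fixture(scope="module")
def toy_model():
    return arch.GraphModel(_toy_graph(), seed=7, dtype=np.float64)


@pytest.fixture(scope="module")
def toy_image():
    rng = np.random.default_rng(0)
    return rng.uniform(0.0, 1.0, size=(8, 8, 3))


class TestOracle:
    def test_analytic_equals_finite_difference(self, toy_model, toy_image):
        """Channel weights from the backward pass match numeric gradients of
        the class score w.r.t. the target feature map to 1e-4 relative."""
        target_class = 1
        heatmap = gradcam.grad_cam(toy_model, toy_image,
                                   target_layer="Conv1",
                                   target_class=target_class)
        acts = toy_model.forward(toy_image[None], training=False)
        fmap = acts["Conv1"].copy()

        def score(feature_map):
            out = toy_model.forward(
                toy_image[None], training=False,
                override={"Conv1": feature_map})
            return out["Fc3"][0, target_class]

        eps = 1e-6
        h, w, c = fmap.shape[1:]
        numeric_grad = np.zeros((h, w, c))
        for i in range(h):
            for j in range(w):
                for k in range(c):
                    up = fmap.copy()
                    up[0, i, j, k] += eps
                    down = fmap.copy()
                    down[0, i, j, k] -= eps
                    numeric_grad[i, j, k] = (score(up) - score(down)) / (2 * eps)
        weights = numeric_grad.mean(axis=(0, 1))
        cam = np.maximum((fmap[0] * weights).sum(axis=-1), 0.0)
        cam = sk_resize(cam, toy_image.shape[:2], order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        cam = cam / cam.max()
        np.testing.assert_allclose(heatmap.values, cam, rtol=1e-4, atol=1e-7)


class TestHeatmapProperties:
    def test_nonnegative_and_max_normalized(self, toy_model, toy_image):
        hm = gradcam.grad_cam(toy_model, toy_image, target_layer="Conv1")
        assert np.all(hm.values >= 0)
        assert hm.values.max() == pytest.approx(1.0)
        assert not hm.is_zero

    def test_defaults_to_predicted_class(self, toy_model, toy_image):
        hm = gradcam.grad_cam(toy_model, toy_image, target_layer="Conv1")
        predicted = int(toy_model.predict(toy_image[None])[0])
        assert hm.target_class == predicted

    def test_zero_map_flagged(self, toy_image):
        model = arch.GraphModel(_toy_graph(), seed=7, dtype=np.float64)
        model.layers["Fc3"].params["W"][...] = 0.0  # no score gradient
        hm = gradcam.grad_cam(model, toy_image, target_layer="Conv1",
                              target_class=0)
        assert hm.is_zero
        assert np.all(hm.values == 0)

    def test_unknown_layer_lists_valid_ones(self, toy_model, toy_image):
        with pytest.raises(ConfigurationError, match="Conv1"):
            gradcam.grad_cam(toy_model, toy_image, target_layer="Nope")

    def test_fully_connected_target_rejected(self, toy_model, toy_image):
        with pytest.raises(ConfigurationError):
            gradcam.grad_cam(toy_model, toy_image, target_layer="Fc3")

    def test_default_layer_set_has_nine_entries(self):
        graph = arch.build_swnet(input_size=64, width_multiplier=1 / 8)
        layers = gradcam.default_gradcam_layers(graph)
        assert len(layers) == 9
        assert "Conv1" in layers and "BNConcat4" in layers


class TestOverlay:
    def test_alpha_zero_returns_image(self, toy_image):
        hm = gradcam.Heatmap(np.random.default_rng(0).uniform(size=(8, 8)),
                             "Conv1", 0)
        out = gradcam.overlay(toy_image, hm, alpha=0.0)
        assert np.allclose(out, toy_image, atol=1e-6)

    def test_alpha_one_returns_colormap(self, toy_image):
        from matplotlib import colormaps

        values = np.random.default_rng(1).uniform(size=(8, 8))
        hm = gradcam.Heatmap(values, "Conv1", 0)
        out = gradcam.overlay(toy_image, hm, alpha=1.0)
        assert np.allclose(out, colormaps["jet"](values)[..., :3], atol=1e-6)

    def test_blend_identity_on_constant_image(self):
        img = np.full((8, 8, 3), 0.5, dtype=np.float32)
        values = np.random.default_rng(2).uniform(size=(8, 8))
        hm = gradcam.Heatmap(values, "Conv1", 0)
        from matplotlib import colormaps

        expected = 0.6 * img + 0.4 * colormaps["jet"](values)[..., :3]
        assert np.allclose(gradcam.overlay(img, hm, alpha=0.4), expected,
                           atol=1e-6)

    def test_mismatched_dims_rejected(self, toy_image):
        hm = gradcam.Heatmap(np.zeros((4, 4)), "Conv1", 0)
        with pytest.raises(ShapeError):
            gradcam.overlay(toy_image, hm)


class TestSaliencyMass:
    def test_uniform_map_quarter_mask(self):
        hm = gradcam.Heatmap(np.ones((8, 8)), "x", 0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4, :4] = True
        assert gradcam.saliency_mass(hm, mask) == pytest.approx(0.25)

    def test_full_mask_is_one(self):
        hm = gradcam.Heatmap(np.random.default_rng(0).uniform(size=(8, 8)),
                             "x", 0)
        assert gradcam.saliency_mass(hm, np.ones((8, 8), bool)) == 1.0

    def test_concentrated_map(self):
        values = np.zeros((8, 8))
        values[2, 3] = 1.0
        mask = np.zeros((8, 8), bool)
        mask[:4, :] = True
        hm = gradcam.Heatmap(values, "x", 0)
        assert gradcam.saliency_mass(hm, mask) == 1.0

    def test_mass_additivity_over_complement(self):
        values = np.random.default_rng(3).uniform(size=(16, 16))
        hm = gradcam.Heatmap(values, "x", 0)
        mask = np.random.default_rng(4).random((16, 16)) < 0.3
        total = (gradcam.saliency_mass(hm, mask)
                 + gradcam.saliency_mass(hm, ~mask))
        assert total == pytest.approx(1.0)

    def test_zero_map_mass_is_zero(self):
        hm = gradcam.Heatmap(np.zeros((8, 8)), "x", 0, is_zero=True)
        assert gradcam.saliency_mass(hm, np.ones((8, 8), bool)) == 0.0


def test_save_heatmap_16bit_png_with_metadata(tmp_path, toy_model, toy_image):
    from PIL import Image
    import json

    hm = gradcam.grad_cam(toy_model, toy_image, target_layer="Conv1")
    out = tmp_path / "heatmap.png"
    mask = np.zeros((8, 8), bool)
    mask[:4] = True
    gradcam.save_heatmap(hm, out, mask=mask)
    with Image.open(out) as im:
        restored = np.asarray(im) / 65535.0
    assert np.allclose(restored, hm.values, atol=1e-4)
    meta = json.loads(out.with_suffix(".json").read_text())
    assert meta["target_layer"] == "Conv1"
    assert meta["mask_saliency_mass"] == pytest.approx(
        gradcam.saliency_mass(hm, mask))


class TestBiasDetection:
    def test_confounded_model_attends_to_vignette_ring(self, bias_experiment):
        """A model trained where the vignette predicts the label puts more
        Grad-CAM mass in the vignette ring than a model trained on the
        pooled (de-confounded) sources."""
        assert bias_experiment["n_probes"] >= 20
        assert (bias_experiment["mass_confounded"]
                > bias_experiment["mass_pooled"])
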