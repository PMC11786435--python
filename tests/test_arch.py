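"""Structural audits of the SWNet graph: node counts, shapes, parameters."""

import numpy as np
import pytest

from swnet import arch
from swnet.exceptions import AuditError, ConfigurationError, ShapeError


@pytest.fixture(scope="module")
def default_graph():
    return arch.build_swnet()


class TestStructure:
    def test_node_counts_match_published_architecture(self, default_graph):
        kinds = {}
        for n in default_graph.nodes:
            kinds[n.kind] = kinds.get(n.kind, 0) + 1
        assert kinds["conv"] == 33
        assert kinds["batchnorm"] == 37
        assert kinds["relu"] == 33
        assert kinds["concat"] == 4
        assert kinds["gap"] == 1
        assert kinds["fc"] == 3
        assert kinds["dropout"] == 2

    def test_total_layer_count(self, default_graph):
        assert arch.count_layers(default_graph) == 113

    def test_layer_count_invariant_to_classes_and_width(self):
        assert arch.count_layers(arch.build_swnet(num_classes=7)) == 113
        g = arch.build_swnet(width_multiplier=1 / 8)
        assert sum(1 for n in g.nodes if n.kind == "conv") == 33
        assert sum(1 for n in g.nodes if n.kind == "concat") == 4

    def test_hand_built_two_layer_graph(self):
        nodes = [
            arch.LayerNode("Input", "input", {"channels": 3, "size": 16}),
            arch.LayerNode("Conv1", "conv",
                           {"in_channels": 3, "out_channels": 8,
                            "kernel": 3, "stride": 1, "padding": 1}),
            arch.LayerNode("BN1", "batchnorm", {"channels": 8}),
        ]
        edges = [("Input", "Conv1"), ("Conv1", "BN1")]
        g = arch.NetworkGraph(nodes, edges, input_size=16, num_classes=2)
        assert arch.count_layers(g) == 2

    def test_verify_architecture_all_ok(self, default_graph):
        report = arch.verify_architecture(default_graph)
        assert report["all_ok"]
        assert report["measured"]["conv_parameters"] == 9_368_192

    def test_build_errors(self):
        with pytest.raises(ConfigurationError):
            arch.build_swnet(input_size=100)  # not divisible by 16
        with pytest.raises(ConfigurationError):
            arch.build_swnet(width_multiplier=0)
        with pytest.raises(ConfigurationError):
            arch.build_swnet(width_multiplier=-1.0)


class TestParameters:
    def test_published_conv_parameter_total(self, default_graph):
        report = arch.count_parameters(default_graph)
        assert report.conv_total == 9_368_192
        assert report.conv_weights == 9_364_320
        assert report.conv_biases == 3_872

    def test_single_conv_closed_form(self):
        nodes = [
            arch.LayerNode("Input", "input", {"channels": 3, "size": 16}),
            arch.LayerNode("Conv1", "conv",
                           {"in_channels": 3, "out_channels": 32,
                            "kernel": 3, "stride": 1, "padding": 1}),
        ]
        g = arch.NetworkGraph(nodes, [("Input", "Conv1")], 16, 2)
        assert arch.count_parameters(g).conv_total == 9 * 3 * 32 + 32 == 896

    @pytest.mark.parametrize("multiplier,expected", [
        # hand-evaluated closed-form sums with scaled widths
        (1 / 8, 146_896),
        (1 / 2, 2_343_232),
        (1, 9_368_192),
    ])
    def test_width_scaling_law(self, multiplier, expected):
        g = arch.build_swnet(width_multiplier=multiplier)
        assert arch.count_parameters(g).conv_total == expected

    def test_report_matches_instantiated_tensor_sizes(self):
        """Brute-force oracle: enumerate every actual weight array."""
        g = arch.build_swnet(input_size=32, width_multiplier=1 / 8)
        model = arch.GraphModel(g, seed=0)
        report = arch.count_parameters(g)
        by_family = {"conv": 0, "batchnorm": 0, "fc": 0}
        for name, layer in model.layers.items():
            kind = g.node(name).kind
            if kind in by_family:
                by_family[kind] += sum(p.size for p in layer.params.values())
        assert by_family["conv"] == report.conv_total
        assert by_family["batchnorm"] == report.batchnorm_total
        assert by_family["fc"] == report.fc_total

    def test_unresolved_channels_raise_naming_node(self):
        nodes = [
            arch.LayerNode("Input", "input", {"channels": 3, "size": 16}),
            arch.LayerNode("ConvX", "conv", {"stride": 1}),
        ]
        g = arch.NetworkGraph(nodes, [("Input", "ConvX")], 16, 2)
        with pytest.raises(AuditError, match="ConvX"):
            arch.count_parameters(g)


class TestShapes:
    def test_published_activation_shapes(self, default_graph):
        shapes = arch.forward_shapes(default_graph)
        assert shapes["Input"] == (224, 224, 3)
        assert shapes["Conv1"] == (224, 224, 32)
        assert shapes["Concat1"] == (112, 112, 128)
        # channel-sum rule at the later concatenations
        assert shapes["Concat2"] == (56, 56, 256)
        assert shapes["Conv18"] == (56, 56, 128)
        assert shapes["Concat3"] == (28, 28, 512)
        assert shapes["Concat4"] == (14, 14, 1024)
        assert shapes["GlobalAvgPool"] == (1, 1, 1024)
        assert shapes["Fc1"] == (1, 1, 300)
        assert shapes["Drop2"] == (1, 1, 64)
        assert shapes["Fc3"] == (1, 1, 2)

    def test_resolution_halves_once_per_stage(self, default_graph):
        shapes = arch.forward_shapes(default_graph)
        chain = [shapes[f"Concat{i}"][0] for i in range(1, 5)]
        assert chain == [112, 56, 28, 14]

    def test_concat_channels_sum_inputs(self, default_graph):
        shapes = arch.forward_shapes(default_graph)
        for i in range(1, 5):
            preds = default_graph.predecessors(f"Concat{i}")
            total = sum(shapes[p][2] for p in preds)
            assert shapes[f"Concat{i}"][2] == total

    def test_mismatched_input_shape_raises(self, default_graph):
        with pytest.raises(ShapeError):
            arch.forward_shapes(default_graph, (128, 128, 3))

    def test_incompatible_concat_raises_naming_stage(self):
        nodes = [
            arch.LayerNode("Input", "input", {"channels": 3, "size": 16}),
            arch.LayerNode("Conv1", "conv",
                           {"in_channels": 3, "out_channels": 4,
                            "kernel": 3, "stride": 1, "padding": 1}),
            arch.LayerNode("Conv2", "conv",
                           {"in_channels": 3, "out_channels": 4,
                            "kernel": 3, "stride": 2, "padding": 1}),
            arch.LayerNode("Concat1", "concat", {}),
        ]
        edges = [("Input", "Conv1"), ("Input", "Conv2"),
                 ("Conv1", "Concat1"), ("Conv2", "Concat1")]
        g = arch.NetworkGraph(nodes, edges, 16, 2)
        with pytest.raises(ShapeError, match="Concat1"):
            arch.forward_shapes(g)


@pytest.fixture(scope="module")
def tiny_model():
    g = arch.build_swnet(input_size=32, width_multiplier=1 / 8)
    return arch.GraphModel(g, seed=3)


class TestForward:

    def test_softmax_probability_simplex(self, tiny_model):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 32, 32, 3)).astype(np.float32)
        probs = arch.forward(tiny_model, x)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_input_fresh_model_is_uniform(self, tiny_model):
        """Zero input through zero-biased convs and identity-initialized
        batch norms yields zero logits, hence a uniform posterior."""
        probs = arch.forward(tiny_model, np.zeros((2, 32, 32, 3)))
        assert np.allclose(probs, 0.5, atol=1e-6)

    def test_forward_deterministic_given_seed(self):
        g = arch.build_swnet(input_size=32, width_multiplier=1 / 8)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 32, 32, 3)).astype(np.float32)
        p1 = arch.forward(arch.GraphModel(g, seed=5), x)
        p2 = arch.forward(arch.GraphModel(g, seed=5), x)
        assert np.array_equal(p1, p2)

    def test_wrong_input_size_raises(self, tiny_model):
        with pytest.raises(ShapeError):
            tiny_model.forward(np.zeros((1, 64, 64, 3)))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        g = arch.build_swnet(input_size=32, width_multiplier=1 / 8)
        model = arch.GraphModel(g, seed=2)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 32, 32, 3)).astype(np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "weights.npz"
        arch.save_checkpoint(model, path)
        fresh = arch.GraphModel(g, seed=99)
        arch.load_checkpoint(fresh, path)
        assert np.array_equal(fresh.predict_proba(x), before)

    def test_fingerprint_mismatch_rejected(self, tmp_path):
        g1 = arch.build_swnet(input_size=32, width_multiplier=1 / 8)
        g2 = arch.build_swnet(input_size=32, width_multiplier=1 / 4)
        path = tmp_path / "weights.npz"
        arch.save_checkpoint(arch.GraphModel(g1, seed=0), path)
        with pytest.raises(ConfigurationError):
            arch.load_checkpoint(arch.GraphModel(g2, seed=0), path)
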