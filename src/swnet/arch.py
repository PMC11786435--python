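"""SWNet architecture: DAG construction, structural audits, and execution.

SWNet is a wide, four-stage convolutional network for binary (benign vs
malignant) skin-lesion classification.  A stem 3×3 convolution lifts the RGB
input to the first stage width; each of the four stages then runs four
parallel branches of two 3×3 convolutions (stride 1 then stride 2) over the
same stage input and concatenates the branch outputs along the channel axis,
so the representation widens (32→64→128→256 channels per branch, 128/256/
512/1024 after concatenation) while the resolution halves per stage
(224→112→56→28→14).  Every convolution is followed by batch normalization
and ReLU; each concatenation is followed by batch normalization.  A global
average pool feeds three fully connected layers (300 → 64 → classes) with
dropout 0.5 between them and a terminal softmax.

The default build reproduces the published structural arithmetic exactly:
33 convolutions, 37 batch norms, 113 total layers and 9,368,192
convolutional parameters.

``build_swnet`` returns a :class:`NetworkGraph` — a plain, auditable node/
edge description.  :class:`GraphModel` instantiates engine layers for the
graph and runs forward/backward passes; the audits (``count_layers``,
``count_parameters``, ``forward_shapes``, ``audit_table``,
``verify_architecture``) work on the graph alone, without weights.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .exceptions import AuditError, ConfigurationError, ShapeError

__all__ = [
    "LayerNode",
    "NetworkGraph",
    "ParamReport",
    "ShapeReport",
    "build_swnet",
    "count_layers",
    "count_parameters",
    "forward_shapes",
    "forward",
    "GraphModel",
    "audit_table",
    "verify_architecture",
    "architecture_fingerprint",
    "save_checkpoint",
    "load_checkpoint",
]

#: layer families included in the published total-layer count; the input
#: node and the terminal softmax are not counted separately.
COUNTED_KINDS = ("conv", "batchnorm", "relu", "concat", "gap", "fc", "dropout")

#: per-branch channel widths of the four stages at multiplier 1.
STAGE_WIDTHS = (32, 64, 128, 256)
BRANCHES_PER_STAGE = 4
FC_SIZES = (300, 64)
DROPOUT_P = 0.5


@dataclass
class LayerNode:
    """One node of the network DAG.

    ``attrs`` carries the structural facts audits need: ``in_channels`` /
    ``out_channels`` and ``stride`` for convolutions, ``channels`` for batch
    norms, ``in_features`` / ``out_features`` for fully connected layers,
    ``p`` for dropout.
    """

    name: str
    kind: str
    attrs: dict = field(default_factory=dict)


@dataclass
class NetworkGraph:
    """Directed acyclic layer graph; ``nodes`` is a topological order."""

    nodes: list[LayerNode]
    edges: list[tuple[str, str]]
    input_size: int
    num_classes: int

    def __post_init__(self):
        self._by_name = {n.name: n for n in self.nodes}
        if len(self._by_name) != len(self.nodes):
            raise ConfigurationError("duplicate node names in graph")
        self._preds: dict[str, list[str]] = {n.name: [] for n in self.nodes}
        self._succs: dict[str, list[str]] = {n.name: [] for n in self.nodes}
        order = {n.name: i for i, n in enumerate(self.nodes)}
        for src, dst in self.edges:
            if order[src] >= order[dst]:
                raise ConfigurationError(
                    f"edge {src}->{dst} violates topological node order")
            self._preds[dst].append(src)
            self._succs[src].append(dst)

    def node(self, name: str) -> LayerNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no node named {name!r}") from None

    def predecessors(self, name: str) -> list[str]:
        return self._preds[name]

    def successors(self, name: str) -> list[str]:
        return self._succs[name]

    def names(self) -> list[str]:
        return [n.name for n in self.nodes]


def build_swnet(input_size: int = 224, num_classes: int = 2,
                width_multiplier: float = 1.0) -> NetworkGraph:
    """Construct the SWNet DAG.

    Parameters
    ----------
    input_size
        Side of the square RGB input; must be divisible by 16 (four
        stride-2 halvings).
    num_classes
        Output classes (2 for benign/malignant).
    width_multiplier
        Scales the per-branch stage widths 32/64/128/256 (ceil to integers);
        useful for desk-scale experiments (e.g. 1/8 → widths 4/8/16/32).
        Node counts are width-invariant.
    """
    if input_size <= 0 or input_size % 16 != 0:
        raise ConfigurationError(
            f"input_size must be a positive multiple of 16, got {input_size}")
    if width_multiplier <= 0:
        raise ConfigurationError(
            f"width_multiplier must be positive, got {width_multiplier}")
    if num_classes < 2:
        raise ConfigurationError(f"num_classes must be >= 2, got {num_classes}")
    widths = [math.ceil(width_multiplier * w) for w in STAGE_WIDTHS]

    nodes: list[LayerNode] = []
    edges: list[tuple[str, str]] = []

    def add(node: LayerNode, *sources: str) -> str:
        nodes.append(node)
        for s in sources:
            edges.append((s, node.name))
        return node.name

    add(LayerNode("Input", "input", {"channels": 3, "size": input_size}))

    def conv_bn_relu(idx: int, src: str, cin: int, cout: int, stride: int) -> str:
        add(LayerNode(f"Conv{idx}", "conv",
                      {"in_channels": cin, "out_channels": cout,
                       "kernel": 3, "stride": stride, "padding": 1}), src)
        add(LayerNode(f"BN{idx}", "batchnorm", {"channels": cout}), f"Conv{idx}")
        add(LayerNode(f"ReLU{idx}", "relu", {}), f"BN{idx}")
        return f"ReLU{idx}"

    # Stem convolution lifts RGB to the stage-1 width at full resolution.
    stage_input = conv_bn_relu(1, "Input", 3, widths[0], 1)
    conv_idx = 2
    for stage, width in enumerate(widths, start=1):
        cin = widths[0] if stage == 1 else BRANCHES_PER_STAGE * widths[stage - 2]
        branch_outputs = []
        for _ in range(BRANCHES_PER_STAGE):
            mid = conv_bn_relu(conv_idx, stage_input, cin, width, 1)
            conv_idx += 1
            out = conv_bn_relu(conv_idx, mid, width, width, 2)
            conv_idx += 1
            branch_outputs.append(out)
        cat = add(LayerNode(f"Concat{stage}", "concat", {}), *branch_outputs)
        stage_input = add(
            LayerNode(f"BNConcat{stage}", "batchnorm",
                      {"channels": BRANCHES_PER_STAGE * width}), cat)

    gap_channels = BRANCHES_PER_STAGE * widths[-1]
    add(LayerNode("GlobalAvgPool", "gap", {"channels": gap_channels}), stage_input)
    fc_in = gap_channels
    prev = "GlobalAvgPool"
    for i, fc_out in enumerate(FC_SIZES, start=1):
        add(LayerNode(f"Fc{i}", "fc",
                      {"in_features": fc_in, "out_features": fc_out}), prev)
        prev = add(LayerNode(f"Drop{i}", "dropout", {"p": DROPOUT_P}), f"Fc{i}")
        fc_in = fc_out
    add(LayerNode("Fc3", "fc",
                  {"in_features": fc_in, "out_features": num_classes}), prev)
    add(LayerNode("Softmax", "softmax", {}), "Fc3")

    return NetworkGraph(nodes, edges, input_size, num_classes)


# ---------------------------------------------------------------------------
# Structural audits
# ---------------------------------------------------------------------------

def count_layers(graph: NetworkGraph) -> int:
    """Total computational layers: conv + BN + ReLU + concat + pool + FC +
    dropout nodes (the input node and the terminal softmax are not counted)."""
    return sum(1 for n in graph.nodes if n.kind in COUNTED_KINDS)


@dataclass
class ParamReport:
    """Learnable-parameter audit, broken down per node and by layer family."""

    per_node: dict[str, tuple[int, int]]  # name -> (weights, biases)
    conv_weights: int
    conv_biases: int
    batchnorm_total: int
    fc_total: int

    @property
    def conv_total(self) -> int:
        return self.conv_weights + self.conv_biases

    @property
    def total(self) -> int:
        return self.conv_total + self.batchnorm_total + self.fc_total


def count_parameters(graph: NetworkGraph) -> ParamReport:
    """Closed-form parameter counts: 9·Cin·Cout + Cout per convolution,
    2·C per batch norm (scale + shift), In·Out + Out per FC layer."""
    per_node: dict[str, tuple[int, int]] = {}
    cw = cb = bn = fc = 0
    for n in graph.nodes:
        if n.kind == "conv":
            cin = n.attrs.get("in_channels")
            cout = n.attrs.get("out_channels")
            if not cin or not cout:
                raise AuditError(f"unresolved channels on conv node {n.name!r}")
            w, b = 9 * cin * cout, cout
            cw += w
            cb += b
            per_node[n.name] = (w, b)
        elif n.kind == "batchnorm":
            c = n.attrs.get("channels")
            if not c:
                raise AuditError(f"unresolved channels on batch-norm node {n.name!r}")
            bn += 2 * c
            per_node[n.name] = (c, c)  # gamma, beta
        elif n.kind == "fc":
            fi, fo = n.attrs.get("in_features"), n.attrs.get("out_features")
            if not fi or not fo:
                raise AuditError(f"unresolved features on fc node {n.name!r}")
            fc += fi * fo + fo
            per_node[n.name] = (fi * fo, fo)
        else:
            per_node[n.name] = (0, 0)
    return ParamReport(per_node, cw, cb, bn, fc)


@dataclass
class ShapeReport:
    """Per-node activation shapes as (H, W, C); FC-stack nodes are (1, 1, F)."""

    shapes: dict[str, tuple[int, int, int]]

    def __getitem__(self, name: str) -> tuple[int, int, int]:
        return self.shapes[name]


def forward_shapes(graph: NetworkGraph,
                   input_shape: tuple[int, int, int] | None = None) -> ShapeReport:
    """Symbolic shape propagation.

    Stride-1 convolutions preserve spatial dims (same padding); stride-2
    halve them; concatenations sum channels and require matching spatial
    dims; global average pooling collapses to 1×1×C.
    """
    if input_shape is None:
        input_shape = (graph.input_size, graph.input_size, 3)
    h, w, c = input_shape
    inp = graph.node("Input").attrs
    if h != inp.get("size", h) or w != inp.get("size", w) or c != inp.get("channels", c):
        raise ShapeError(
            f"input shape {input_shape} does not match graph input "
            f"{inp.get('size')}×{inp.get('size')}×{inp.get('channels')}")
    shapes: dict[str, tuple[int, int, int]] = {}
    for n in graph.nodes:
        preds = graph.predecessors(n.name)
        ins = [shapes[p] for p in preds]
        if n.kind == "input":
            shapes[n.name] = (h, w, c)
        elif n.kind == "conv":
            ih, iw, ic = ins[0]
            if ic != n.attrs["in_channels"]:
                raise ShapeError(
                    f"{n.name}: expected {n.attrs['in_channels']} input "
                    f"channels, got {ic}")
            s = n.attrs["stride"]
            shapes[n.name] = (ih // s, iw // s, n.attrs["out_channels"])
        elif n.kind in ("batchnorm", "relu", "dropout", "softmax"):
            shapes[n.name] = ins[0]
        elif n.kind == "concat":
            spatial = {(sh, sw) for sh, sw, _ in ins}
            if len(spatial) != 1:
                raise ShapeError(
                    f"{n.name}: concatenation inputs disagree on spatial "
                    f"dims {sorted(spatial)}")
            sh, sw = next(iter(spatial))
            shapes[n.name] = (sh, sw, sum(sc for _, _, sc in ins))
        elif n.kind == "gap":
            shapes[n.name] = (1, 1, ins[0][2])
        elif n.kind == "fc":
            shapes[n.name] = (1, 1, n.attrs["out_features"])
        else:  # pragma: no cover - unknown kinds are a programming error
            raise ShapeError(f"unknown node kind {n.kind!r} on {n.name!r}")
    return ShapeReport(shapes)


def audit_table(graph: NetworkGraph) -> list[dict]:
    """Layer-by-layer audit rows: name, kind, kernel/stride, activation
    shape, parameter count.  Mirrors the architecture summary table."""
    shapes = forward_shapes(graph)
    params = count_parameters(graph)
    rows = []
    for n in graph.nodes:
        w, b = params.per_node[n.name]
        kernel = ""
        if n.kind == "conv":
            kernel = f"3x3, stride={n.attrs['stride']}"
        h, ww, c = shapes[n.name]
        rows.append({
            "name": n.name,
            "kind": n.kind,
            "kernel": kernel,
            "activation": f"{h}x{ww}x{c}",
            "parameters": w + b,
        })
    return rows


def verify_architecture(graph: NetworkGraph) -> dict:
    """Recompute the five published structural counts for the default build.

    Returns a dict with the measured values and ``ok`` flags against the
    printed reference (33 convs, 37 batch norms, 113 layers, 9,368,192
    convolutional parameters, 1024 pooled channels).
    """
    kinds = {k: sum(1 for n in graph.nodes if n.kind == k) for k in COUNTED_KINDS}
    params = count_parameters(graph)
    shapes = forward_shapes(graph)
    measured = {
        "conv_layers": kinds["conv"],
        "batchnorm_layers": kinds["batchnorm"],
        "total_layers": count_layers(graph),
        "conv_parameters": params.conv_total,
        "gap_channels": shapes["GlobalAvgPool"][2],
    }
    reference = {
        "conv_layers": 33,
        "batchnorm_layers": 37,
        "total_layers": 113,
        "conv_parameters": 9_368_192,
        "gap_channels": 1024,
    }
    return {
        "measured": measured,
        "reference": reference,
        "ok": {k: measured[k] == reference[k] for k in reference},
        "all_ok": all(measured[k] == reference[k] for k in reference),
    }


def architecture_fingerprint(graph: NetworkGraph) -> str:
    """SHA-256 over the structural description (nodes, attrs, edges)."""
    payload = json.dumps(
        {
            "nodes": [[n.name, n.kind, sorted(n.attrs.items())] for n in graph.nodes],
            "edges": graph.edges,
            "input_size": graph.input_size,
            "num_classes": graph.num_classes,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

class GraphModel:
    """Executable instantiation of a :class:`NetworkGraph`.

    Holds one engine layer per parametric node, runs forward passes in
    topological order and backward passes in reverse order with gradient
    accumulation at fan-out points (the stage inputs feed four branches).
    """

    def __init__(self, graph: NetworkGraph, seed: int = 0, dtype=np.float32):
        self.graph = graph
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.layers: dict[str, object] = {}
        for n in graph.nodes:
            if n.kind == "conv":
                self.layers[n.name] = engine.Conv2d(
                    n.attrs["in_channels"], n.attrs["out_channels"],
                    n.attrs["stride"], rng=rng, dtype=dtype)
            elif n.kind == "batchnorm":
                self.layers[n.name] = engine.BatchNorm2d(
                    n.attrs["channels"], dtype=dtype)
            elif n.kind == "relu":
                self.layers[n.name] = engine.ReLU()
            elif n.kind == "fc":
                self.layers[n.name] = engine.Dense(
                    n.attrs["in_features"], n.attrs["out_features"],
                    rng=rng, dtype=dtype)
            elif n.kind == "dropout":
                self.layers[n.name] = engine.Dropout(n.attrs["p"])
        self._acts: dict[str, np.ndarray] = {}
        self._dacts: dict[str, np.ndarray] = {}
        self._concat_splits: dict[str, list[int]] = {}

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers.items():
            for k, v in getattr(layer, "params", {}).items():
                out[f"{name}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers.items():
            for k in getattr(layer, "params", {}):
                out[f"{name}.{k}"] = layer.grads[k]
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = dict(self.parameters())
        for name, layer in self.layers.items():
            if isinstance(layer, engine.BatchNorm2d):
                state[f"{name}.running_mean"] = layer.running_mean
                state[f"{name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            name, attr = key.rsplit(".", 1)
            layer = self.layers[name]
            if attr in ("running_mean", "running_var"):
                setattr(layer, attr, value.astype(self.dtype))
            else:
                if layer.params[attr].shape != value.shape:
                    raise ConfigurationError(
                        f"shape mismatch loading {key}: "
                        f"{layer.params[attr].shape} vs {value.shape}")
                layer.params[attr][...] = value

    # -- passes -------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                override: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
        """Run the network on a channels-last (N, H, W, 3) batch.

        Returns the full activation dict (node name → activation); the class
        probabilities live under ``"Softmax"`` and the pre-softmax scores
        under the final FC node.  ``override`` injects a fixed activation at
        a node instead of computing it — used for finite-difference checks.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[3] != 3 or x.shape[1] != x.shape[2] \
                or x.shape[1] != self.graph.input_size:
            raise ShapeError(
                f"expected input (N, {self.graph.input_size}, "
                f"{self.graph.input_size}, 3), got {x.shape}")
        acts: dict[str, np.ndarray] = {}
        for n in self.graph.nodes:
            if override is not None and n.name in override:
                acts[n.name] = np.asarray(override[n.name], dtype=self.dtype)
                continue
            if n.kind == "input":
                acts[n.name] = x
                continue
            ins = [acts[p] for p in self.graph.predecessors(n.name)]
            if n.kind == "concat":
                self._concat_splits[n.name] = [a.shape[-1] for a in ins]
                acts[n.name] = np.concatenate(ins, axis=-1)
            elif n.kind == "gap":
                acts[n.name] = ins[0].mean(axis=(1, 2))
            elif n.kind == "softmax":
                acts[n.name] = engine.softmax(ins[0])
            elif n.kind == "dropout":
                acts[n.name] = self.layers[n.name].forward(ins[0], training, rng)
            else:
                acts[n.name] = self.layers[n.name].forward(ins[0], training)
        self._acts = acts
        return acts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)["Softmax"]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def backward(self, grad: np.ndarray, from_node: str | None = None) -> dict[str, np.ndarray]:
        """Backpropagate ``grad`` injected at ``from_node`` (default: the
        final FC node, i.e. the pre-softmax scores).

        Returns the activation-gradient dict; parameter gradients are left
        on the layers (see :meth:`gradients`).
        """
        if from_node is None:
            from_node = "Fc3" if "Fc3" in self.graph.names() else self.graph.nodes[-2].name
        dacts: dict[str, np.ndarray] = {from_node: np.asarray(grad, dtype=self.dtype)}
        for n in reversed(self.graph.nodes):
            if n.name not in dacts:
                continue
            d = dacts[n.name]
            preds = self.graph.predecessors(n.name)
            if n.kind == "input" or not preds:
                continue
            if n.kind == "concat":
                splits = np.cumsum(self._concat_splits[n.name])[:-1]
                parts = np.split(d, splits, axis=-1)
                dins = list(parts)
            elif n.kind == "gap":
                src = self._acts[preds[0]]
                h, w = src.shape[1], src.shape[2]
                dins = [np.broadcast_to(
                    d[:, None, None, :] / (h * w), src.shape).astype(d.dtype)]
            elif n.kind == "softmax":
                p = self._acts[n.name]
                dins = [p * (d - (d * p).sum(axis=-1, keepdims=True))]
            else:
                dins = [self.layers[n.name].backward(d)]
            for p, dp in zip(preds, dins):
                if p in dacts:
                    dacts[p] = dacts[p] + dp
                else:
                    dacts[p] = dp
        self._dacts = dacts
        return dacts


def forward(model: GraphModel, batch: np.ndarray) -> np.ndarray:
    """Class-probability vectors for a batch of images (N, H, W, 3)."""
    return model.predict_proba(batch)


def save_checkpoint(model: GraphModel, path) -> None:
    """Persist weights plus an architecture fingerprint as an .npz archive."""
    state = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    state["__fingerprint__"] = np.array(architecture_fingerprint(model.graph))
    np.savez(path, **state)


def load_checkpoint(model: GraphModel, path) -> None:
    """Load weights saved by :func:`save_checkpoint`, verifying the
    architecture fingerprint."""
    with np.load(path, allow_pickle=False) as data:
        fp = str(data["__fingerprint__"])
        if fp != architecture_fingerprint(model.graph):
            raise ConfigurationError(
                "checkpoint fingerprint does not match model architecture")
        model.load_state_dict(
            {k.replace("/", "."): data[k] for k in data.files
             if k != "__fingerprint__"})
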