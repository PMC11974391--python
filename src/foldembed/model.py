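"""Invariant graph neural network mapping a structure graph to a unit
embedding vector.

Architecture
------------
A message-passing network in the E(n)-GNN family, configured without
coordinate updates, so it reduces to a standard GNN whose edge operation
additionally receives the squared Cα–Cα distance — the only geometric
input, which together with the invariant node features makes the
embedding SE(3)-invariant by construction:

1. one-layer MLP lifting the 69 node features to ``hidden_dim``;
2. ``n_layers`` message-passing layers with residual connections: per
   directed edge (i, j) an edge MLP (hidden 256 → output 64 by default,
   SiLU after both layers) consumes (h_i, h_j, ‖x_i − x_j‖²); messages
   are sum-aggregated at the receiving node i and a two-layer node MLP
   of (h_i, m_i) produces the update, added to h_i;
3. a two-layer node MLP, sum-pooling over nodes, a final two-layer MLP
   to ``embedding_dim``, and L2 normalization.

All hidden layers are 128-wide with SiLU activation by default and the
final embedding has 128 dimensions. Squared distances enter the edge MLP
raw (no scaling). There are no dropout or normalization layers; the
model behaves identically in training and inference.

Graphs are batched block-diagonally (node/edge concatenation with index
offsets plus segmented pooling), so batching never changes values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import MLP
from .features import N_NODE_FEATURES, StructureGraph

__all__ = ["ModelConfig", "Embedding", "Model", "GraphBatch", "init_model",
           "embed_graph", "embed_batch", "save_model", "load_model"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    embedding_dim: int = 128
    hidden_dim: int = 128
    n_layers: int = 6
    edge_hidden_dim: int = 256
    edge_out_dim: int = 64
    activation: str = "silu"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "hidden_dim", "n_layers",
                     "edge_hidden_dim", "edge_out_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.activation.lower() not in {"silu", "swish"}:
            raise ValueError("only the Swish/SiLU activation is supported")


@dataclass
class Embedding:
    """L2-normalized embedding vector of one domain."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        norm = np.linalg.norm(self.vector)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-5:
            raise ValueError(f"embedding is not unit length (‖v‖ = {norm})")

    @property
    def D(self) -> int:
        return len(self.vector)


class GraphBatch:
    """Block-diagonal concatenation of several structure graphs."""

    def __init__(self, graphs: list[StructureGraph]):
        if not graphs:
            raise ValueError("empty batch")
        sizes = [g.n_nodes for g in graphs]
        offsets = np.cumsum([0] + sizes[:-1])
        self.n_graphs = len(graphs)
        self.n_nodes = int(sum(sizes))
        self.node_features = np.vstack([g.node_features for g in graphs])
        self.coords = np.vstack([g.coords for g in graphs])
        edge_blocks = [
            g.edges + off for g, off in zip(graphs, offsets) if len(g.edges)
        ]
        self.edges = (
            np.vstack(edge_blocks) if edge_blocks else np.empty((0, 2), dtype=int)
        )
        self.graph_index = np.repeat(np.arange(self.n_graphs), sizes)


class _MessagePassingLayer:
    """One residual invariant message-passing layer."""

    def __init__(self, rng: np.random.Generator, cfg: ModelConfig):
        h, eh, eo = cfg.hidden_dim, cfg.edge_hidden_dim, cfg.edge_out_dim
        self.hidden_dim = h
        self.edge_mlp = MLP(rng, [2 * h + 1, eh, eo], final_activation=True)
        self.node_mlp = MLP(rng, [h + eo, h, h])

    def forward(self, h: np.ndarray, d2: np.ndarray, edges: np.ndarray) -> np.ndarray:
        self._edges = edges
        self._n = len(h)
        eo = self.node_mlp.layers[0].W.shape[0] - self.hidden_dim
        if len(edges):
            recv, send = edges[:, 0], edges[:, 1]
            edge_in = np.concatenate([h[recv], h[send], d2[:, None]], axis=1)
            messages = self.edge_mlp.forward(edge_in)
            agg = np.zeros((len(h), messages.shape[1]))
            np.add.at(agg, recv, messages)
        else:
            agg = np.zeros((len(h), eo))
        update = self.node_mlp.forward(np.concatenate([h, agg], axis=1))
        return h + update

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h_dim = self.hidden_dim
        grad_in = grad.copy()  # residual path
        grad_node_in = self.node_mlp.backward(grad)
        grad_in += grad_node_in[:, :h_dim]
        grad_agg = grad_node_in[:, h_dim:]
        if len(self._edges):
            recv, send = self._edges[:, 0], self._edges[:, 1]
            grad_messages = grad_agg[recv]
            grad_edge_in = self.edge_mlp.backward(grad_messages)
            np.add.at(grad_in, recv, grad_edge_in[:, :h_dim])
            np.add.at(grad_in, send, grad_edge_in[:, h_dim : 2 * h_dim])
        return grad_in

    def parameters(self):
        yield from self.edge_mlp.parameters()
        yield from self.node_mlp.parameters()

    def zero_grad(self) -> None:
        self.edge_mlp.zero_grad()
        self.node_mlp.zero_grad()


class Model:
    """The full embedding network. Use :func:`init_model` to build one."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.embed_mlp = MLP(rng, [N_NODE_FEATURES, h])
        self.mp_layers = [
            _MessagePassingLayer(rng, config) for _ in range(config.n_layers)
        ]
        self.post_mlp = MLP(rng, [h, h, h])
        self.out_mlp = MLP(rng, [h, h, config.embedding_dim])

    # ---- forward / backward -------------------------------------------

    def forward(self, batch: GraphBatch) -> np.ndarray:
        """Embed a batch; returns (n_graphs, embedding_dim) unit rows."""
        edges = batch.edges
        if len(edges):
            delta = batch.coords[edges[:, 0]] - batch.coords[edges[:, 1]]
            d2 = np.einsum("ij,ij->i", delta, delta)
        else:
            d2 = np.empty(0)
        h = self.embed_mlp.forward(batch.node_features)
        for layer in self.mp_layers:
            h = layer.forward(h, d2, edges)
        hn = self.post_mlp.forward(h)
        pooled = np.zeros((batch.n_graphs, hn.shape[1]))
        np.add.at(pooled, batch.graph_index, hn)
        raw = self.out_mlp.forward(pooled)
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
        if np.any(norms == 0) or not np.all(np.isfinite(raw)):
            raise FloatingPointError("non-finite or zero-norm embedding")
        self._cache = (batch, raw, norms)
        return raw / norms

    def backward(self, grad_z: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward pass."""
        batch, raw, norms = self._cache
        z = raw / norms
        grad_raw = (grad_z - z * np.sum(z * grad_z, axis=1, keepdims=True)) / norms
        grad_pooled = self.out_mlp.backward(grad_raw)
        grad_hn = grad_pooled[batch.graph_index]
        grad = self.post_mlp.backward(grad_hn)
        for layer in reversed(self.mp_layers):
            grad = layer.backward(grad)
        self.embed_mlp.backward(grad)

    # ---- parameter plumbing -------------------------------------------

    def parameters(self):
        yield from self.embed_mlp.parameters()
        for layer in self.mp_layers:
            yield from layer.parameters()
        yield from self.post_mlp.parameters()
        yield from self.out_mlp.parameters()

    def zero_grad(self) -> None:
        self.embed_mlp.zero_grad()
        for layer in self.mp_layers:
            layer.zero_grad()
        self.post_mlp.zero_grad()
        self.out_mlp.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("parameter count mismatch")
        for p, new in zip(own, arrays):
            if p.shape != new.shape:
                raise ValueError("parameter shape mismatch")
            p[:] = new

    def copy_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def fingerprint(self) -> str:
        """Hex digest identifying the architecture + weights; embeddings
        from models with different fingerprints are not comparable."""
        digest = hashlib.sha256()
        digest.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        for p, _ in self.parameters():
            digest.update(np.ascontiguousarray(p).tobytes())
        return digest.hexdigest()[:16]


def init_model(config: ModelConfig | None = None) -> Model:
    """Build a model with freshly initialized weights, deterministic in
    ``config.seed``."""
    return Model(config or ModelConfig())


def embed_graph(model: Model, graph: StructureGraph) -> Embedding:
    """Embed a single structure graph into a unit vector."""
    if graph.n_nodes < 1:
        raise ValueError("graph has no nodes")
    return Embedding(model.forward(GraphBatch([graph]))[0])


def embed_batch(model: Model, graphs: list[StructureGraph]) -> list[Embedding]:
    """Embed several graphs in one pass; numerically identical to calling
    :func:`embed_graph` per graph because pooling is segmented, not
    padded."""
    if not graphs:
        raise ValueError("no graphs to embed")
    z = model.forward(GraphBatch(graphs))
    return [Embedding(row) for row in z]


# ---- checkpoint container ---------------------------------------------
#
# A checkpoint is a .npz container holding a versioned JSON header
# (format version + model config) plus the named parameter arrays in
# order. Written through an explicit file handle so the caller's path is
# used verbatim.


def save_model(model: Model, path) -> None:
    header = json.dumps(
        {"format_version": CHECKPOINT_VERSION, "config": asdict(model.config)},
        sort_keys=True,
    )
    arrays = {f"param_{i:04d}": p for i, p in enumerate(model.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> Model:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"].tobytes()).decode())
        if header.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {header.get('format_version')}"
            )
        config = ModelConfig(**header["config"])
        model = Model(config)
        names = sorted(k for k in data.files if k.startswith("param_"))
        model.load_state_arrays([data[name] for name in names])
    return model
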