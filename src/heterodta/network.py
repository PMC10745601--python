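"""The heterogeneous affinity model.

Three entity streams are encoded and fused:

* targets and pockets — one-hot residue features pass through a sequence
  encoder (1D-CNN by default; LSTM, BiLSTM and CNN+LSTM variants available)
  whose per-position outputs become the vertex features of the residue
  contact graph;
* drugs — the 27-dimensional one-hot element features feed the molecular
  graph directly.

Each stream runs through an independent three-layer message-passing stack
(GraphSAGE by default; GCN, GAT and GIN variants available) with dimensions
32 -> 64 -> 128 and LeakyReLU after every layer, is pooled to a graph-level
vector, and projected to 256 dimensions.  The three projections are
concatenated (768) and a two-layer fully connected head (768 -> 256 -> 1,
LeakyReLU + dropout on the hidden layer) produces the predicted pKd.

For interpretability, a bidirectional scaled-dot-product attention over the
final pre-pooling vertex embeddings yields two row-stochastic score
matrices: atoms -> residues and residues -> atoms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, concat, gather_rows, spmm
from .graphs import Graph

__all__ = [
    "ModelConfig",
    "AttentionResult",
    "AffinityModel",
    "NumericError",
    "bidirectional_attention",
    "save_checkpoint",
    "load_checkpoint",
]

SEQ_ENCODERS = ("cnn", "lstm", "bilstm", "cnn_lstm", "none")
GNN_LAYERS = ("graphsage", "gcn", "gat", "gin")
POOLINGS = ("mean", "max")


class NumericError(Exception):
    """A non-finite value appeared during a forward pass."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference regime)."""

    seq_encoder: str = "cnn"
    gnn_layer: str = "graphsage"
    gnn_dims: tuple = (32, 64, 128)
    seq_out_dim: int = 128
    target_kernel: int = 5
    pocket_kernel: int = 3
    stride: int = 1
    projection_dim: int = 256
    fc_hidden: int = 256
    dropout: float = 0.4
    leaky_slope: float = 0.01
    pooling: str = "mean"
    residue_dim: int = 20
    atom_dim: int = 27

    def __post_init__(self):
        self.seq_encoder = self.seq_encoder.lower()
        self.gnn_layer = self.gnn_layer.lower()
        self.pooling = self.pooling.lower()
        self.gnn_dims = tuple(int(d) for d in self.gnn_dims)
        if self.seq_encoder not in SEQ_ENCODERS:
            raise ValueError(f"unknown seq_encoder {self.seq_encoder!r}")
        if self.gnn_layer not in GNN_LAYERS:
            raise ValueError(f"unknown gnn_layer {self.gnn_layer!r}")
        if self.pooling not in POOLINGS:
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if any(d <= 0 for d in self.gnn_dims):
            raise ValueError("gnn_dims must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")

    @property
    def residue_vertex_dim(self) -> int:
        """Vertex feature dimension entering the target/pocket GNN stacks."""
        return self.residue_dim if self.seq_encoder == "none" else self.seq_out_dim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gnn_dims"] = list(self.gnn_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class AttentionResult:
    """Row-stochastic interaction score matrices between a drug and a target."""

    atoms_to_residues: np.ndarray  # n_atoms x n_residues
    residues_to_atoms: np.ndarray  # n_residues x n_atoms


def bidirectional_attention(drug_emb, target_emb) -> AttentionResult:
    """Scaled dot-product attention in both directions.

    ``S = drug_emb @ target_emb.T / sqrt(d)``; atoms->residues rows are the
    row softmax of S, residues->atoms rows the row softmax of S.T.
    """
    drug_emb = np.asarray(getattr(drug_emb, "data", drug_emb), dtype=float)
    target_emb = np.asarray(getattr(target_emb, "data", target_emb), dtype=float)
    if drug_emb.size == 0 or target_emb.size == 0:
        raise ValueError("attention inputs must be nonempty")
    if drug_emb.shape[1] != target_emb.shape[1]:
        raise ValueError(
            f"embedding dims differ: {drug_emb.shape[1]} vs {target_emb.shape[1]}"
        )
    scores = drug_emb @ target_emb.T / np.sqrt(drug_emb.shape[1])

    def _softmax_rows(m):
        e = np.exp(m - m.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    return AttentionResult(
        atoms_to_residues=_softmax_rows(scores),
        residues_to_atoms=_softmax_rows(scores.T),
    )


# ---------------------------------------------------------------------------
# Parameterized building blocks
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear:
    def __init__(self, rng, d_in, d_out):
        self.W = _glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class Conv1dSame:
    """1D convolution with stride 1 and zero 'same' padding.

    The input is always leaf data (raw encodings), so the convolution is an
    im2col matrix times the kernel weights.
    """

    def __init__(self, rng, kernel, d_in, d_out):
        self.kernel = kernel
        self.d_in = d_in
        self.W = _glorot(rng, kernel * d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        length, d = x.shape
        if d != self.d_in:
            raise ValueError(f"expected {self.d_in} channels, got {d}")
        half = self.kernel // 2
        padded = np.zeros((length + 2 * half, d))
        padded[half : half + length] = x
        cols = [padded[t : t + length] for t in range(self.kernel)]
        return np.concatenate(cols, axis=1)

    def __call__(self, sequences) -> Tensor:
        """Encode a list of L_i x d_in arrays; returns one (sum L_i) x d_out
        tensor in input order."""
        col = np.vstack([self._im2col(np.asarray(s, float)) for s in sequences])
        return Tensor(col) @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class LSTMDirection:
    """One direction of an LSTM, unrolled over a ragged batch of sequences."""

    def __init__(self, rng, d_in, hidden):
        self.hidden = hidden
        self.W_x = _glorot(rng, d_in, 4 * hidden)
        self.W_h = _glorot(rng, hidden, 4 * hidden)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)

    def parameters(self):
        return [self.W_x, self.W_h, self.b]

    def run(self, x: Tensor, lengths, reverse: bool = False) -> Tensor:
        """``x`` is the (sum L_i) x d_in concatenation of sequences; returns
        the (sum L_i) x hidden per-position hidden states, position-aligned
        with the input (each sequence processed over its own valid window,
        right-to-left when ``reverse``)."""
        lengths = np.asarray(lengths, dtype=np.intp)
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        total, batch = int(offsets[-1]), len(lengths)
        l_max = int(lengths.max())
        # appended zero row stands in for exhausted sequences
        x_pad = concat([x, Tensor(np.zeros((1, x.shape[1])))], axis=0)
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        step_states = []
        for t in range(l_max):
            pos = (lengths - 1 - t) if reverse else np.full(batch, t)
            active = (t < lengths)
            idx = np.where(active, offsets[:-1] + np.clip(pos, 0, None), total)
            x_t = gather_rows(x_pad, idx)
            gates = x_t @ self.W_x + h @ self.W_h + self.b
            hsz = self.hidden
            i_g = _slice_cols(gates, 0, hsz).sigmoid()
            f_g = _slice_cols(gates, hsz, 2 * hsz).sigmoid()
            g_g = _slice_cols(gates, 2 * hsz, 3 * hsz).tanh()
            o_g = _slice_cols(gates, 3 * hsz, 4 * hsz).sigmoid()
            c = f_g * c + i_g * g_g
            h = o_g * c.tanh()
            step_states.append(h)
        stacked = concat(step_states, axis=0)  # (l_max * batch) x hidden
        # output row for sample i, sequence position p
        out_idx = np.empty(total, dtype=np.intp)
        for i in range(batch):
            p = np.arange(lengths[i])
            t_of_p = (lengths[i] - 1 - p) if reverse else p
            out_idx[offsets[i] : offsets[i + 1]] = t_of_p * batch + i
        return gather_rows(stacked, out_idx)


def _slice_cols(x: Tensor, lo, hi) -> Tensor:
    idx = np.arange(lo, hi)

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            acc[:, idx] = g
            x._accum(acc)

    return Tensor._node(x.data[:, idx], (x,), bwd)


class SequenceEncoder:
    """CNN / LSTM / BiLSTM / CNN+LSTM encoder producing d_out per position."""

    def __init__(self, rng, kind, kernel, d_in, d_out, slope):
        self.kind = kind
        self.slope = slope
        self._mods = []
        if kind == "cnn":
            self.conv = Conv1dSame(rng, kernel, d_in, d_out)
            self._mods = [self.conv]
        elif kind == "lstm":
            self.fwd = LSTMDirection(rng, d_in, d_out)
            self._mods = [self.fwd]
        elif kind == "bilstm":
            if d_out % 2:
                raise ValueError("bilstm output dim must be even")
            self.fwd = LSTMDirection(rng, d_in, d_out // 2)
            self.bwd = LSTMDirection(rng, d_in, d_out // 2)
            self._mods = [self.fwd, self.bwd]
        elif kind == "cnn_lstm":
            self.conv = Conv1dSame(rng, kernel, d_in, d_out)
            self.fwd = LSTMDirection(rng, d_out, d_out)
            self._mods = [self.conv, self.fwd]
        else:
            raise ValueError(f"unknown sequence encoder {kind!r}")

    def parameters(self):
        return [p for m in self._mods for p in m.parameters()]

    def __call__(self, sequences) -> Tensor:
        lengths = [np.asarray(s).shape[0] for s in sequences]
        if self.kind == "cnn":
            return self.conv(sequences).leaky_relu(self.slope)
        flat = Tensor(np.vstack([np.asarray(s, float) for s in sequences]))
        if self.kind == "lstm":
            return self.fwd.run(flat, lengths)
        if self.kind == "bilstm":
            return concat(
                [self.fwd.run(flat, lengths), self.bwd.run(flat, lengths, reverse=True)],
                axis=1,
            )
        # cnn_lstm
        conv_out = self.conv(sequences).leaky_relu(self.slope)
        return self.fwd.run(conv_out, lengths)


# ---------------------------------------------------------------------------
# Graph layers
# ---------------------------------------------------------------------------

class _BatchOps:
    """Constant sparse operators for a batched graph (built once per batch)."""

    def __init__(self, n_vertices, edge_index, membership):
        self.n = n_vertices
        src, dst = edge_index
        ones = np.ones(len(src))
        self.adj = sp.csr_matrix((ones, (dst, src)), shape=(self.n, self.n))
        deg = np.asarray(self.adj.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        self.adj_mean = sp.diags(inv) @ self.adj
        # GCN: symmetric normalization with self-loops added transparently
        adj_sl = self.adj + sp.identity(self.n, format="csr")
        deg_sl = np.asarray(adj_sl.sum(axis=1)).ravel()
        d_half = sp.diags(1.0 / np.sqrt(deg_sl))
        self.adj_gcn = d_half @ adj_sl @ d_half
        # GAT edge arrays include self-loops
        self.gat_src = np.concatenate([src, np.arange(self.n)])
        self.gat_dst = np.concatenate([dst, np.arange(self.n)])
        n_e = len(self.gat_src)
        self.gat_incidence = sp.csr_matrix(
            (np.ones(n_e), (self.gat_dst, np.arange(n_e))), shape=(self.n, n_e)
        )
        self.membership = np.asarray(membership, dtype=np.intp)
        k = int(self.membership.max()) + 1 if self.n else 0
        counts = np.bincount(self.membership, minlength=k).astype(float)
        self.pool_mean = sp.csr_matrix(
            (1.0 / counts[self.membership], (self.membership, np.arange(self.n))),
            shape=(k, self.n),
        )
        self.n_graphs = k


def _segment_max(x: Tensor, membership: np.ndarray, n_graphs: int) -> Tensor:
    """Per-graph column-wise max; gradient routes to the argmax rows."""
    n, d = x.shape
    best = np.full((n_graphs, d), -np.inf)
    arg = np.zeros((n_graphs, d), dtype=np.intp)
    for row in range(n):
        g = membership[row]
        better = x.data[row] > best[g]
        best[g][better] = x.data[row][better]
        arg[g][better] = row

    def bwd(grad):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            cols = np.broadcast_to(np.arange(d), (n_graphs, d))
            np.add.at(acc, (arg.ravel(), cols.ravel()), grad.ravel())
            x._accum(acc)

    return Tensor._node(best, (x,), bwd)


class SAGELayer:
    """GraphSAGE with mean neighbor aggregation and an explicit self term."""

    def __init__(self, rng, d_in, d_out):
        self.lin_self = Linear(rng, d_in, d_out)
        self.lin_neigh = Linear(rng, d_in, d_out)

    def __call__(self, x, ops):
        return self.lin_self(x) + self.lin_neigh(spmm(ops.adj_mean, x))

    def parameters(self):
        return self.lin_self.parameters() + self.lin_neigh.parameters()


class GCNLayer:
    def __init__(self, rng, d_in, d_out):
        self.lin = Linear(rng, d_in, d_out)

    def __call__(self, x, ops):
        return spmm(ops.adj_gcn, self.lin(x))

    def parameters(self):
        return self.lin.parameters()


class GINLayer:
    """Sum aggregation followed by a 2-layer MLP update (epsilon = 0)."""

    def __init__(self, rng, d_in, d_out):
        self.lin1 = Linear(rng, d_in, d_out)
        self.lin2 = Linear(rng, d_out, d_out)

    def __call__(self, x, ops):
        agg = x + spmm(ops.adj, x)
        return self.lin2(self.lin1(agg).leaky_relu())

    def parameters(self):
        return self.lin1.parameters() + self.lin2.parameters()


class GATLayer:
    """Single-head graph attention over neighbors plus a self-loop."""

    def __init__(self, rng, d_in, d_out):
        self.lin = Linear(rng, d_in, d_out)
        self.a_src = _glorot(rng, d_out, 1)
        self.a_dst = _glorot(rng, d_out, 1)

    def __call__(self, x, ops):
        h = self.lin(x)
        h_src = gather_rows(h, ops.gat_src)
        h_dst = gather_rows(h, ops.gat_dst)
        e = (h_src @ self.a_src + h_dst @ self.a_dst).leaky_relu(0.2)
        # segment softmax over incoming edges of each destination vertex
        m = np.full(ops.n, -np.inf)
        np.maximum.at(m, ops.gat_dst, e.data.ravel())
        z = (e - Tensor(m[ops.gat_dst][:, None])).exp()
        denom = spmm(ops.gat_incidence, z)
        alpha = z / gather_rows(denom, ops.gat_dst)
        return spmm(ops.gat_incidence, alpha * h_src)

    def parameters(self):
        return self.lin.parameters() + [self.a_src, self.a_dst]


_LAYER_TYPES = {
    "graphsage": SAGELayer,
    "gcn": GCNLayer,
    "gat": GATLayer,
    "gin": GINLayer,
}


class GNNStack:
    """Three message-passing layers with LeakyReLU after each."""

    def __init__(self, rng, layer_type, d_in, dims, slope):
        cls = _LAYER_TYPES[layer_type]
        self.slope = slope
        self.layers = []
        prev = d_in
        for d in dims:
            self.layers.append(cls(rng, prev, d))
            prev = d

    def __call__(self, x, ops) -> Tensor:
        for layer in self.layers:
            x = layer(x, ops).leaky_relu(self.slope)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------

class AffinityModel:
    """Heterogeneous CNN+GNN pKd regressor over drug/target/pocket triples."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.target_encoder = None
        self.pocket_encoder = None
        if c.seq_encoder != "none":
            self.target_encoder = SequenceEncoder(
                rng, c.seq_encoder, c.target_kernel, c.residue_dim,
                c.seq_out_dim, c.leaky_slope,
            )
            self.pocket_encoder = SequenceEncoder(
                rng, c.seq_encoder, c.pocket_kernel, c.residue_dim,
                c.seq_out_dim, c.leaky_slope,
            )
        res_dim = c.residue_vertex_dim
        self.gnn_drug = GNNStack(rng, c.gnn_layer, c.atom_dim, c.gnn_dims, c.leaky_slope)
        self.gnn_target = GNNStack(rng, c.gnn_layer, res_dim, c.gnn_dims, c.leaky_slope)
        self.gnn_pocket = GNNStack(rng, c.gnn_layer, res_dim, c.gnn_dims, c.leaky_slope)
        out = c.gnn_dims[-1]
        self.proj_drug = Linear(rng, out, c.projection_dim)
        self.proj_target = Linear(rng, out, c.projection_dim)
        self.proj_pocket = Linear(rng, out, c.projection_dim)
        self.fc1 = Linear(rng, 3 * c.projection_dim, c.fc_hidden)
        self.fc2 = Linear(rng, c.fc_hidden, 1)

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        mods = []
        if self.target_encoder is not None:
            mods += [self.target_encoder, self.pocket_encoder]
        mods += [
            self.gnn_drug, self.gnn_target, self.gnn_pocket,
            self.proj_drug, self.proj_target, self.proj_pocket,
            self.fc1, self.fc2,
        ]
        return [p for m in mods for p in m.parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    # -- spec'd operations -------------------------------------------------
    def encode_sequence(self, features: np.ndarray, which: str = "target") -> Tensor:
        """Per-position d_out features of one residue sequence (L x 20 in)."""
        enc = self.target_encoder if which == "target" else self.pocket_encoder
        if enc is None:
            raise ValueError("model configured without a sequence encoder")
        return enc([np.asarray(features, float)])

    def encode_graph(self, graph: Graph, stream: str = "drug"):
        """(vertex_embeddings, pooled) for a single graph."""
        if graph.n_vertices == 0:
            raise ValueError("cannot encode an empty graph")
        ops = _BatchOps(graph.n_vertices, graph.edge_index(), np.zeros(graph.n_vertices, dtype=int))
        stack = {"drug": self.gnn_drug, "target": self.gnn_target, "pocket": self.gnn_pocket}[stream]
        emb = stack(Tensor(graph.vertex_features), ops)
        pooled = self._pool(emb, ops)
        return emb, pooled

    def _pool(self, emb: Tensor, ops: _BatchOps) -> Tensor:
        if self.config.pooling == "mean":
            return spmm(ops.pool_mean, emb)
        return _segment_max(emb, ops.membership, ops.n_graphs)

    def project(self, pooled: Tensor, stream: str) -> Tensor:
        proj = {"drug": self.proj_drug, "target": self.proj_target,
                "pocket": self.proj_pocket}[stream]
        return proj(pooled)

    def fuse_and_predict(self, drug, target, pocket, training=False, rng=None) -> Tensor:
        """Concatenate the three 256-d stream vectors and regress pKd."""
        fused = concat([drug, target, pocket], axis=1)
        hidden = self.fc1(fused).leaky_relu(self.config.leaky_slope)
        if training and self.config.dropout > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            keep = (rng.random(hidden.shape) >= self.config.dropout) / (
                1.0 - self.config.dropout
            )
            hidden = hidden * Tensor(keep)
        out = self.fc2(hidden)
        if not np.all(np.isfinite(out.data)):
            raise NumericError("non-finite prediction in fusion head")
        return out

    # -- batched forward ---------------------------------------------------
    def forward_batch(self, samples, training=False, rng=None, want_attention=False):
        """Predictions for a list of featurized samples.

        Returns ``(predictions: Tensor of shape (B, 1), attention)`` where
        ``attention`` is a list of per-sample :class:`AttentionResult` (or
        None when not requested).
        """
        from .featurize import collate  # local import to avoid a cycle

        batch = collate(samples)
        c = self.config

        if self.target_encoder is not None:
            target_feats = self.target_encoder(batch.target_seqs)
            pocket_feats = self.pocket_encoder(batch.pocket_seqs)
        else:
            target_feats = Tensor(np.vstack(batch.target_seqs))
            pocket_feats = Tensor(np.vstack(batch.pocket_seqs))
        drug_feats = Tensor(batch.drug_features)

        emb_t = self.gnn_target(target_feats, batch.target_ops)
        emb_p = self.gnn_pocket(pocket_feats, batch.pocket_ops)
        emb_d = self.gnn_drug(drug_feats, batch.drug_ops)

        vec_t = self.project(self._pool(emb_t, batch.target_ops), "target")
        vec_p = self.project(self._pool(emb_p, batch.pocket_ops), "pocket")
        vec_d = self.project(self._pool(emb_d, batch.drug_ops), "drug")

        preds = self.fuse_and_predict(vec_d, vec_t, vec_p, training=training, rng=rng)

        attention = None
        if want_attention:
            attention = []
            for k in range(len(samples)):
                t_lo, t_hi = batch.target_offsets[k], batch.target_offsets[k + 1]
                d_lo, d_hi = batch.drug_offsets[k], batch.drug_offsets[k + 1]
                attention.append(
                    bidirectional_attention(
                        emb_d.data[d_lo:d_hi], emb_t.data[t_lo:t_hi]
                    )
                )
        return preds, attention

    def forward(self, sample, want_attention=False):
        """Single-sample evaluation-mode prediction (and optional attention)."""
        preds, attention = self.forward_batch(
            [sample], training=False, want_attention=want_attention
        )
        return float(preds.data[0, 0]), (attention[0] if attention else None)


def save_checkpoint(path, model: AffinityModel) -> None:
    """Persist parameters with the architecture config embedded."""
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __config__=json.dumps(model.config.to_dict()), **arrays)


def load_checkpoint(path) -> AffinityModel:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
    model = AffinityModel(config, seed=0)
    keys = sorted(k for k in data.files if k.startswith("param_"))
    model.load_state_arrays([data[k] for k in keys])
    return model
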