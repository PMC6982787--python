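"""Graph convolutional regression networks on molecular graphs.

The architecture follows the neural-fingerprint (Duvenaud-style) recipe for
ADMET regression: starting from 75 binary atom features, two graph
convolution steps of width 128 propagate information between bonded atoms
with ReLU activations, a per-atom dense layer lifts features to 256, and a
readout concatenates the mean and the max over atoms and applies a tanh,
yielding a 512-dimensional molecule embedding.  One linear output unit per
task sits on the shared embedding.

Each convolution applies a single affine pair to self and neighbour-summed
features: ``h'_v = ReLU(W_self h_v + W_nb Σ_{u∈N(v)} h_u + b)``.  Bond
types are not distinguished, and hydrogens are implicit.  Every operation
is invariant to the ordering of atoms within a molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._autograd import Tensor, concat, gather_rows, segment_max, sparse_matmul
from .mol import N_ATOM_FEATURES, MolecularGraph
from .nn import Adam, he_normal, zeros

MAX_DEGREE = 10


@dataclass
class GraphConvConfig:
    conv_dims: tuple[int, ...] = (128, 128)
    dense_dim: int = 256
    n_tasks: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 40
    lr_decay_every: int | None = 1000
    lr_decay_factor: float = 0.95
    weight_decay: float = 0.0
    # fidelity switches, all off by default
    degree_specific_weights: bool = False
    neighbor_maxpool: bool = False
    batch_norm: bool = False

    @property
    def readout_dim(self) -> int:
        return 2 * self.dense_dim


@dataclass
class GraphBatch:
    """A batch of molecular graphs packed into one block structure."""

    node_features: np.ndarray   # (n_total_atoms, 75)
    adjacency: sp.csr_matrix    # block-diagonal neighbour-sum operator
    mean_op: sp.csr_matrix      # (n_mols, n_atoms) row-averaging operator
    segment_ids: np.ndarray     # (n_atoms,) sorted molecule index per atom
    degrees: np.ndarray         # (n_atoms,)
    n_mols: int
    # edge list with self-loops (dst-sorted) for the optional max-pool
    edge_src: np.ndarray
    edge_dst: np.ndarray


def pack_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    """Concatenate graphs into a block-diagonal batch."""
    if not graphs:
        raise ValueError("empty graph batch")
    sizes = [g.n_atoms for g in graphs]
    offsets = np.cumsum([0] + sizes)
    features = np.concatenate([g.node_features for g in graphs], axis=0)
    adjacency = sp.block_diag([sp.csr_matrix(g.adjacency.astype(np.float64)) for g in graphs],
                              format="csr")
    n_atoms = offsets[-1]
    segment_ids = np.repeat(np.arange(len(graphs)), sizes)
    mean_op = sp.csr_matrix(
        (np.concatenate([np.full(s, 1.0 / s) for s in sizes]),
         (segment_ids, np.arange(n_atoms))),
        shape=(len(graphs), n_atoms))
    src, dst = [], []
    for g, off in zip(graphs, offsets[:-1]):
        ii, jj = np.nonzero(g.adjacency)
        src.append(ii + off)
        dst.append(jj + off)
        loops = np.arange(g.n_atoms) + off
        src.append(loops)
        dst.append(loops)
    src, dst = np.concatenate(src), np.concatenate(dst)
    order = np.argsort(dst, kind="stable")
    return GraphBatch(node_features=features, adjacency=adjacency, mean_op=mean_op,
                      segment_ids=segment_ids,
                      degrees=np.concatenate([g.degrees for g in graphs]),
                      n_mols=len(graphs), edge_src=src[order], edge_dst=dst[order])


def graph_conv_layer(x: Tensor, adjacency: sp.spmatrix, w_self: Tensor,
                     w_nb: Tensor, bias: Tensor) -> Tensor:
    """One convolution step: ReLU(x W_self + (A x) W_nb + b)."""
    return (x @ w_self + sparse_matmul(adjacency, x) @ w_nb + bias).relu()


def readout(atom_features: Tensor, batch: GraphBatch) -> Tensor:
    """tanh(concat(mean over atoms, max over atoms)) per molecule."""
    mean_part = sparse_matmul(batch.mean_op, atom_features)
    max_part = segment_max(atom_features, batch.segment_ids, batch.n_mols)
    return concat([mean_part, max_part], axis=1).tanh()


class GraphConvModel:
    """Two graph convolutions, a per-atom dense layer, mean/max readout,
    and independent linear task heads."""

    kind = "gcn"

    def __init__(self, config: GraphConvConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, Tensor] = {}
        dims = [N_ATOM_FEATURES, *config.conv_dims]
        for i, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            self.params[f"conv{i}_W_self"] = he_normal(rng, fan_in, fan_out)
            self.params[f"conv{i}_b"] = zeros(fan_out)
            if config.degree_specific_weights:
                for d in range(1, MAX_DEGREE + 1):
                    self.params[f"conv{i}_W_nb{d}"] = he_normal(rng, fan_in, fan_out)
            else:
                self.params[f"conv{i}_W_nb"] = he_normal(rng, fan_in, fan_out)
            if config.batch_norm:
                self.params[f"conv{i}_gamma"] = Tensor(np.ones(fan_out), requires_grad=True)
                self.params[f"conv{i}_beta"] = zeros(fan_out)
        self.params["dense_W"] = he_normal(rng, dims[-1], config.dense_dim)
        self.params["dense_b"] = zeros(config.dense_dim)
        self.params["W_out"] = he_normal(rng, config.readout_dim, config.n_tasks)
        self.params["b_out"] = zeros(config.n_tasks)

    # -- layers ----------------------------------------------------------
    def _conv(self, i: int, h: Tensor, batch: GraphBatch) -> Tensor:
        pre = h @ self.params[f"conv{i}_W_self"] + self.params[f"conv{i}_b"]
        if self.config.degree_specific_weights:
            summed = sparse_matmul(batch.adjacency, h)
            for d in range(1, MAX_DEGREE + 1):
                rows = batch.degrees == d
                if rows.any():
                    sel = Tensor(rows[:, None].astype(float))
                    pre = pre + (summed * sel) @ self.params[f"conv{i}_W_nb{d}"]
        else:
            pre = pre + sparse_matmul(batch.adjacency, h) @ self.params[f"conv{i}_W_nb"]
        out = pre.relu()
        if self.config.batch_norm:
            n = out.shape[0]
            mu = out.sum(axis=0) * (1.0 / n)
            centered = out - mu
            var = (centered * centered).sum(axis=0) * (1.0 / n)
            out = centered * ((var + Tensor(1e-5)) ** -0.5)
            out = out * self.params[f"conv{i}_gamma"] + self.params[f"conv{i}_beta"]
        if self.config.neighbor_maxpool:
            expanded = gather_rows(out, batch.edge_src)
            out = segment_max(expanded, batch.edge_dst, out.shape[0])
        return out

    # -- forward ---------------------------------------------------------
    def embed(self, batch: GraphBatch | list[MolecularGraph]) -> Tensor:
        """512-dimensional molecule embeddings (entries in (−1, 1))."""
        if isinstance(batch, list):
            batch = pack_graphs(batch)
        h = Tensor(batch.node_features)
        for i in range(len(self.config.conv_dims)):
            h = self._conv(i, h, batch)
        h = (h @ self.params["dense_W"] + self.params["dense_b"]).relu()
        return readout(h, batch)

    def forward(self, batch: GraphBatch | list[MolecularGraph],
                training: bool = False, rng=None) -> Tensor:
        """Per-task predictions on the standardized scale, shape (B, T)."""
        return self.embed(batch) @ self.params["W_out"] + self.params["b_out"]

    def predict(self, graphs: list[MolecularGraph]) -> np.ndarray:
        return self.forward(pack_graphs(graphs)).data

    def make_optimizer(self) -> Adam:
        cfg = self.config
        return Adam(self.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
                    lr_decay_every=cfg.lr_decay_every, lr_decay_factor=cfg.lr_decay_factor)
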