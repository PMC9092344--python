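"""Directed message-passing encoder over featurized graphs.

Hidden states live on directed edges. With atom features x_v and bond
features e_vw, the encoder computes

    h0_vw  = tau(W_i cat(x_v, e_vw))                       (edge init)
    h{t+1}_vw = tau(h0_vw + W_h sum_{k in N(v)\\w} ht_kv)   (T message steps)
    h_v    = tau(W_o cat(x_v, sum_{w in N(v)} hT_wv))      (back to atoms)
    h      = mean_v h_v   (or sum), then cat(h, f)          (readout input)

where the incoming sum excludes the reverse edge. W_i carries no bias;
W_h and W_o do. The functions here are the reference forward path used by
the trained model and by tests; training-time gradients are in
:mod:`cgrnet.nn`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .featurizer import FeaturizedGraph


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.

    hidden_size: width h of edge/atom hidden states (default 300).
    depth: number of message-passing steps T (default 3); 0 skips the
        update entirely and reads out the initial edge states.
    activation: only "relu" is supported.
    aggregation: "mean" (default) or "sum" pooling of atom states.
    """

    hidden_size: int = 300
    depth: int = 3
    activation: str = "relu"
    aggregation: str = "mean"

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def init_encoder_weights(cfg: EncoderConfig, atom_dim: int, bond_dim: int,
                         rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Glorot-uniform weights; biases start at zero.

    W_i has no bias; W_h and W_o each carry one (the bias on W_h is what
    brings the trainable-scalar count of the default reaction model to its
    printed value).
    """
    h = cfg.hidden_size

    def glorot(rows, cols):
        limit = np.sqrt(6.0 / (rows + cols))
        return rng.uniform(-limit, limit, size=(rows, cols))

    return {
        "W_i": glorot(h, atom_dim + bond_dim),
        "W_h": glorot(h, h),
        "b_h": np.zeros(h),
        "W_o": glorot(h, atom_dim + h),
        "b_o": np.zeros(h),
    }


def init_edge_states(graph: FeaturizedGraph, cfg: EncoderConfig,
                     weights: Dict[str, np.ndarray]) -> np.ndarray:
    """h0_vw = tau(W_i cat(x_v, e_vw)) for every directed edge v->w."""
    inp = np.concatenate([graph.atom_matrix[graph.edge_src],
                          graph.edge_matrix], axis=1)
    if inp.shape[1] != weights["W_i"].shape[1]:
        raise ValueError(
            f"W_i expects input dim {weights['W_i'].shape[1]}, "
            f"graph provides {inp.shape[1]}")
    return relu(inp @ weights["W_i"].T)


def _incoming_sum(states: np.ndarray, graph: FeaturizedGraph,
                  hidden: int) -> np.ndarray:
    """Per-atom sum of hidden states over incoming directed edges."""
    acc = np.zeros((graph.n_atoms, hidden))
    np.add.at(acc, graph.edge_tgt, states)
    return acc


def message_passing_step(states: np.ndarray, h0: np.ndarray,
                         graph: FeaturizedGraph, cfg: EncoderConfig,
                         weights: Dict[str, np.ndarray]) -> np.ndarray:
    """One directed update: the reverse edge is excluded from the sum.

    The incoming sum for edge v->w over N(v)\\w equals the full incoming
    sum at v minus the state of the reverse edge w->v.
    """
    acc = _incoming_sum(states, graph, cfg.hidden_size)
    msg = acc[graph.edge_src] - states[graph.rev_index]
    return relu(h0 + msg @ weights["W_h"].T + weights["b_h"])


def atom_hidden_states(states: np.ndarray, graph: FeaturizedGraph,
                       cfg: EncoderConfig,
                       weights: Dict[str, np.ndarray]) -> np.ndarray:
    """h_v = tau(W_o cat(x_v, sum of final incoming edge states))."""
    acc = _incoming_sum(states, graph, cfg.hidden_size)
    inp = np.concatenate([graph.atom_matrix, acc], axis=1)
    return relu(inp @ weights["W_o"].T + weights["b_o"])


def aggregate(atom_states: np.ndarray,
              extra_features: Optional[np.ndarray],
              cfg: EncoderConfig) -> np.ndarray:
    """Pool atom states into one embedding, then append descriptors f."""
    if atom_states.shape[0] == 0:
        raise ValueError("cannot aggregate an empty graph")
    if cfg.aggregation == "mean":
        emb = atom_states.mean(axis=0)
    else:
        emb = atom_states.sum(axis=0)
    if extra_features is not None:
        emb = np.concatenate([emb, np.asarray(extra_features, dtype=float)])
    return emb


def encode(graph: FeaturizedGraph, cfg: EncoderConfig,
           weights: Dict[str, np.ndarray]) -> np.ndarray:
    """Full encoder pass for a single graph."""
    h0 = init_edge_states(graph, cfg, weights)
    ht = h0
    for _ in range(cfg.depth):
        ht = message_passing_step(ht, h0, graph, cfg, weights)
    atoms = atom_hidden_states(ht, graph, cfg, weights)
    return aggregate(atoms, graph.extra_features, cfg)


def count_parameters(cfg: EncoderConfig, atom_dim: int, bond_dim: int,
                     ffn_layers: int = 2, n_extra: int = 0,
                     out_dim: int = 1) -> int:
    """Closed-form count of trainable scalars for encoder + FFN readout.

    W_i is bias-free; W_h, W_o and every FFN layer carry biases. The FFN
    maps (h + n_extra) -> h -> ... -> out_dim with ffn_layers weight
    matrices.
    """
    if ffn_layers < 1:
        raise ValueError("ffn_layers must be >= 1")
    h = cfg.hidden_size
    total = h * (atom_dim + bond_dim)          # W_i, no bias
    total += h * h + h                         # W_h + bias
    total += h * (atom_dim + h) + h            # W_o + bias
    dims = [h + n_extra] + [h] * (ffn_layers - 1) + [out_dim]
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        total += d_in * d_out + d_out
    return total


@dataclass
class BatchedGraph:
    """Disjoint union of featurized graphs with per-graph segments.

    Encoding the union with segment-wise aggregation gives results
    identical to encoding each graph alone.
    """

    atom_matrix: np.ndarray
    edge_matrix: np.ndarray
    edge_src: np.ndarray
    edge_tgt: np.ndarray
    rev_index: np.ndarray
    graph_id: np.ndarray               # atom -> graph index
    atom_counts: np.ndarray            # atoms per graph
    n_graphs: int
    extras: Optional[np.ndarray] = None   # n_graphs x n_extra

    @property
    def n_atoms(self) -> int:
        return self.atom_matrix.shape[0]


def batch_graphs(graphs: Sequence[FeaturizedGraph]) -> BatchedGraph:
    """Stack graphs into one disjoint union with offset edge indices."""
    if not graphs:
        raise ValueError("empty batch")
    atom_mats, edge_mats = [], []
    srcs, tgts, revs, gids = [], [], [], []
    extras: List[np.ndarray] = []
    a_off = e_off = 0
    for gi, g in enumerate(graphs):
        atom_mats.append(g.atom_matrix)
        edge_mats.append(g.edge_matrix)
        srcs.append(g.edge_src + a_off)
        tgts.append(g.edge_tgt + a_off)
        revs.append(g.rev_index + e_off)
        gids.append(np.full(g.n_atoms, gi, dtype=np.int64))
        if g.extra_features is not None:
            extras.append(np.asarray(g.extra_features, dtype=float))
        a_off += g.n_atoms
        e_off += g.n_directed_edges
    if extras and len(extras) != len(graphs):
        raise ValueError("either all graphs or none must carry extra features")
    return BatchedGraph(
        atom_matrix=np.concatenate(atom_mats, axis=0),
        edge_matrix=np.concatenate(edge_mats, axis=0),
        edge_src=np.concatenate(srcs),
        edge_tgt=np.concatenate(tgts),
        rev_index=np.concatenate(revs),
        graph_id=np.concatenate(gids),
        atom_counts=np.array([g.n_atoms for g in graphs], dtype=np.int64),
        n_graphs=len(graphs),
        extras=np.stack(extras) if extras else None,
    )
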