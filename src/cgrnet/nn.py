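"""NumPy neural-network engine: forward, backprop and Adam.

Two network front ends share one feed-forward readout stack and one
training path: :class:`DMPNNetwork` runs the directed message-passing
encoder over batched graphs, :class:`MLPNetwork` consumes fixed-length
vectors (fingerprint baselines). Gradients are hand-derived; a finite-
difference check in the test suite guards them. All math is float64.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .encoder import BatchedGraph, EncoderConfig

Params = Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# shared FFN readout

def ffn_dims(in_dim: int, hidden: int, n_layers: int, out_dim: int) -> List[int]:
    return [in_dim] + [hidden] * (n_layers - 1) + [out_dim]


def init_ffn(dims: List[int], rng: np.random.Generator) -> Params:
    params: Params = {}
    for l, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
        limit = np.sqrt(6.0 / (d_in + d_out))
        params[f"F{l}_W"] = rng.uniform(-limit, limit, size=(d_out, d_in))
        params[f"F{l}_b"] = np.zeros(d_out)
    return params


def ffn_forward(params: Params, x: np.ndarray, n_layers: int,
                dropout: float, train: bool,
                rng: Optional[np.random.Generator]) -> Tuple[np.ndarray, dict]:
    cache = {"inputs": [], "masks": []}
    for l in range(n_layers):
        cache["inputs"].append(x)
        z = x @ params[f"F{l}_W"].T + params[f"F{l}_b"]
        if l == n_layers - 1:
            x = z
            cache["masks"].append(None)
        else:
            # dropout sits after the activation; inverted scaling
            mask = (z > 0).astype(float)
            if dropout > 0 and train:
                mask *= (rng.random(z.shape) >= dropout) / (1.0 - dropout)
            x = z * mask
            cache["masks"].append(mask)
    return x, cache


def ffn_backward(params: Params, cache: dict, dout: np.ndarray,
                 n_layers: int) -> Tuple[Params, np.ndarray]:
    grads: Params = {}
    d = dout
    for l in reversed(range(n_layers)):
        if cache["masks"][l] is not None:
            d = d * cache["masks"][l]
        x_in = cache["inputs"][l]
        grads[f"F{l}_W"] = d.T @ x_in
        grads[f"F{l}_b"] = d.sum(axis=0)
        d = d @ params[f"F{l}_W"]
    return grads, d


# ---------------------------------------------------------------------------
# D-MPNN network

@dataclass
class DMPNNetwork:
    """Encoder + FFN readout over batched reaction/molecule graphs."""

    enc_cfg: EncoderConfig
    atom_dim: int
    bond_dim: int
    ffn_layers: int = 2
    n_extra: int = 0
    out_dim: int = 1
    dropout: float = 0.0

    def init_params(self, rng: np.random.Generator) -> Params:
        from .encoder import init_encoder_weights

        params = init_encoder_weights(self.enc_cfg, self.atom_dim,
                                      self.bond_dim, rng)
        dims = ffn_dims(self.enc_cfg.hidden_size + self.n_extra,
                        self.enc_cfg.hidden_size, self.ffn_layers,
                        self.out_dim)
        params.update(init_ffn(dims, rng))
        return params

    def forward(self, params: Params, batch: BatchedGraph,
                train: bool = False,
                rng: Optional[np.random.Generator] = None
                ) -> Tuple[np.ndarray, dict]:
        cfg = self.enc_cfg
        h = cfg.hidden_size
        inp = np.concatenate([batch.atom_matrix[batch.edge_src],
                              batch.edge_matrix], axis=1)
        z0 = inp @ params["W_i"].T
        h0 = np.maximum(z0, 0.0)

        h_list = [h0]
        masks, msgs = [], []
        ht = h0
        for _ in range(cfg.depth):
            acc = np.zeros((batch.n_atoms, h))
            np.add.at(acc, batch.edge_tgt, ht)
            msg = acc[batch.edge_src] - ht[batch.rev_index]
            z = h0 + msg @ params["W_h"].T + params["b_h"]
            ht = np.maximum(z, 0.0)
            masks.append((z > 0).astype(float))
            msgs.append(msg)
            h_list.append(ht)

        acc_atoms = np.zeros((batch.n_atoms, h))
        np.add.at(acc_atoms, batch.edge_tgt, ht)
        cat_atoms = np.concatenate([batch.atom_matrix, acc_atoms], axis=1)
        za = cat_atoms @ params["W_o"].T + params["b_o"]
        atoms = np.maximum(za, 0.0)

        # segment mean/sum pooling
        emb = np.zeros((batch.n_graphs, h))
        np.add.at(emb, batch.graph_id, atoms)
        if cfg.aggregation == "mean":
            emb = emb / batch.atom_counts[:, None]
        x = emb
        if batch.extras is not None:
            x = np.concatenate([emb, batch.extras], axis=1)
        out, ffn_cache = ffn_forward(params, x, self.ffn_layers,
                                     self.dropout, train, rng)
        cache = {"inp": inp, "z0_mask": (z0 > 0).astype(float),
                 "masks": masks, "msgs": msgs, "h_list": h_list,
                 "cat_atoms": cat_atoms, "za_mask": (za > 0).astype(float),
                 "ffn": ffn_cache, "batch": batch}
        return out, cache

    def backward(self, params: Params, cache: dict,
                 dout: np.ndarray) -> Params:
        cfg = self.enc_cfg
        h = cfg.hidden_size
        batch: BatchedGraph = cache["batch"]

        grads, dx = ffn_backward(params, cache["ffn"], dout, self.ffn_layers)
        demb = dx[:, :h]
        if cfg.aggregation == "mean":
            demb = demb / batch.atom_counts[:, None]
        datoms = demb[batch.graph_id]

        ga = datoms * cache["za_mask"]
        grads["W_o"] = ga.T @ cache["cat_atoms"]
        grads["b_o"] = ga.sum(axis=0)
        dacc = (ga @ params["W_o"])[:, self.atom_dim:]
        dht = dacc[batch.edge_tgt]

        grads["W_h"] = np.zeros_like(params["W_h"])
        grads["b_h"] = np.zeros_like(params["b_h"])
        dh0 = np.zeros_like(dht)
        dh = dht
        for t in reversed(range(cfg.depth)):
            g = dh * cache["masks"][t]
            grads["W_h"] += g.T @ cache["msgs"][t]
            grads["b_h"] += g.sum(axis=0)
            dh0 += g
            dmsg = g @ params["W_h"]
            da = np.zeros((batch.n_atoms, h))
            np.add.at(da, batch.edge_src, dmsg)
            dh = da[batch.edge_tgt] - dmsg[batch.rev_index]
        dh0 += dh

        g0 = dh0 * cache["z0_mask"]
        grads["W_i"] = g0.T @ cache["inp"]
        return grads


@dataclass
class MLPNetwork:
    """FFN-only front end for precomputed fixed-length representations."""

    in_dim: int
    hidden: int = 300
    ffn_layers: int = 2
    out_dim: int = 1
    dropout: float = 0.0

    def init_params(self, rng: np.random.Generator) -> Params:
        return init_ffn(ffn_dims(self.in_dim, self.hidden, self.ffn_layers,
                                 self.out_dim), rng)

    def forward(self, params: Params, batch: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        return ffn_forward(params, batch, self.ffn_layers, self.dropout,
                           train, rng)

    def backward(self, params: Params, cache: dict,
                 dout: np.ndarray) -> Params:
        grads, _ = ffn_backward(params, cache, dout, self.ffn_layers)
        return grads


def n_parameters(params: Params) -> int:
    return int(sum(p.size for p in params.values()))


# ---------------------------------------------------------------------------
# losses

def mse_loss(pred: np.ndarray, target: np.ndarray,
             weights: Optional[np.ndarray] = None
             ) -> Tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. predictions."""
    diff = pred - target
    if weights is None:
        loss = float(np.mean(diff ** 2))
        grad = 2.0 * diff / diff.size
    else:
        w = weights[:, None]
        loss = float(np.sum(w * diff ** 2) / (np.sum(weights) * diff.shape[1]))
        grad = 2.0 * w * diff / (np.sum(weights) * diff.shape[1])
    return loss, grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray
                       ) -> Tuple[float, np.ndarray]:
    """Softmax cross-entropy; ``labels`` are integer class indices."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with the conventional defaults; learning rate passed per step."""

    def __init__(self, params: Params, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
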