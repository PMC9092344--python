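"""Baseline predictors: training-mean dummy and Morgan-fingerprint FFNs.

The dummy model predicts the training-target mean for every test reaction
and defines the floor any real model must beat (and the zero point of
R^2). The fingerprint models hash reactant and product sides separately
into count-based Morgan fingerprints (radius 3, width 1024 by default) and
either subtract ("diff") or concatenate ("concat") them; the resulting
vectors feed the same feed-forward readout and training loop as the graph
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator

from .model import TargetScaler, TrainConfig, evaluate, run_training
from .nn import MLPNetwork, Params, softmax
from .rxn_graph import ReactionRecord, strip_atom_maps


def dummy_mean_predict(train_targets: np.ndarray, test_size: int) -> np.ndarray:
    """Constant prediction equal to the training mean."""
    train_targets = np.asarray(train_targets, dtype=float)
    if train_targets.size == 0:
        raise ValueError("empty training targets")
    mean = train_targets.reshape(len(train_targets), -1).mean(axis=0)
    return np.tile(mean, (test_size, 1)).squeeze()


@dataclass
class FingerprintSpec:
    """Morgan fingerprint settings for reaction representations."""

    radius: int = 3
    width: int = 1024
    variant: str = "diff"      # or "concat"

    def __post_init__(self):
        if self.width < 1 or self.radius < 0:
            raise ValueError("width must be >= 1 and radius >= 0")
        if self.variant not in ("diff", "concat"):
            raise ValueError("variant must be 'diff' or 'concat'")

    @property
    def length(self) -> int:
        return self.width if self.variant == "diff" else 2 * self.width


def _side_counts(mol, spec: FingerprintSpec) -> np.ndarray:
    """Summed count fingerprint of one (possibly multi-molecule) side.

    Atom maps are stripped first so the hash does not encode the mapping.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius,
                                                    fpSize=spec.width)
    vec = np.zeros(spec.width)
    fp = gen.GetCountFingerprint(strip_atom_maps(mol))
    for bit, count in fp.GetNonzeroElements().items():
        vec[bit] += count
    return vec


def morgan_reaction_fingerprint(record: ReactionRecord,
                                spec: Optional[FingerprintSpec] = None
                                ) -> np.ndarray:
    """Count-based reaction fingerprint: product-minus-reactant difference
    or reactant/product concatenation."""
    spec = spec or FingerprintSpec()
    reac = _side_counts(record.reactant, spec)
    prod = _side_counts(record.product, spec)
    if spec.variant == "diff":
        return prod - reac
    return np.concatenate([reac, prod])


class FingerprintModel:
    """FFN on Morgan reaction fingerprints; same readout/training path as
    the graph model, different front end."""

    def __init__(self, records: Sequence[ReactionRecord],
                 spec: Optional[FingerprintSpec] = None,
                 task: str = "regression", hidden: int = 300,
                 ffn_layers: int = 2, dropout: float = 0.0):
        self.records = list(records)
        self.spec = spec or FingerprintSpec()
        self.task = task
        self.X = np.stack([morgan_reaction_fingerprint(r, self.spec)
                           for r in self.records])
        if task == "multiclass":
            labels = [np.asarray(r.targets).ravel()[0] for r in self.records]
            self.label_map: Optional[Dict[object, int]] = {}
            for lab in labels:
                if lab not in self.label_map:
                    self.label_map[lab] = len(self.label_map)
            self.targets = np.array([self.label_map[l] for l in labels])
            out_dim = len(self.label_map)
        else:
            self.label_map = None
            self.targets = np.stack([np.atleast_1d(np.asarray(r.targets,
                                                              dtype=float))
                                     for r in self.records])
            out_dim = self.targets.shape[1]
        self.net = MLPNetwork(in_dim=self.spec.length, hidden=hidden,
                              ffn_layers=ffn_layers, out_dim=out_dim,
                              dropout=dropout)

    def fit(self, train_idx: Optional[Sequence[int]] = None,
            val_idx: Optional[Sequence[int]] = None,
            train_config: Optional[TrainConfig] = None,
            **overrides) -> "FingerprintFitResult":
        tcfg = train_config or TrainConfig(**overrides)
        train_idx = (np.arange(len(self.records)) if train_idx is None
                     else np.asarray(train_idx, dtype=int))
        val_idx = (train_idx if val_idx is None
                   else np.asarray(val_idx, dtype=int))
        rng = np.random.default_rng(tcfg.seed)
        params = self.net.init_params(rng)
        if self.task == "regression":
            scaler = TargetScaler.fit(self.targets[train_idx])
            y = scaler.transform(self.targets)
        else:
            scaler = None
            y = self.targets
        batch = tcfg.batch_size
        steps_per_epoch = max(1, int(np.ceil(len(train_idx) / batch)))

        def batches(epoch_rng):
            order = epoch_rng.permutation(len(train_idx))
            out = []
            for s in range(0, len(order), batch):
                idx = train_idx[order[s:s + batch]]
                out.append((self.X[idx], y[idx], None))
            return out

        def val_metric(p: Params) -> float:
            out, _ = self.net.forward(p, self.X[val_idx])
            if self.task == "regression":
                pred = scaler.inverse(out)
                return float(np.mean(np.abs(pred - self.targets[val_idx])))
            return float(np.mean(out.argmax(axis=1) == self.targets[val_idx]))

        best, history, best_epoch = run_training(
            self.net, params, batches, self.task, tcfg, val_metric,
            self.task == "regression", steps_per_epoch, rng)
        return FingerprintFitResult(model=self, params=best, history=history,
                                    best_epoch=best_epoch, scaler=scaler)


@dataclass
class FingerprintFitResult:
    model: FingerprintModel
    params: Params
    history: pd.DataFrame
    best_epoch: int
    scaler: Optional[TargetScaler]

    def predict_indices(self, idx: Sequence[int]) -> np.ndarray:
        out, _ = self.model.net.forward(self.params,
                                        self.model.X[np.asarray(idx, int)])
        if self.model.task == "regression":
            return self.scaler.inverse(out)
        return softmax(out)

    def evaluate_indices(self, idx: Sequence[int], k: int = 3):
        idx = np.asarray(idx, dtype=int)
        return evaluate(self.predict_indices(idx), self.model.targets[idx],
                        self.model.task, k=k)
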