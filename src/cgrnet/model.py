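"""Reaction-property model: encoder + feed-forward readout, fit/predict.

The public surface follows the model/results convention: build a
:class:`ReactionPropertyModel` from parsed records or a DataFrame, call
:meth:`~ReactionPropertyModel.fit` to train, and work with the returned
:class:`FitResult` (predictions, metrics, summary table, checkpointing,
warm-started fine-tuning).

Training uses Adam with the warmup/decay schedule of :func:`lr_at_step`:
the learning rate climbs linearly from ``lr_init`` to ``lr_max`` over the
first two epochs, then decays exponentially to ``lr_final`` by the last
step. Regression targets are standardized on the training partition and
predictions are mapped back; the checkpoint with the best validation
metric (MAE for regression, accuracy for classification) is returned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from . import featurizer as ft
from .encoder import BatchedGraph, EncoderConfig, batch_graphs
from .nn import (Adam, DMPNNetwork, MLPNetwork, Params, cross_entropy_loss,
                 mse_loss, n_parameters, softmax)
from .rxn_graph import ReactionRecord, parse_reaction

TASKS = ("regression", "multiclass")


@dataclass
class ModelConfig:
    """Architecture and task settings.

    ``out_dim`` is the number of regression targets or classes; it is
    filled in from the data when left at 0.
    """

    task: str = "regression"
    out_dim: int = 0
    hidden_size: int = 300
    depth: int = 3
    ffn_layers: int = 2
    dropout: float = 0.0
    aggregation: str = "mean"
    rxn_mode: str = "reac_diff"
    imbalance_mode: str = "zero"
    target_scaling: str = "standardize"   # regression only; or "none"

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.task == "multiclass" and self.out_dim == 1:
            raise ValueError("multiclass requires out_dim >= 2")
        if self.out_dim < 0:
            raise ValueError("out_dim must be >= 1")

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(hidden_size=self.hidden_size, depth=self.depth,
                             aggregation=self.aggregation)


@dataclass
class TrainConfig:
    """Optimization settings (batch size 50 and the 1e-4/1e-3/1e-4
    learning-rate trajectory are the defaults used throughout)."""

    batch_size: int = 50
    epochs: int = 30
    warmup_epochs: float = 2.0
    lr_init: float = 1e-4
    lr_max: float = 1e-3
    lr_final: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.lr_init > self.lr_max or self.lr_final > self.lr_max:
            raise ValueError("lr_init and lr_final must not exceed lr_max")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def lr_at_step(cfg: TrainConfig, step: int, steps_per_epoch: int,
               total_steps: int) -> float:
    """Learning rate at a global optimizer step.

    Linear warmup from ``lr_init`` to ``lr_max`` across the warmup epochs,
    then exponential decay with a per-step factor chosen so that the final
    step lands exactly on ``lr_final``.
    """
    warmup_steps = cfg.warmup_epochs * steps_per_epoch
    if total_steps <= warmup_steps:
        raise ValueError("total_steps must exceed the warmup steps")
    if step < warmup_steps:
        return cfg.lr_init + (cfg.lr_max - cfg.lr_init) * step / warmup_steps
    frac = (step - warmup_steps) / (total_steps - warmup_steps)
    return cfg.lr_max * (cfg.lr_final / cfg.lr_max) ** frac


# ---------------------------------------------------------------------------
# metrics

def regression_metrics(predictions: np.ndarray, targets: np.ndarray) -> Dict[str, float]:
    predictions = np.asarray(predictions, dtype=float).reshape(len(predictions), -1)
    targets = np.asarray(targets, dtype=float).reshape(len(targets), -1)
    return {
        "mae": float(mean_absolute_error(targets, predictions)),
        "rmse": float(np.sqrt(mean_squared_error(targets, predictions))),
        "r2": float(r2_score(targets.ravel(), predictions.ravel())),
    }


def topk_accuracy(probabilities: np.ndarray, labels: np.ndarray,
                  k: int) -> float:
    """Fraction of rows whose true class is among the k highest scores."""
    probabilities = np.asarray(probabilities, dtype=float)
    if k > probabilities.shape[1]:
        raise ValueError(f"k={k} exceeds the number of classes "
                         f"({probabilities.shape[1]})")
    topk = np.argsort(-probabilities, axis=1, kind="stable")[:, :k]
    return float(np.mean([labels[i] in topk[i] for i in range(len(labels))]))


def evaluate(predictions: np.ndarray, targets: np.ndarray, task: str,
             k: int = 3) -> Dict[str, float]:
    """Task-appropriate metric set.

    Regression: MAE, RMSE, R^2. Multiclass: top-1 and top-k accuracy
    (``predictions`` are per-class scores, ``targets`` integer labels).
    """
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets differ in length")
    if task == "regression":
        return regression_metrics(predictions, targets)
    if task == "multiclass":
        labels = np.asarray(targets)
        return {"top1": topk_accuracy(predictions, labels, 1),
                f"top{k}": topk_accuracy(predictions, labels, k)}
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# target scaling

@dataclass
class TargetScaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, y: np.ndarray) -> "TargetScaler":
        mean = y.mean(axis=0)
        std = y.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean=mean, std=std)

    @classmethod
    def identity(cls, k: int) -> "TargetScaler":
        return cls(mean=np.zeros(k), std=np.ones(k))

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.std

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return y * self.std + self.mean


# ---------------------------------------------------------------------------
# generic training loop (shared by graph and fingerprint front ends)

def run_training(net, params: Params, batches: Callable[[np.random.Generator], list],
                 task: str, tcfg: TrainConfig,
                 val_metric: Callable[[Params], float],
                 minimize: bool, steps_per_epoch: int,
                 rng: np.random.Generator) -> Tuple[Params, pd.DataFrame, int]:
    """Adam + LR schedule + best-validation-checkpoint selection.

    ``batches(rng)`` yields one epoch of ``(input, target, weights)``
    triples; ``val_metric`` scores a parameter set on the validation
    partition. Returns the best parameters, the per-epoch history and the
    index of the best epoch.
    """
    optimizer = Adam(params)
    total_steps = tcfg.epochs * steps_per_epoch
    history = []
    best_params = {k: v.copy() for k, v in params.items()}
    best_metric = None
    best_epoch = -1
    step = 0
    for epoch in range(tcfg.epochs):
        losses = []
        for batch_in, target, wts in batches(rng):
            out, cache = net.forward(params, batch_in, train=True, rng=rng)
            if task == "regression":
                loss, dout = mse_loss(out, target, wts)
            else:
                loss, dout = cross_entropy_loss(out, target)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}; "
                    "inspect the learning rate and input features")
            grads = net.backward(params, cache, dout)
            optimizer.step(params, grads,
                           lr_at_step(tcfg, step, steps_per_epoch, total_steps))
            step += 1
            losses.append(loss)
        metric = val_metric(params)
        improved = (best_metric is None
                    or (metric < best_metric if minimize else metric > best_metric))
        if improved:
            best_metric = metric
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_metric": metric,
                        "lr": lr_at_step(tcfg, step, steps_per_epoch,
                                         total_steps)})
    return best_params, pd.DataFrame(history), best_epoch


# ---------------------------------------------------------------------------
# the model object

class ReactionPropertyModel:
    """A reaction-property predictor built from atom-mapped reactions.

    Parameters
    ----------
    records : sequence of ReactionRecord
        Parsed reactions. Regression targets are taken from
        ``record.targets``; multiclass labels may be any hashable values
        and are encoded in first-seen order.
    config : ModelConfig, optional
        Architecture/task settings; keyword overrides are accepted too.
    """

    def __init__(self, records: Sequence[ReactionRecord],
                 config: Optional[ModelConfig] = None, **overrides):
        if not records:
            raise ValueError("no records provided")
        if config is None:
            config = ModelConfig(**overrides)
        elif overrides:
            config = ModelConfig(**{**asdict(config), **overrides})
        self.records = list(records)
        self.config = config
        self.label_map: Optional[Dict[object, int]] = None
        self._graphs: List[Optional[ft.FeaturizedGraph]] = \
            [None] * len(self.records)

        if config.task == "multiclass":
            labels = [self._scalar_target(r) for r in self.records]
            self.label_map = {}
            for lab in labels:
                if lab not in self.label_map:
                    self.label_map[lab] = len(self.label_map)
            if len(self.label_map) < 2:
                raise ValueError("multiclass data must contain >= 2 classes")
            if config.out_dim == 0:
                config.out_dim = len(self.label_map)
            elif config.out_dim < len(self.label_map):
                raise ValueError("out_dim smaller than the number of classes")
            self.targets = np.array([self.label_map[l] for l in labels])
        else:
            ys = [np.atleast_1d(np.asarray(r.targets, dtype=float))
                  for r in self.records]
            widths = {len(y) for y in ys}
            if len(widths) != 1:
                raise ValueError("inconsistent target lengths across records")
            self.targets = np.stack(ys)
            if config.out_dim != self.targets.shape[1]:
                config.out_dim = self.targets.shape[1]

        extras = [r.extra_features for r in self.records]
        if any(e is not None for e in extras):
            if any(e is None for e in extras):
                raise ValueError("extra features must be present on all "
                                 "records or none")
            self.n_extra = len(np.asarray(extras[0]).ravel())
        else:
            self.n_extra = 0

    @staticmethod
    def _scalar_target(record: ReactionRecord):
        t = record.targets
        if isinstance(t, np.ndarray) and t.size == 1:
            return t.item()
        if isinstance(t, (list, tuple)) and len(t) == 1:
            return t[0]
        return t

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, reaction_column: str = "smiles",
                       target_columns: Optional[Sequence[str]] = None,
                       features: Optional[np.ndarray] = None,
                       keep_explicit_h: bool = False,
                       config: Optional[ModelConfig] = None,
                       **overrides) -> "ReactionPropertyModel":
        """Build the model from a reaction-SMILES DataFrame.

        ``features`` is an optional row-aligned matrix of per-reaction
        descriptors appended to the embedding before the readout.
        """
        if reaction_column not in df.columns:
            raise ValueError(f"missing reaction column {reaction_column!r}")
        if target_columns is None:
            target_columns = [c for c in df.columns if c != reaction_column]
        if features is not None:
            features = np.asarray(features, dtype=float)
            if len(features) != len(df):
                raise ValueError("feature matrix and dataframe row counts "
                                 "differ")
        cfg = config or ModelConfig(**overrides)
        records = []
        for i, (_, row) in enumerate(df.iterrows()):
            rec = parse_reaction(str(row[reaction_column]),
                                 keep_explicit_h=keep_explicit_h)
            if cfg.task == "multiclass":
                rec.targets = np.array([row[target_columns[0]]], dtype=object)
            else:
                rec.targets = np.array([float(row[c]) for c in target_columns])
            if features is not None:
                rec.extra_features = features[i]
            records.append(rec)
        return cls(records, config=cfg)

    # -- featurization ------------------------------------------------------

    def graph(self, i: int) -> ft.FeaturizedGraph:
        if self._graphs[i] is None:
            from .rxn_graph import build_cgr
            rec = self.records[i]
            extra = (np.asarray(rec.extra_features, dtype=float).ravel()
                     if rec.extra_features is not None else None)
            self._graphs[i] = ft.featurize_cgr(
                build_cgr(rec), mode=self.config.rxn_mode,
                imbalance_mode=self.config.imbalance_mode,
                extra_features=extra)
        return self._graphs[i]

    def _batch(self, idx: Sequence[int]) -> BatchedGraph:
        return batch_graphs([self.graph(i) for i in idx])

    def network(self) -> DMPNNetwork:
        return DMPNNetwork(
            enc_cfg=self.config.encoder_config(),
            atom_dim=ft.RXN_ATOM_FDIM, bond_dim=ft.RXN_BOND_FDIM,
            ffn_layers=self.config.ffn_layers, n_extra=self.n_extra,
            out_dim=self.config.out_dim, dropout=self.config.dropout)

    def n_parameters(self) -> int:
        rng = np.random.default_rng(0)
        return n_parameters(self.network().init_params(rng))

    # -- fitting ------------------------------------------------------------

    def fit(self, train_idx: Optional[Sequence[int]] = None,
            val_idx: Optional[Sequence[int]] = None,
            train_config: Optional[TrainConfig] = None,
            init_params: Optional[Union[Params, "FitResult", str]] = None,
            **overrides) -> "FitResult":
        """Train and return the best-validation checkpoint as a FitResult.

        With no explicit partitions, all records train and also validate
        (useful for overfit checks only). ``init_params`` warm-starts from
        an earlier result or checkpoint file for pretraining/fine-tuning.
        """
        tcfg = train_config or TrainConfig(**overrides)
        if train_config is not None and overrides:
            tcfg = TrainConfig(**{**asdict(train_config), **overrides})
        train_idx = (np.arange(len(self.records)) if train_idx is None
                     else np.asarray(train_idx, dtype=int))
        val_idx = (train_idx if val_idx is None
                   else np.asarray(val_idx, dtype=int))
        if len(train_idx) == 0 or len(val_idx) == 0:
            raise ValueError("empty train or validation partition")

        rng = np.random.default_rng(tcfg.seed)
        net = self.network()
        if init_params is None:
            params = net.init_params(rng)
        else:
            source = init_params
            if isinstance(source, str):
                source = FitResult.load(source)
            if isinstance(source, FitResult):
                source = source.params
            params = {k: v.copy() for k, v in source.items()}

        if self.config.task == "regression":
            if self.config.target_scaling == "standardize":
                scaler = TargetScaler.fit(self.targets[train_idx])
            else:
                scaler = TargetScaler.identity(self.targets.shape[1])
            y_scaled = scaler.transform(self.targets)
        else:
            scaler = None
            y_scaled = self.targets

        weights = np.array([r.weight for r in self.records], dtype=float)
        batch = tcfg.batch_size
        steps_per_epoch = max(1, int(np.ceil(len(train_idx) / batch)))

        def batches(epoch_rng: np.random.Generator):
            order = epoch_rng.permutation(len(train_idx))
            out = []
            for s in range(0, len(order), batch):
                idx = train_idx[order[s:s + batch]]
                out.append((self._batch(idx), y_scaled[idx], weights[idx]))
            return out

        val_batch = self._batch(val_idx)

        def val_metric(p: Params) -> float:
            out, _ = net.forward(p, val_batch)
            if self.config.task == "regression":
                pred = scaler.inverse(out)
                return float(mean_absolute_error(self.targets[val_idx], pred))
            pred = out.argmax(axis=1)
            return float(np.mean(pred == self.targets[val_idx]))

        minimize = self.config.task == "regression"
        best_params, history, best_epoch = run_training(
            net, params, batches, self.config.task, tcfg, val_metric,
            minimize, steps_per_epoch, rng)
        return FitResult(model=self, params=best_params, history=history,
                         best_epoch=best_epoch, scaler=scaler,
                         label_map=self.label_map, train_config=tcfg,
                         train_idx=train_idx, val_idx=val_idx)


@dataclass
class FitResult:
    """A trained reaction-property model and its training record."""

    model: Optional[ReactionPropertyModel]
    params: Params
    history: pd.DataFrame
    best_epoch: int
    scaler: Optional[TargetScaler]
    label_map: Optional[Dict[object, int]]
    train_config: Optional[TrainConfig] = None
    train_idx: Optional[np.ndarray] = None
    val_idx: Optional[np.ndarray] = None
    _config: Optional[ModelConfig] = None
    _n_extra: int = 0

    @property
    def config(self) -> ModelConfig:
        return self.model.config if self.model is not None else self._config

    @property
    def n_extra(self) -> int:
        return self.model.n_extra if self.model is not None else self._n_extra

    def network(self) -> DMPNNetwork:
        cfg = self.config
        return DMPNNetwork(
            enc_cfg=cfg.encoder_config(), atom_dim=ft.RXN_ATOM_FDIM,
            bond_dim=ft.RXN_BOND_FDIM, ffn_layers=cfg.ffn_layers,
            n_extra=self.n_extra, out_dim=cfg.out_dim, dropout=cfg.dropout)

    # -- prediction ---------------------------------------------------------

    def _predict_graphs(self, graphs: List[ft.FeaturizedGraph]) -> np.ndarray:
        net = self.network()
        outs = []
        for s in range(0, len(graphs), 50):
            out, _ = net.forward(self.params, batch_graphs(graphs[s:s + 50]))
            outs.append(out)
        return np.concatenate(outs, axis=0)

    def predict_indices(self, idx: Sequence[int]) -> np.ndarray:
        """Raw predictions for records held by the model (de-standardized
        values for regression, class probabilities for multiclass)."""
        graphs = [self.model.graph(i) for i in np.asarray(idx, dtype=int)]
        out = self._predict_graphs(graphs)
        if self.config.task == "regression":
            return self.scaler.inverse(out)
        return softmax(out)

    def predict(self, data: Union[pd.DataFrame, Sequence],
                reaction_column: str = "smiles",
                features: Optional[np.ndarray] = None,
                keep_explicit_h: bool = False) -> pd.DataFrame:
        """Predict for new reactions (DataFrame, SMILES strings or records).

        Rows whose reaction fails to parse or featurize are flagged
        ``valid=False`` with NaN predictions; other rows are unaffected.
        Output row order matches input order.
        """
        from .rxn_graph import build_cgr

        if isinstance(data, pd.DataFrame):
            items: Sequence = data[reaction_column].tolist()
        else:
            items = list(data)
        cfg = self.config
        graphs, valid = [], []
        for i, item in enumerate(items):
            try:
                rec = (item if isinstance(item, ReactionRecord)
                       else parse_reaction(str(item),
                                           keep_explicit_h=keep_explicit_h))
                extra = None
                if features is not None:
                    extra = np.asarray(features[i], dtype=float).ravel()
                elif isinstance(item, ReactionRecord) \
                        and item.extra_features is not None:
                    extra = np.asarray(item.extra_features, dtype=float).ravel()
                graphs.append(ft.featurize_cgr(
                    build_cgr(rec), mode=cfg.rxn_mode,
                    imbalance_mode=cfg.imbalance_mode, extra_features=extra))
                valid.append(True)
            except Exception as exc:  # noqa: BLE001 -- flag and continue
                warnings.warn(f"row {i}: {exc}")
                graphs.append(None)
                valid.append(False)
        ok = [g for g in graphs if g is not None]
        out = self._predict_graphs(ok) if ok else np.zeros((0, cfg.out_dim))
        if cfg.task == "regression":
            out = self.scaler.inverse(out)
            cols = [f"pred_{i}" for i in range(cfg.out_dim)]
        else:
            out = softmax(out)
            inv = {v: k for k, v in self.label_map.items()}
            cols = [f"prob_{inv[i]}" for i in range(cfg.out_dim)]
        table = np.full((len(items), cfg.out_dim), np.nan)
        table[np.asarray(valid, dtype=bool)] = out
        result = pd.DataFrame(table, columns=cols)
        result.insert(0, "valid", valid)
        if cfg.task == "multiclass":
            labels = [inv[int(np.argmax(row))] if v else None
                      for v, row in zip(valid, table)]
            result["pred_label"] = labels
        return result

    # -- evaluation ---------------------------------------------------------

    def evaluate_indices(self, idx: Sequence[int], k: int = 3) -> Dict[str, float]:
        idx = np.asarray(idx, dtype=int)
        pred = self.predict_indices(idx)
        return evaluate(pred, self.model.targets[idx], self.config.task, k=k)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        cfg = self.config
        lines = [
            "Reaction property model (condensed graph of reaction, D-MPNN)",
            "=" * 62,
            f"task: {cfg.task:<22} targets/classes: {cfg.out_dim}",
            f"hidden size: {cfg.hidden_size:<15} message passing depth: {cfg.depth}",
            f"ffn layers: {cfg.ffn_layers:<16} dropout: {cfg.dropout}",
            f"reaction mode: {cfg.rxn_mode:<13} imbalance mode: {cfg.imbalance_mode}",
            f"extra descriptors: {self.n_extra:<9} "
            f"trainable parameters: {n_parameters(self.params):,}",
        ]
        if self.train_idx is not None:
            lines.append(f"train size: {len(self.train_idx):<16} "
                         f"validation size: {len(self.val_idx)}")
        if len(self.history):
            best = self.history.iloc[self.best_epoch]
            name = "val MAE" if cfg.task == "regression" else "val accuracy"
            lines.append(f"best epoch: {self.best_epoch:<16} "
                         f"{name}: {best['val_metric']:.6g}")
            lines.append(f"final train loss: {self.history['train_loss'].iloc[-1]:.6g}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint: weights, configs, target scaler and label map."""
        cfg = self.config
        meta = {
            "model_config": asdict(cfg),
            "n_extra": self.n_extra,
            "best_epoch": int(self.best_epoch),
            "scaler": (None if self.scaler is None else
                       {"mean": self.scaler.mean.tolist(),
                        "std": self.scaler.std.tolist()}),
            "label_map": (None if self.label_map is None else
                          {str(k): v for k, v in self.label_map.items()}),
            "history": self.history.to_dict(orient="list"),
        }
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "FitResult":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        params = {k[len("param::"):]: data[k] for k in data.files
                  if k.startswith("param::")}
        scaler = None
        if meta["scaler"] is not None:
            scaler = TargetScaler(mean=np.array(meta["scaler"]["mean"]),
                                  std=np.array(meta["scaler"]["std"]))
        label_map = meta["label_map"]
        return cls(model=None, params=params,
                   history=pd.DataFrame(meta["history"]),
                   best_epoch=meta["best_epoch"], scaler=scaler,
                   label_map=label_map,
                   _config=ModelConfig(**meta["model_config"]),
                   _n_extra=meta["n_extra"])


def cross_validate(df: pd.DataFrame, split_spec, n_folds: int = 5,
                   reaction_column: str = "smiles",
                   target_columns: Optional[Sequence[str]] = None,
                   features: Optional[np.ndarray] = None,
                   keep_explicit_h: bool = False,
                   config: Optional[ModelConfig] = None,
                   train_config: Optional[TrainConfig] = None,
                   k: int = 3) -> pd.DataFrame:
    """Five-fold protocol: independent splits/seeds, mean +/- sd reporting.

    Each fold re-splits the data with ``split_spec`` at seed
    ``split_spec.seed + fold`` and trains a fresh model at the matching
    training seed; the returned frame has one row per fold plus mean/std.
    """
    from dataclasses import replace as _replace
    from .splits import make_split

    model = ReactionPropertyModel.from_dataframe(
        df, reaction_column=reaction_column, target_columns=target_columns,
        features=features, keep_explicit_h=keep_explicit_h, config=config)
    tcfg = train_config or TrainConfig()
    rows = []
    for fold in range(n_folds):
        spec = _replace(split_spec, seed=split_spec.seed + fold)
        tr, va, te = make_split(model.records, spec)
        result = model.fit(train_idx=tr, val_idx=va,
                           train_config=_replace(tcfg, seed=tcfg.seed + fold))
        metrics = result.evaluate_indices(te, k=k)
        rows.append({"fold": fold, **metrics})
    frame = pd.DataFrame(rows).set_index("fold")
    frame.loc["mean"] = frame.mean()
    frame.loc["std"] = frame.iloc[:-1].std()
    return frame
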