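"""Optimisation: MSE loss, Adam, early stopping, grouped CV, grid search.

Training minimises mean squared error on ddG with Adam, monitors validation
RMSE (and Pearson r) after every epoch, and stops early once the monitored
metric has not improved for ``patience`` consecutive epochs, returning the
parameters of the best epoch.  Cross-validation folds partition *proteins*,
not records, so no wild-type sequence is seen in both a training and a
validation fold, and direct/inverse versions of a mutation always travel
together.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import network as net
from .autodiff import Tensor, mean_all, square, sub
from .evaluation import regression_metrics
from .graphs import GraphSample
from .network import GraphBatch, ModelConfig, ModelParams


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class TrainConfig:
    max_epochs: int = 20
    patience: int = 5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    folds: int = 5
    seed: int = 0
    monitor: str = "val_rmse"

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.monitor != "val_rmse":
            raise ValueError("only val_rmse monitoring is supported")


@dataclass
class FoldResult:
    fold: int
    best_epoch: int
    history: list[dict[str, float]] = field(default_factory=list)
    val_pred: np.ndarray | None = None
    val_obs: np.ndarray | None = None


def mse_loss(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    return float(np.mean((pred - obs) ** 2))


class Adam:
    """Standard Adam with bias correction."""

    def __init__(
        self,
        params: ModelParams,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            p.value -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class _Packed:
    wild: net.PackedGraph
    mut: net.PackedGraph
    ddg: float


def _pack_samples(samples: Sequence[GraphSample], cfg: ModelConfig) -> list[_Packed]:
    return [
        _Packed(net.pack_graph(s.wild, cfg), net.pack_graph(s.mut, cfg), s.ddg) for s in samples
    ]


def _build_batches(
    packed: Sequence[_Packed], order: np.ndarray, batch_size: int
) -> list[tuple[GraphBatch, GraphBatch, np.ndarray, np.ndarray]]:
    """Materialise disjoint-union minibatches once; reused across epochs."""
    out = []
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        bw = net.make_batch([packed[i].wild for i in idx])
        bm = net.make_batch([packed[i].mut for i in idx])
        y = np.array([packed[i].ddg for i in idx])[:, None]
        out.append((bw, bm, y, idx))
    return out


def _evaluate_batches(
    batches: Sequence[tuple[GraphBatch, GraphBatch, np.ndarray, np.ndarray]],
    n: int,
    params: ModelParams,
    cfg: ModelConfig,
) -> np.ndarray:
    preds = np.empty(n)
    for bw, bm, _, idx in batches:
        preds[idx] = net.forward_pairs(bw, bm, params, cfg).value[:, 0]
    return preds


def train(
    samples: Sequence[GraphSample],
    cfg: ModelConfig,
    tcfg: TrainConfig,
    val_samples: Sequence[GraphSample],
    params: ModelParams | None = None,
    fold: int = 0,
) -> tuple[ModelParams, FoldResult]:
    """Fit the network; returns parameters from the best validation epoch.

    Deterministic given (cfg.seed, tcfg.seed) — shuffling and dropout draw
    from their own seeded generator.
    """
    if not samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    in_dim = samples[0].wild.feature_dim
    if params is None:
        params = net.init_params(cfg, in_dim)
    packed = _pack_samples(samples, cfg)
    packed_val = _pack_samples(val_samples, cfg)
    y_val = np.array([s.ddg for s in val_samples])

    opt = Adam(params, lr=tcfg.learning_rate)
    rng = np.random.default_rng((tcfg.seed, cfg.seed, fold))
    result = FoldResult(fold=fold, best_epoch=-1)
    best_rmse = math.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0

    # minibatch composition is fixed by the seeded grouping below; only the
    # order in which batches are visited is reshuffled each epoch
    train_batches = _build_batches(packed, rng.permutation(len(packed)), tcfg.batch_size)
    val_batches = _build_batches(packed_val, np.arange(len(packed_val)), 256)
    y_train = np.array([p.ddg for p in packed])

    for epoch in range(tcfg.max_epochs):
        epoch_loss = 0.0
        for b in rng.permutation(len(train_batches)):
            bw, bm, y, _ = train_batches[b]
            opt.zero_grad()
            masks = net.dropout_masks(cfg, y.shape[0], rng)
            pred = net.forward_pairs(bw, bm, params, cfg, masks=masks)
            loss = mean_all(square(sub(pred, Tensor(y))))
            if not np.isfinite(loss.value):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value) * y.shape[0]
        epoch_loss /= len(packed)

        train_pred = _evaluate_batches(train_batches, len(packed), params, cfg)
        tr = regression_metrics(train_pred, y_train)
        val_pred = _evaluate_batches(val_batches, len(packed_val), params, cfg)
        va = regression_metrics(val_pred, y_val)
        result.history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss,
                "train_pcc": tr.pcc,
                "train_rmse": tr.rmse,
                "val_pcc": va.pcc,
                "val_rmse": va.rmse,
            }
        )
        if va.rmse < best_rmse:
            best_rmse = va.rmse
            best_state = {k: p.value.copy() for k, p in params.items()}
            result.best_epoch = epoch
            result.val_pred = val_pred
            stale = 0
        else:
            stale += 1
            if stale >= tcfg.patience:
                break

    assert best_state is not None
    for k, p in params.items():
        p.value = best_state[k]
    result.val_obs = y_val
    return params, result


def assign_folds(protein_ids: Sequence[str], folds: int, seed: int) -> dict[str, int]:
    """Deterministic protein -> fold assignment (shuffle of sorted unique ids)."""
    unique = sorted(set(protein_ids))
    if len(unique) < folds:
        raise ValueError(f"need at least {folds} distinct proteins, got {len(unique)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    return {unique[i]: int(k % folds) for k, i in enumerate(perm)}


def cross_validate(
    samples: Sequence[GraphSample], cfg: ModelConfig, tcfg: TrainConfig
) -> tuple[list[FoldResult], dict[str, float]]:
    """Protein-grouped k-fold CV; returns per-fold results + pooled metrics.

    Direct and inverse versions of a mutation share a protein_id and are
    therefore always co-assigned, so the held-out antisymmetry assessment
    never leaks across folds.
    """
    fold_of = assign_folds([s.protein_id for s in samples], tcfg.folds, tcfg.seed)
    results: list[FoldResult] = []
    pooled_pred: list[np.ndarray] = []
    pooled_obs: list[np.ndarray] = []
    for k in range(tcfg.folds):
        train_set = [s for s in samples if fold_of[s.protein_id] != k]
        val_set = [s for s in samples if fold_of[s.protein_id] == k]
        if not val_set or not train_set:
            raise ValueError(f"fold {k} is empty; too few proteins for {tcfg.folds} folds")
        _, res = train(train_set, cfg, tcfg, val_set, fold=k)
        results.append(res)
        pooled_pred.append(res.val_pred)
        pooled_obs.append(res.val_obs)
    pooled = regression_metrics(np.concatenate(pooled_pred), np.concatenate(pooled_obs))
    mean_val_rmse = float(np.mean([r.history[r.best_epoch]["val_rmse"] for r in results]))
    mean_val_pcc = float(np.mean([r.history[r.best_epoch]["val_pcc"] for r in results]))
    summary = {
        "pooled_pcc": pooled.pcc,
        "pooled_rmse": pooled.rmse,
        "mean_val_rmse": mean_val_rmse,
        "mean_val_pcc": mean_val_pcc,
        "n": float(len(samples)),
    }
    return results, summary


def grid_search(
    samples: Sequence[GraphSample],
    grid: Mapping[str, Sequence],
    tcfg: TrainConfig,
    base_cfg: ModelConfig | None = None,
) -> tuple[ModelConfig, list[dict]]:
    """Exhaustive search over ModelConfig axes by cross-validated RMSE.

    Best = lowest mean validation RMSE; ties broken by higher mean validation
    PCC, then by enumeration order.  Returns the winning config and the full
    results table (one row per combination).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    base = base_cfg or ModelConfig()
    keys = list(grid)
    table: list[dict] = []
    best_cfg = None
    best_key: tuple[float, float, int] | None = None
    for order, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        cfg = replace(base, **dict(zip(keys, values)))
        _, summary = cross_validate(samples, cfg, tcfg)
        row = dict(zip(keys, values))
        row.update(summary)
        table.append(row)
        key = (summary["mean_val_rmse"], -summary["mean_val_pcc"], order)
        if best_key is None or key < best_key:
            best_key, best_cfg = key, cfg
    assert best_cfg is not None
    return best_cfg, table
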