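"""MIL losses, optimization loop, dataset splitting and evaluation.

The loss is a convex combination of the attention-weighted conformer-level
(instance) MSE and the molecule-level (bag) MSE:

    L = beta * L_ins + (1 - beta) * L_bag,   beta = 0.5 by default,

with L_ins = mean_n sum_m alpha_{n,m} (y_n - yhat_{n,m})^2 and L_bag the
plain MSE of the molecule-level predictions.  Attention coefficients are
normalized within each molecule, never across the batch.  Optimization uses
Adam (learning rate 0.001, otherwise standard defaults); model selection
keeps the parameters of the epoch with the best validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .autodiff import Tensor
from .errors import (
    EmptyBatchError,
    ShapeError,
    SplitError,
    TrainingDivergedError,
)
from .model import EquiVS, EquiVSConfig, ForwardResult, GraphBatch, make_batch
from .molgraph import MolecularGraph


@dataclass
class TrainConfig:
    lr: float = 0.001
    epochs: int = 200
    batch_size: int = 128
    beta: float = 0.5          # weight of the instance loss
    dropout: float = 0.05
    split_ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass
class EvalReport:
    r2: float | None
    mse: float
    mae: float


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# Losses (autodiff tensors; numpy arrays also accepted for direct evaluation)
# ---------------------------------------------------------------------------

def _lift(v) -> Tensor:
    return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))


def instance_loss(yGm, y, alpha) -> Tensor:
    """Attention-weighted conformer-level MSE.

    yGm: (N, M) conformer predictions; y: (N,) labels; alpha: (N, M) weights
    summing to 1 within each molecule.
    """
    yGm, y, alpha = _lift(yGm), _lift(y), _lift(alpha)
    if yGm.shape != alpha.shape or yGm.shape[0] != y.shape[0]:
        raise ShapeError(
            f"shape mismatch: yGm {yGm.shape}, alpha {alpha.shape}, y {y.shape}"
        )
    if yGm.shape[0] == 0:
        raise EmptyBatchError("instance loss on empty batch")
    resid = y.reshape(-1, 1) - yGm
    return (alpha * resid.square()).sum(axis=1).mean()


def bag_loss(yG, y) -> Tensor:
    """Molecule-level MSE."""
    yG, y = _lift(yG), _lift(y)
    if yG.shape != y.shape:
        raise ShapeError(f"shape mismatch: yG {yG.shape}, y {y.shape}")
    if yG.value.size == 0:
        raise EmptyBatchError("bag loss on empty batch")
    return (y - yG).square().mean()


def combined_loss(l_ins, l_bag, beta: float = 0.5) -> Tensor:
    """Convex combination beta * L_ins + (1 - beta) * L_bag."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    return _lift(l_ins) * beta + _lift(l_bag) * (1.0 - beta)


def batch_loss(out: ForwardResult, y: np.ndarray, beta: float) -> Tensor:
    """Total loss of a forward pass; uniform alpha when attention is absent."""
    l_bag = bag_loss(out.yG, Tensor(np.asarray(y, dtype=np.float32)))
    if beta == 0.0:
        return l_bag
    if out.alpha is not None:
        alpha = out.alpha
    else:  # no-attention variant: uniform weights inside the instance loss
        M = out.yGm.shape[1]
        alpha = Tensor(np.full(out.yGm.shape, 1.0 / M, dtype=np.float32))
    l_ins = instance_loss(out.yGm, Tensor(np.asarray(y, dtype=np.float32)), alpha)
    return combined_loss(l_ins, l_bag, beta)


# ---------------------------------------------------------------------------
# Splitting & evaluation
# ---------------------------------------------------------------------------

def split_dataset(items, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Random, seed-deterministic partition into train/valid/test.

    Accepts any sequence (records, graphs, indices) and returns three lists
    that are disjoint and exhaustive; valid/test sizes are rounded, train
    takes the remainder.
    """
    items = list(items)
    n = len(items)
    if n < 3:
        raise SplitError(f"need at least 3 records to split, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    order = np.random.default_rng(seed).permutation(n)
    n_valid = max(1, int(round(ratios[1] * n)))
    n_test = max(1, int(round(ratios[2] * n)))
    n_train = n - n_valid - n_test
    if n_train < 1:
        raise SplitError(f"split ratios leave no training records for n={n}")
    train = [items[i] for i in order[:n_train]]
    valid = [items[i] for i in order[n_train : n_train + n_valid]]
    test = [items[i] for i in order[n_train + n_valid :]]
    return train, valid, test


def evaluate(y_true, y_pred) -> EvalReport:
    """R^2 / MSE / MAE; R^2 is None (with a warning) for constant y_true."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ShapeError("y_true and y_pred must be equal-length and non-empty")
    mse = float(mean_squared_error(y_true, y_pred))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.ptp(y_true) == 0.0:
        import warnings

        warnings.warn("R^2 undefined for constant y_true; reporting None")
        return EvalReport(r2=None, mse=mse, mae=mae)
    return EvalReport(r2=float(r2_score(y_true, y_pred)), mse=mse, mae=mae)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam over a named parameter dict (in-place updates)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if g is None:
                continue
            g = g.astype(self.params[k].dtype, copy=False)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _epoch_loss(model: EquiVS, batches: list[GraphBatch], beta: float) -> float:
    total, n = 0.0, 0
    for batch in batches:
        out = model.forward(batch, train=False)
        total += float(batch_loss(out, batch.y, beta).value) * batch.B
        n += batch.B
    return total / max(n, 1)


def train(
    graphs: list[MolecularGraph],
    model_config: EquiVSConfig,
    train_config: TrainConfig,
    presplit: tuple[list, list, list] | None = None,
) -> tuple[EquiVS, EvalReport, TrainHistory]:
    """Train EquiVS on labeled molecular graphs.

    Splits 8:1:1 (unless `presplit` is given), runs Adam for the configured
    epochs with dropout active, tracks train/validation losses per epoch,
    restores the best-validation checkpoint, and evaluates molecule-level
    predictions on the held-out test set.
    """
    tc = train_config
    if presplit is not None:
        train_set, valid_set, test_set = presplit
    else:
        train_set, valid_set, test_set = split_dataset(
            graphs, tc.split_ratio, seed=tc.seed
        )
    model_config.dropout = tc.dropout
    model = EquiVS(model_config)
    M = model_config.n_conformers
    mode = model_config.coord_scale_mode
    valid_batches = [make_batch(valid_set, M, mode)]
    rng = np.random.default_rng(tc.seed + 1)
    opt = Adam(model.params, lr=tc.lr)
    history = TrainHistory()
    best_valid = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    indices = np.arange(len(train_set))
    beta = tc.beta if model_config.use_instance_predictor else 0.0

    for epoch in range(tc.epochs):
        rng.shuffle(indices)
        epoch_total, seen = 0.0, 0
        for start in range(0, len(indices), tc.batch_size):
            chunk = [train_set[i] for i in indices[start : start + tc.batch_size]]
            batch = make_batch(chunk, M, mode)
            out = model.forward(batch, train=True, rng=rng)
            loss = batch_loss(out, batch.y, beta)
            value = float(loss.value)
            if not np.isfinite(value):
                raise TrainingDivergedError(epoch)
            loss.backward()
            grads = {k: t.grad for k, t in out.param_tensors.items()}
            opt.step(grads)
            epoch_total += value * batch.B
            seen += batch.B
        history.train_loss.append(epoch_total / max(seen, 1))
        v_loss = _epoch_loss(model, valid_batches, beta)
        if not np.isfinite(v_loss):
            raise TrainingDivergedError(epoch)
        history.valid_loss.append(v_loss)
        if v_loss < best_valid:
            best_valid = v_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            history.best_epoch = epoch

    model.params = best_params
    preds = model.predict(test_set)
    y_true = np.array([g.label_y for g in test_set])
    y_pred = np.array([r.yG for r in preds])
    report = evaluate(y_true, y_pred)
    return model, report, history
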