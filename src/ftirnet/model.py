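"""The six-layer 1D convolutional binary classifier, in pure NumPy.

Architecture (fixed order): input (1,600 standardized absorbances) ->
1D convolution, 8 filters, kernel 12, ReLU, valid padding (length 1,589) ->
dropout 50 % -> max pooling, pool size 2 (length 794) -> flatten ->
dense 32, ReLU -> dense 1, sigmoid.  Trained with binary cross-entropy and
Adam; at each epoch accuracy is measured on the held-out test split and the
checkpoint with the highest test accuracy is kept (earliest epoch on ties).

All randomness (weight init, split shuffle, batch order, dropout masks)
derives from a single user seed, so training is bit-reproducible on one
thread.
"""

from __future__ import annotations

import copy
import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "PredictionSet",
    "layer_output_shapes",
    "build_model",
    "train",
    "predict_scores",
    "classify",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the six-layer network (defaults are the study's)."""

    input_dim: int = 1600
    conv_filters: int = 8
    conv_kernel: int = 12
    dropout_rate: float = 0.5
    pool_size: int = 2
    dense_units: int = 32
    output_units: int = 1
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.conv_kernel > self.input_dim:
            raise ValueError("conv_kernel must not exceed input_dim")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")

    @property
    def conv_len(self) -> int:
        return self.input_dim - self.conv_kernel + 1  # valid padding

    @property
    def pooled_len(self) -> int:
        return self.conv_len // self.pool_size  # trailing unpaired element dropped

    @property
    def flat_dim(self) -> int:
        return self.pooled_len * self.conv_filters


@dataclass(frozen=True)
class TrainConfig:
    train_fraction: float = 0.8
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def layer_output_shapes(cfg: ModelConfig) -> list[int]:
    """Per-layer output lengths: input, conv, dropout, pool, dense, output.

    Under the defaults: 1600 -> 1589 -> 1589 -> 794 -> 32 -> 1.
    """
    return [
        cfg.input_dim,
        cfg.conv_len,
        cfg.conv_len,
        cfg.pooled_len,
        cfg.dense_units,
        cfg.output_units,
    ]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _init_weights(cfg: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    k, f = cfg.conv_kernel, cfg.conv_filters
    return {
        "Wc": _glorot(rng, (k, f), k, f),
        "bc": np.zeros(f),
        "W1": _glorot(rng, (cfg.flat_dim, cfg.dense_units), cfg.flat_dim, cfg.dense_units),
        "b1": np.zeros(cfg.dense_units),
        "W2": _glorot(rng, (cfg.dense_units, cfg.output_units), cfg.dense_units, cfg.output_units),
        "b2": np.zeros(cfg.output_units),
    }


@dataclass
class TrainedModel:
    """Architecture + weights + training provenance."""

    config: ModelConfig
    weights: dict[str, np.ndarray]
    seed: int = 0
    best_epoch: int = -1
    best_test_accuracy: float = float("nan")
    training_log: list[dict] = field(default_factory=list)
    # row indices of the seeded train/test split, for downstream analyses
    train_indices: list[int] = field(default_factory=list)
    test_indices: list[int] = field(default_factory=list)


@dataclass
class PredictionSet:
    """Continuous scores in [0, 1] plus their thresholded binary labels."""

    sample_ids: list[str]
    scores: np.ndarray
    labels_pred: np.ndarray
    labels_true: np.ndarray | None = None


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> TrainedModel:
    """Instantiate the network with seeded Glorot-uniform weights (untrained)."""
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return TrainedModel(config=cfg, weights=_init_weights(cfg, rng), seed=seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(
    cfg: ModelConfig,
    w: dict[str, np.ndarray],
    X: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass; dropout is applied only when a dropout_rng is given
    (training mode).  Returns (scores, cache-for-backward)."""
    N = X.shape[0]
    # contiguous im2col so both the forward and the weight-gradient matmuls
    # hit BLAS instead of strided fallbacks
    windows = np.ascontiguousarray(
        sliding_window_view(X, cfg.conv_kernel, axis=1)
    )  # (N, Lc, k)
    z1 = (
        windows.reshape(-1, cfg.conv_kernel) @ w["Wc"]
    ).reshape(N, cfg.conv_len, cfg.conv_filters) + w["bc"]  # (N, Lc, F)
    a1 = np.maximum(z1, 0.0)
    if dropout_rng is not None and cfg.dropout_rate > 0:
        keep = dropout_rng.random(a1.shape, dtype=np.float32) >= cfg.dropout_rate
        d1 = a1 * keep / np.asarray(1.0 - cfg.dropout_rate, dtype=a1.dtype)
    else:
        keep = None
        d1 = a1
    Lp, ps = cfg.pooled_len, cfg.pool_size
    r = d1[:, : Lp * ps, :].reshape(N, Lp, ps, cfg.conv_filters)
    pool_arg = r.argmax(axis=2)  # (N, Lp, F)
    pooled = np.take_along_axis(r, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
    flat = pooled.reshape(N, cfg.flat_dim)
    z2 = flat @ w["W1"] + w["b1"]
    a2 = np.maximum(z2, 0.0)
    z3 = a2 @ w["W2"] + w["b2"]
    scores = _sigmoid(z3)[:, 0]
    cache = dict(
        windows=windows, z1=z1, keep=keep, pool_arg=pool_arg,
        flat=flat, z2=z2, a2=a2, scores=scores, N=N,
    )
    return scores, cache


def _backward(
    cfg: ModelConfig, w: dict[str, np.ndarray], cache: dict, y: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of mean binary cross-entropy w.r.t. all parameters."""
    N = cache["N"]
    # d(BCE)/dz3 for sigmoid output simplifies to (p - y) / N
    dz3 = ((cache["scores"] - y) / N)[:, None]  # (N, 1)
    dW2 = cache["a2"].T @ dz3
    db2 = dz3.sum(axis=0)
    da2 = dz3 @ w["W2"].T
    dz2 = da2 * (cache["z2"] > 0)
    dW1 = cache["flat"].T @ dz2
    db1 = dz2.sum(axis=0)
    dflat = dz2 @ w["W1"].T
    Lp, ps, F = cfg.pooled_len, cfg.pool_size, cfg.conv_filters
    dpooled = dflat.reshape(N, Lp, F)
    # route gradient to the argmax positions within each pool window
    dr = np.zeros((N, Lp, ps, F), dtype=dflat.dtype)
    np.put_along_axis(dr, cache["pool_arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
    dd1 = np.zeros((N, cfg.conv_len, F), dtype=dflat.dtype)
    dd1[:, : Lp * ps, :] = dr.reshape(N, Lp * ps, F)
    if cache["keep"] is not None:
        dd1 = dd1 * cache["keep"] / np.asarray(1.0 - cfg.dropout_rate, dtype=dflat.dtype)
    dz1 = dd1 * (cache["z1"] > 0)
    dWc = cache["windows"].reshape(-1, cfg.conv_kernel).T @ dz1.reshape(-1, F)
    dbc = dz1.sum(axis=(0, 1))
    return {"Wc": dWc, "bc": dbc, "W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bce(scores: np.ndarray, y: np.ndarray) -> float:
    # clip wide enough that 1 - eps is representable in float32
    eps = 1e-7
    p = np.clip(scores.astype(np.float64), eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _split_indices(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator, stratify: bool
) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    if stratify:
        train_idx, test_idx = [], []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            cut = int(round(len(idx) * train_fraction))
            train_idx.append(idx[:cut])
            test_idx.append(idx[cut:])
        tr = np.concatenate(train_idx)
        te = np.concatenate(test_idx)
        rng.shuffle(tr)
        rng.shuffle(te)
        return tr, te
    perm = rng.permutation(n)
    cut = int(round(n * train_fraction))
    return perm[:cut], perm[cut:]


def train(
    model: TrainedModel,
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    tc: TrainConfig | None = None,
) -> TrainedModel:
    """Train with Adam on binary cross-entropy, 80/20 seeded split.

    After each epoch, accuracy at the decision threshold is measured on the
    test split; the returned model carries the weights of the epoch with the
    highest test accuracy (earliest on ties) and the full per-epoch log.
    """
    tc = tc or TrainConfig()
    cfg = model.config
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[1] != cfg.input_dim:
        raise ValueError(f"features must be (n, {cfg.input_dim})")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary")

    ss = np.random.SeedSequence(tc.seed)
    split_rng, batch_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    tr, te = _split_indices(y.astype(int), tc.train_fraction, split_rng, tc.stratify)
    for name, idx in (("training", tr), ("test", te)):
        counts = np.bincount(y[idx].astype(int), minlength=2)
        if counts.min() < 2:
            raise ValueError(f"{name} split needs >= 2 samples of each class")
    # training runs in float32: halves memory traffic with no effect on the
    # thresholded test accuracy that drives checkpoint selection
    Xtr, ytr = X[tr].astype(np.float32), y[tr].astype(np.float32)
    Xte, yte = X[te].astype(np.float32), y[te]

    w = {k: v.astype(np.float32) for k, v in model.weights.items()}
    opt = _Adam(w, tc.learning_rate)
    best_acc, best_epoch, best_w = -1.0, -1, None
    log: list[dict] = []
    n_tr = len(tr)
    for epoch in range(tc.epochs):
        order = batch_rng.permutation(n_tr)
        losses = []
        for start in range(0, n_tr, tc.batch_size):
            b = order[start : start + tc.batch_size]
            scores, cache = _forward(cfg, w, Xtr[b], dropout_rng=drop_rng)
            losses.append(_bce(scores, ytr[b]) * len(b))
            grads = _backward(cfg, w, cache, ytr[b])
            opt.step(w, grads)
        te_scores, _ = _forward(cfg, w, Xte)
        te_acc = float(
            np.mean((te_scores >= cfg.decision_threshold).astype(int) == yte)
        )
        log.append(
            {"epoch": epoch, "train_loss": sum(losses) / n_tr, "test_accuracy": te_acc}
        )
        if te_acc > best_acc:
            best_acc, best_epoch = te_acc, epoch
            best_w = {k: v.copy() for k, v in w.items()}

    assert best_w is not None
    return TrainedModel(
        config=cfg,
        weights={k: v.astype(np.float64) for k, v in best_w.items()},
        seed=tc.seed,
        best_epoch=best_epoch,
        best_test_accuracy=best_acc,
        training_log=log,
        train_indices=[int(i) for i in tr],
        test_indices=[int(i) for i in te],
    )


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Deterministic scores in [0, 1] (dropout disabled)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"features must have {model.config.input_dim} columns, got {X.shape[1]}"
        )
    scores, _ = _forward(model.config, model.weights, X)
    return scores


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Round to a binary call: 1 iff score >= threshold (closed at the bound)."""
    return (np.asarray(scores) >= threshold).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist config + weights + training log to a single zip archive."""
    path = Path(path)
    buf = BytesIO()
    np.savez(buf, **model.weights)
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "best_epoch": model.best_epoch,
        "best_test_accuracy": model.best_test_accuracy,
        "training_log": model.training_log,
        "train_indices": model.train_indices,
        "test_indices": model.test_indices,
        "format_version": 1,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("weights.npz") as f:
            npz = np.load(BytesIO(f.read()))
            weights = {k: npz[k] for k in npz.files}
    return TrainedModel(
        config=ModelConfig(**meta["config"]),
        weights=weights,
        seed=meta["seed"],
        best_epoch=meta["best_epoch"],
        best_test_accuracy=meta["best_test_accuracy"],
        training_log=meta["training_log"],
        train_indices=meta.get("train_indices", []),
        test_indices=meta.get("test_indices", []),
    )
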