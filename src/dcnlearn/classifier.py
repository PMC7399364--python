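"""The standardized classifier whose averaged test confusions define
feature-learnability.

A single-hidden-layer pattern-recognition network: tanh hidden units
(42 by default), softmax output over the 16 stimulus classes,
cross-entropy loss, trained by full-batch gradient descent with momentum
and a multiplicative adaptive learning rate (the rate grows after
improving epochs and shrinks — with the step discarded — when the loss
overshoots).  Inputs are min–max normalized to [−1, 1] per column; rows
are split 70/15/15 into train/validation/test, and training stops early
once the validation loss fails to improve for ``patience`` consecutive
epochs (the best-validation weights are kept).

The network is deliberately simple and fully deterministic under a seed:
it is a measuring instrument, standardized across all experiments, not a
model to be tuned per feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import META_COLUMNS

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "ConfusionMatrix",
    "train",
    "predict",
    "select_hidden_size",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training hyperparameters of the standardized net."""

    n_hidden: int = 42
    split: tuple = (0.70, 0.15, 0.15)
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_perf_inc: float = 1.04  # loss-overshoot ratio that triggers lr decrease
    max_epochs: int = 1000
    patience: int = 6
    stratified: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized K x K confusion (rows true, columns predicted)."""

    matrix: np.ndarray
    labels: tuple

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def diagonal_mean(self) -> float:
        return float(np.mean(self.diagonal))


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, labels: Sequence[str]
) -> ConfusionMatrix:
    k = len(labels)
    index = {c: i for i, c in enumerate(labels)}
    mat = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1.0
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(sums > 0, mat / sums, 0.0)
    return ConfusionMatrix(mat, tuple(labels))


@dataclass
class TrainedModel:
    """Weights, normalization constants and training log of one fit."""

    spec: ClassifierSpec
    feature_cols: tuple
    classes: tuple
    col_min: np.ndarray
    col_max: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    seed: int
    history: dict = field(default_factory=dict)
    test_confusion: ConfusionMatrix | None = None


def _split_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, tuple]:
    feat_cols = tuple(c for c in table.columns if c not in META_COLUMNS)
    x = table[list(feat_cols)].to_numpy(dtype=float)
    y = table["condition"].to_numpy()
    return x, y, feat_cols


def _normalize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cmin = x.min(axis=0)
    cmax = x.max(axis=0)
    degenerate = cmax - cmin <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature column(s) mapped to 0",
            stacklevel=3,
        )
    return cmin, cmax


def _normalize_apply(x: np.ndarray, cmin: np.ndarray, cmax: np.ndarray) -> np.ndarray:
    rng = cmax - cmin
    out = np.zeros_like(x, dtype=float)
    ok = rng > 0
    out[:, ok] = 2.0 * (x[:, ok] - cmin[ok]) / rng[ok] - 1.0
    return np.clip(out, -1.0, 1.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(x, w1, b1, w2, b2) -> tuple[np.ndarray, np.ndarray]:
    h = np.tanh(x @ w1 + b1)
    return h, _softmax(h @ w2 + b2)


def _cross_entropy(p: np.ndarray, t_onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(t_onehot * np.log(p + 1e-12), axis=1)))


def _partition(
    n: int, split: tuple, rng: np.random.Generator, y: np.ndarray, stratified: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    def cut(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n_tr = int(round(split[0] * len(idx)))
        n_va = int(round(split[1] * len(idx)))
        return idx[:n_tr], idx[n_tr : n_tr + n_va], idx[n_tr + n_va :]

    if not stratified:
        return cut(rng.permutation(n))
    parts: list[list] = [[], [], []]
    for c in np.unique(y):
        tr, va, te = cut(rng.permutation(np.flatnonzero(y == c)))
        for part, chunk in zip(parts, (tr, va, te)):
            part.extend(chunk)
    return tuple(rng.permutation(np.array(p, dtype=int)) for p in parts)  # type: ignore[return-value]


def train(table: pd.DataFrame, spec: ClassifierSpec | None = None, seed: int = 0) -> TrainedModel:
    """Fit the standardized network on a feature table.

    The held-out test confusion (row-normalized) is attached to the
    returned model when the split reserves test rows.  Identical
    (table, spec, seed) yield an identical model.
    """
    if spec is None:
        spec = ClassifierSpec()
    x_raw, y, feat_cols = _split_table(table)
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if len(y) < 10 * len(classes):
        warnings.warn(
            f"{len(y)} rows for {len(classes)} classes; >= {10 * len(classes)} recommended",
            stacklevel=2,
        )

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5EED)))
    cmin, cmax = _normalize_fit(x_raw)
    x = _normalize_apply(x_raw, cmin, cmax)
    cls_index = {c: i for i, c in enumerate(classes)}
    t_onehot = np.zeros((len(y), len(classes)))
    t_onehot[np.arange(len(y)), [cls_index[c] for c in y]] = 1.0

    idx_tr, idx_va, idx_te = _partition(len(y), spec.split, rng, y, spec.stratified)
    if len(idx_tr) == 0:
        raise ValueError("empty training split")

    n_in, n_out = x.shape[1], len(classes)
    w1 = rng.uniform(-1, 1, (n_in, spec.n_hidden)) / np.sqrt(max(n_in, 1))
    b1 = np.zeros(spec.n_hidden)
    w2 = rng.uniform(-1, 1, (spec.n_hidden, n_out)) / np.sqrt(spec.n_hidden)
    b2 = np.zeros(n_out)
    params = [w1, b1, w2, b2]
    velocity = [np.zeros_like(p) for p in params]

    xtr, ttr = x[idx_tr], t_onehot[idx_tr]
    xva, tva = x[idx_va], t_onehot[idx_va]
    lr = spec.learning_rate
    prev_loss = np.inf
    best_val = np.inf
    best_params = [p.copy() for p in params]
    fails = 0
    train_trace: list[float] = []
    val_trace: list[float] = []

    for epoch in range(spec.max_epochs):
        h, p_out = _forward(xtr, *params)
        loss = _cross_entropy(p_out, ttr)

        if loss > prev_loss * spec.max_perf_inc:
            # Overshoot: discard the step that produced it, cool the rate.
            for p, v in zip(params, velocity):
                p -= v
                v[:] = 0.0
            lr *= spec.lr_dec
            h, p_out = _forward(xtr, *params)
            loss = _cross_entropy(p_out, ttr)
        elif loss < prev_loss:
            lr = min(lr * spec.lr_inc, 10.0)
        prev_loss = loss
        train_trace.append(loss)

        # Backprop (softmax + cross-entropy -> linear output delta).
        m = len(xtr)
        d_out = (p_out - ttr) / m
        g_w2 = h.T @ d_out
        g_b2 = d_out.sum(axis=0)
        d_hid = (d_out @ params[2].T) * (1.0 - h**2)
        g_w1 = xtr.T @ d_hid
        g_b1 = d_hid.sum(axis=0)
        for p, v, g in zip(params, velocity, [g_w1, g_b1, g_w2, g_b2]):
            v *= spec.momentum
            v -= lr * g
            p += v

        if len(idx_va):
            _, p_va = _forward(xva, *params)
            val_loss = _cross_entropy(p_va, tva)
            val_trace.append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                fails = 0
            else:
                fails += 1
                if fails >= spec.patience:
                    break
        else:
            best_params = [p.copy() for p in params]

    model = TrainedModel(
        spec=spec,
        feature_cols=feat_cols,
        classes=classes,
        col_min=cmin,
        col_max=cmax,
        w1=best_params[0],
        b1=best_params[1],
        w2=best_params[2],
        b2=best_params[3],
        seed=int(seed),
        history={
            "epochs": len(train_trace),
            "train_loss": train_trace,
            "val_loss": val_trace,
        },
    )

    if len(idx_te):
        _, labels = predict(model, x_raw[idx_te])
        model.test_confusion = confusion_from_predictions(y[idx_te], labels, classes)
    return model


def predict(model: TrainedModel, rows) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (lowest-index tie-break).

    ``rows`` may be a DataFrame (schema-checked against training) or a
    raw array in training column order.
    """
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in model.feature_cols if c not in rows.columns]
        if missing:
            raise ValueError(f"schema mismatch, missing columns: {missing}")
        x_raw = rows[list(model.feature_cols)].to_numpy(dtype=float)
    else:
        x_raw = np.asarray(rows, dtype=float)
        if x_raw.ndim == 1:
            x_raw = x_raw[None, :]
        if x_raw.shape[1] != len(model.feature_cols):
            raise ValueError(
                f"schema mismatch: {x_raw.shape[1]} columns, "
                f"expected {len(model.feature_cols)}"
            )
    x = _normalize_apply(x_raw, model.col_min, model.col_max)
    _, probs = _forward(x, model.w1, model.b1, model.w2, model.b2)
    labels = np.array([model.classes[i] for i in probs.argmax(axis=1)])
    return probs, labels


def select_hidden_size(
    datasets,
    candidate_sizes: Sequence[int],
    eval_fn: Callable[[int], float] | None = None,
    seed: int = 0,
    n_repeats: int = 3,
) -> int:
    """Pick the hidden-layer size maximizing average learnability.

    For each candidate, learnability is averaged over the smallest
    (single-feature, 7 inputs) and largest (full battery, 154 inputs)
    input sets; the argmax is returned (smallest size on ties).
    ``eval_fn(size) -> score`` may be injected (e.g. for testing).
    """
    candidates = list(candidate_sizes)
    if not candidates:
        raise ValueError("candidate_sizes is empty")

    if eval_fn is None:
        from . import learnability as _ln
        from .features import ALL_FEATURES

        def eval_fn(size: int) -> float:
            spec = ClassifierSpec(n_hidden=size)
            lo = _ln.wia_learnability(
                datasets, [ALL_FEATURES[0]], n_repeats=n_repeats, seed=seed, spec=spec
            )
            hi = _ln.wia_learnability(
                datasets, ALL_FEATURES, n_repeats=n_repeats, seed=seed, spec=spec
            )
            return (lo.mean_pct + hi.mean_pct) / 2.0

    scores = [eval_fn(s) for s in candidates]
    best = max(range(len(candidates)), key=lambda i: (scores[i], -candidates[i]))
    return candidates[best]
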