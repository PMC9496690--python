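"""1D convolutional classifier for SERS spectra.

A small, self-contained convolutional network implemented directly on
numpy: stacked [conv1d -> ReLU -> max-pool] blocks over the 1101-point
fingerprint, a flatten, one hidden dense ReLU layer and a softmax output.
Training minimizes class-weighted categorical cross-entropy with Adagrad
(per-parameter adaptive learning rates accumulated from past squared
gradients) and early-stops on the loss of a held-out, group-respecting
validation split, returning the parameters at the best validation loss.

Defaults are sized so that a full leave-one-group-out evaluation over a
26-sample x 80-spectrum cohort trains in minutes on one CPU core.

Group hygiene is enforced here as well as in the evaluation driver: a
training call can be handed the test fold's group ids as ``forbidden_groups``
and will refuse to run if any training spectrum traces back to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "CNNModel",
    "PredictionSet",
    "build_model",
    "train",
    "predict",
    "conv_output_length",
    "GroupLeakageError",
]


class GroupLeakageError(RuntimeError):
    """Raised when test-group spectra would enter training."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training protocol.

    conv_blocks
        (filters, kernel) per block; each block is conv (valid padding,
        no stride) -> ReLU -> max-pool by ``pool``.
    pool
        Non-overlapping down-sampling factor after every conv.
    dense_hidden
        Width of the hidden fully connected ReLU layer (the output dense
        layer has one unit per class).
    class_weights
        Optional label -> loss weight; default is inverse class frequency
        of the training set, normalized to mean 1.
    learning_rate
        Adagrad base step.
    patience
        Early stopping: epochs without validation-loss improvement before
        training halts (must be < max_epochs).
    min_delta
        Smallest validation-loss decrease (nats) that counts as an
        improvement for early stopping.
    val_fraction
        Fraction of training *groups* held out for the validation loss.
    """

    conv_blocks: tuple[tuple[int, int], ...] = ((8, 9), (16, 7))
    pool: int = 4
    dense_hidden: int = 64
    class_weights: dict | None = None
    learning_rate: float = 0.05
    max_epochs: int = 40
    patience: int = 6
    min_delta: float = 1e-3
    batch: int = 64
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not self.conv_blocks:
            raise ValueError("need at least one conv block")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


def conv_output_length(input_length: int, config: ModelConfig) -> int:
    """Feature length after all conv (valid padding) + pool blocks."""
    L = input_length
    for _, kernel in config.conv_blocks:
        L = L - kernel + 1
        if L <= 0:
            raise ValueError(f"kernel {kernel} reduces feature length to {L}")
        L = L // config.pool
        if L <= 0:
            raise ValueError("pooling reduces feature length to 0")
    return L


@dataclass
class CNNModel:
    """Parameter container for the 1D CNN (see :func:`build_model`)."""

    config: ModelConfig
    classes: tuple[str, ...]
    input_length: int
    params: dict = field(default_factory=dict)
    # input standardization, fitted on the training set
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    history: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class PredictionSet:
    """Per-spectrum class scores (rows sum to 1) with group bookkeeping."""

    proba: np.ndarray  # (n_spectra, n_classes)
    classes: tuple[str, ...]
    group_ids: tuple[str, ...]

    def __post_init__(self):
        if not np.allclose(self.proba.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("class scores must sum to 1 per spectrum")
        if len(self.group_ids) != self.proba.shape[0]:
            raise ValueError("one group id per spectrum required")

    @property
    def labels(self) -> np.ndarray:
        """Argmax class label per spectrum."""
        return np.asarray(self.classes)[np.argmax(self.proba, axis=1)]


def build_model(
    config: ModelConfig, input_length: int, classes: Sequence[str] | int
) -> CNNModel:
    """Seeded parameter initialization (He-scaled normal) for the stack
    [conv(ReLU) -> max-pool] x blocks -> flatten -> dense(ReLU) -> softmax."""
    if isinstance(classes, int):
        classes = tuple(f"class_{k}" for k in range(classes))
    classes = tuple(classes)
    conv_output_length(input_length, config)  # validate shapes early
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    c_in = 1
    L = input_length
    for b, (filters, kernel) in enumerate(config.conv_blocks):
        fan_in = c_in * kernel
        params[f"Wc{b}"] = (
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(filters, c_in, kernel))
        ).astype(np.float32)
        params[f"bc{b}"] = np.zeros(filters, dtype=np.float32)
        L = (L - kernel + 1) // config.pool
        c_in = filters
    flat = L * c_in
    params["Wd0"] = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, config.dense_hidden)).astype(np.float32)
    params["bd0"] = np.zeros(config.dense_hidden, dtype=np.float32)
    params["Wd1"] = rng.normal(
        0.0, np.sqrt(2.0 / config.dense_hidden), size=(config.dense_hidden, len(classes))
    ).astype(np.float32)
    params["bd1"] = np.zeros(len(classes), dtype=np.float32)
    return CNNModel(config=config, classes=classes, input_length=input_length, params=params)


# ---------------------------------------------------------------------------
# forward / backward

def _conv1d(a: np.ndarray, W: np.ndarray, bias: np.ndarray) -> np.ndarray:
    # valid-padding cross-correlation; (N,C,L) x (F,C,K) -> (N,F,L-K+1)
    K = W.shape[2]
    if a.shape[1] == 1:
        xw = np.ascontiguousarray(sliding_window_view(a[:, 0, :], K, axis=1))
        n, l, _ = xw.shape
        z = (xw.reshape(n * l, K) @ W[:, 0, :].T).reshape(n, l, -1).transpose(0, 2, 1)
    else:
        xw = sliding_window_view(a, K, axis=2)
        z = np.einsum("nclk,fck->nfl", xw, W, optimize=True)
    return z + bias[None, :, None]


def _maxpool(z: np.ndarray, pool: int):
    # non-overlapping max pool over the last axis, tail truncated; a running
    # elementwise max over contiguous window slices beats numpy's strided
    # small-axis reduction by an order of magnitude
    N, F, L = z.shape
    Lp = L // pool
    zr = np.ascontiguousarray(z[:, :, : Lp * pool].reshape(N, F, Lp, pool))
    zt = np.ascontiguousarray(zr.transpose(3, 0, 1, 2))
    out = zt[0].copy()
    for j in range(1, pool):
        np.maximum(out, zt[j], out=out)
    return out, zr


def _forward(model: CNNModel, X: np.ndarray, want_cache: bool = False):
    cfg = model.config
    p = model.params
    cache: list = []
    a = X[:, None, :]  # (N, 1, L)
    for b in range(len(cfg.conv_blocks)):
        z = _conv1d(a, p[f"Wc{b}"], p[f"bc{b}"])
        # max-pool commutes with the monotone ReLU: pool first, then clamp
        pooled, zr = _maxpool(z, cfg.pool)
        if want_cache:
            cache.append((a, z.shape, pooled, zr))
        a = np.maximum(pooled, 0.0)
    shp = a.shape
    flat = a.reshape(shp[0], -1)
    h = flat @ p["Wd0"] + p["bd0"]
    hr = np.maximum(h, 0.0)
    logits = hr @ p["Wd1"] + p["bd1"]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    if want_cache:
        return probs, (cache, shp, flat, h, hr)
    return probs


def _backward(model: CNNModel, X, y_idx, sample_w, probs, fwd_cache):
    cfg = model.config
    p = model.params
    cache, shp, flat, h, hr = fwd_cache
    N = X.shape[0]
    wsum = sample_w.sum()
    dlogits = probs.copy()
    dlogits[np.arange(N), y_idx] -= 1.0
    dlogits *= (sample_w / wsum)[:, None]
    grads = {
        "Wd1": hr.T @ dlogits,
        "bd1": dlogits.sum(axis=0),
    }
    dhr = dlogits @ p["Wd1"].T
    dh = dhr * (h > 0)
    grads["Wd0"] = flat.T @ dh
    grads["bd0"] = dh.sum(axis=0)
    dflat = dh @ p["Wd0"].T
    da = dflat.reshape(shp)
    for b in reversed(range(len(cfg.conv_blocks))):
        a_in, z_shape, pooled, zr = cache[b]
        W = p[f"Wc{b}"]
        Nn, F, L = z_shape
        Lp = L // cfg.pool
        # relu mask (relu applied after pooling), then un-pool: route the
        # gradient to the winner of each pooling window via an equality
        # mask (exact float ties would share the gradient; with continuous
        # pre-activations they do not occur in practice)
        dpooled = da * (pooled > 0)
        drr = (zr == pooled[..., None]) * dpooled[..., None]
        dz = np.zeros((Nn, F, L), dtype=da.dtype)
        dz[:, :, : Lp * cfg.pool] = drr.reshape(Nn, F, Lp * cfg.pool)
        xw = sliding_window_view(a_in, W.shape[2], axis=2)
        grads[f"Wc{b}"] = np.einsum("nclk,nfl->fck", xw, dz, optimize=True)
        grads[f"bc{b}"] = dz.sum(axis=(0, 2))
        if b > 0:
            K = W.shape[2]
            dzp = np.pad(dz, ((0, 0), (0, 0), (K - 1, K - 1)))
            dzw = sliding_window_view(dzp, K, axis=2)  # (N, F, L_in, K)
            da = np.einsum("nflk,fck->ncl", dzw, W[:, :, ::-1], optimize=True)
    return grads


# ---------------------------------------------------------------------------
# training protocol

def _weighted_ce(model: CNNModel, X, y_idx, sample_w) -> float:
    probs = _forward(model, X)
    ll = -np.log(np.clip(probs[np.arange(len(y_idx)), y_idx], 1e-12, None))
    return float((sample_w * ll).sum() / sample_w.sum())


def _group_val_split(groups: np.ndarray, frac: float, rng: np.random.Generator):
    uniq = np.array(sorted(set(groups.tolist())))
    if uniq.size >= 3:
        n_val = max(1, int(round(frac * uniq.size)))
        n_val = min(n_val, uniq.size - 2)  # keep >=2 training groups
        val_groups = set(rng.choice(uniq, size=n_val, replace=False).tolist())
        val_mask = np.isin(groups, list(val_groups))
    else:
        # too few groups for a group-respecting split: random 10% of spectra
        val_mask = rng.random(groups.size) < max(frac, 1.0 / groups.size)
        if not val_mask.any():
            val_mask[rng.integers(groups.size)] = True
        if val_mask.all():
            val_mask[rng.integers(groups.size)] = False
    return ~val_mask, val_mask


def train(
    model: CNNModel,
    X: np.ndarray,
    labels: Sequence[str],
    groups: Sequence[str],
    forbidden_groups: set | frozenset = frozenset(),
) -> CNNModel:
    """Fit the model in place (and return it).

    ``X`` is (n_spectra, n_points) of preprocessed, normalized intensities;
    ``labels`` the class per spectrum; ``groups`` the mapping-group id per
    spectrum (synthetic augmented spectra must carry their source group's
    id).  Any overlap between ``groups`` and ``forbidden_groups`` — the
    held-out test fold — aborts with :class:`GroupLeakageError`.
    """
    cfg = model.config
    X = np.asarray(X, dtype=np.float32)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    leaked = set(groups.tolist()) & set(forbidden_groups)
    if leaked:
        raise GroupLeakageError(f"test groups present in training data: {sorted(leaked)}")
    present = set(labels.tolist())
    if len(present) < 2:
        raise ValueError("training set contains a single class")
    missing = present - set(model.classes)
    if missing:
        raise ValueError(f"labels {sorted(missing)} not among model classes {model.classes}")

    class_to_idx = {c: i for i, c in enumerate(model.classes)}
    y_idx = np.array([class_to_idx[l] for l in labels])

    # inverse-frequency class weights, mean 1 over spectra
    if cfg.class_weights is None:
        counts = np.bincount(y_idx, minlength=model.n_classes).astype(float)
        w_class = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        w_class *= len(y_idx) / (w_class[y_idx]).sum()
    else:
        w_class = np.array([cfg.class_weights.get(c, 1.0) for c in model.classes])
    sample_w = w_class[y_idx].astype(np.float32)

    # standardize inputs on the training set
    model.x_mean = X.mean(axis=0)
    model.x_sd = np.maximum(X.std(axis=0), 1e-12).astype(np.float32)
    Xs = (X - model.x_mean) / model.x_sd

    rng = np.random.default_rng(cfg.seed + 1)
    tr_mask, val_mask = _group_val_split(groups, cfg.val_fraction, rng)
    if len(set(labels[tr_mask].tolist())) < 2:
        # validation draw stripped a class; fall back to a spectrum split
        val_mask = rng.random(groups.size) < cfg.val_fraction
        tr_mask = ~val_mask
    Xtr, ytr, wtr = Xs[tr_mask], y_idx[tr_mask], sample_w[tr_mask]
    Xval, yval, wval = Xs[val_mask], y_idx[val_mask], sample_w[val_mask]

    accum = {k: np.zeros_like(v) for k, v in model.params.items()}
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_epoch = 0
    stall = 0
    val_losses = []
    n = Xtr.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch):
            sel = order[start : start + cfg.batch]
            probs, fwd_cache = _forward(model, Xtr[sel], want_cache=True)
            grads = _backward(model, Xtr[sel], ytr[sel], wtr[sel], probs, fwd_cache)
            for k, g in grads.items():
                accum[k] += g * g
                model.params[k] -= cfg.learning_rate * g / (np.sqrt(accum[k]) + 1e-8)
        vloss = _weighted_ce(model, Xval, yval, wval) if Xval.size else _weighted_ce(
            model, Xtr, ytr, wtr
        )
        val_losses.append(vloss)
        if vloss < best_loss - cfg.min_delta:
            best_loss = vloss
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.params = best_params
    model.history = {
        "val_loss": val_losses,
        "best_epoch": best_epoch,
        "stopped_epoch": epoch,
        "n_train": int(tr_mask.sum()),
        "n_val": int(val_mask.sum()),
    }
    return model


def predict(
    model: CNNModel, X: np.ndarray, group_ids: Sequence[str] | None = None
) -> PredictionSet:
    """Per-spectrum class distributions and argmax labels.

    Prediction is a pure function of the trained parameters and the input;
    the input grid length must match the training grid.
    """
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_length:
        raise ValueError(
            f"input length {X.shape[1]} does not match model grid {model.input_length}"
        )
    if model.x_mean is not None:
        X = (X - model.x_mean) / model.x_sd
    probs = _forward(model, X).astype(np.float64)
    probs = probs / probs.sum(axis=1, keepdims=True)
    gids = tuple(group_ids) if group_ids is not None else ("",) * X.shape[0]
    return PredictionSet(probs, model.classes, gids)
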