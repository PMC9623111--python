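"""One-dimensional convolutional neural network for Fv/Fm regression.

Architecture (fixed by design, sizes configurable): five valid-padding conv
layers (16 filters, kernel length 3, stride 1), each followed by ReLU, then one
max-pooling layer (window 2, stride 2), global average pooling down to one
value per filter, and a single linear output neuron.  With a 1024-channel
spectrum the length bookkeeping is 1024 -> 1014 after the conv stack -> 507
after pooling -> 16 features -> 1 output.

Training minimizes mean absolute error with RMSProp (accumulator decay rho,
step lr / sqrt(accumulator + epsilon)) over shuffled mini-batches; everything
is driven by one seed, so runs are exactly reproducible.  All operators are
plain numpy (float64); convolution is realized as an im2col matrix product,
and gradients are derived by hand (checked against finite differences in the
test suite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from cottonfvfm.preprocess import ScalerState, Standardizer

# ---------------------------------------------------------------------------
# configuration and parameter containers


@dataclass(frozen=True)
class PoolSpec:
    """Pooling window: kind ('max' or 'average'), window length, stride."""

    kind: str = "max"
    size: int = 2
    stride: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("max", "average"):
            raise ValueError("pool kind must be 'max' or 'average'")
        if self.size < 1 or self.stride < 1:
            raise ValueError("pool size and stride must be >= 1")


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the network and its optimizer.

    Defaults follow the reference architecture: 5 conv layers of 16 length-3
    kernels at stride 1, 2/2 max pooling, RMSProp with learning rate 1e-3 and
    gradient decay 0.9, MAE loss, batch size 5, 5000 epochs.  ``epsilon`` is
    the RMSProp stabilizer (a literal zero would make the first update
    divide by zero, so a small positive default is used).
    """

    n_conv_layers: int = 5
    n_filters: int = 16
    kernel_size: int = 3
    conv_stride: int = 1
    pool: PoolSpec = field(default_factory=PoolSpec)
    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-7
    lr_decay: float = 0.0
    epochs: int = 5000
    batch_size: int = 5
    loss: str = "mae"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epsilon) < 0 or self.rho < 0:
            raise ValueError("rates must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.n_conv_layers < 1 or self.n_filters < 1 or self.kernel_size < 1:
            raise ValueError("invalid architecture sizes")
        if self.conv_stride != 1:
            raise ValueError("only stride-1 convolutions are supported")
        if self.loss != "mae":
            raise ValueError("only the MAE loss is supported")

    def min_input_length(self) -> int:
        """Smallest spectrum length the conv stack + pooling can consume."""
        return self.n_conv_layers * (self.kernel_size - 1) + self.pool.size


@dataclass
class ConvLayerParams:
    """Weights of one conv layer: kernels (F, C, K) and per-filter bias (F,)."""

    kernels: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.kernels.ndim != 3 or self.bias.shape != (self.kernels.shape[0],):
            raise ValueError("inconsistent conv parameter shapes")


@dataclass
class DenseParams:
    """Weights of the output neuron: one weight per incoming feature + bias."""

    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)


@dataclass
class TrainedModel:
    """A trained network: config, layer parameters, scaler, loss history."""

    config: CNNConfig
    conv_layers: list[ConvLayerParams]
    dense: DenseParams
    scaler: ScalerState
    history: list[float]

    @property
    def n_features(self) -> int:
        return int(self.scaler.x_center.size)


# ---------------------------------------------------------------------------
# forward operators (single-sample contracts)


def relu(x):
    """Rectified linear unit, elementwise max(0, x)."""
    return np.maximum(0, np.asarray(x))


def conv1d_forward(x: np.ndarray, layer: ConvLayerParams) -> np.ndarray:
    """Valid-padding stride-1 cross-correlation of (C, W) input with a layer.

    Output channel j at position p is
    ``bias_j + sum_{i,k} kernels[j, i, k] * x[i, p + k]``; output shape is
    (F, W - K + 1).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    F, C, K = layer.kernels.shape
    if x.shape[0] != C:
        raise ValueError(f"expected {C} input channels, got {x.shape[0]}")
    if x.shape[1] < K:
        raise ValueError(f"input length {x.shape[1]} shorter than kernel {K}")
    out = _conv_batch(x[None], layer.kernels, layer.bias)[0]
    return out


def pool1d(x: np.ndarray, spec: PoolSpec = PoolSpec()) -> np.ndarray:
    """Windowed max/average pooling per channel; trailing remainder dropped.

    Output length is ``floor((W - size) / stride) + 1``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    W = x.shape[-1]
    if W < spec.size:
        raise ValueError(f"input length {W} shorter than pool size {spec.size}")
    starts = np.arange(0, W - spec.size + 1, spec.stride)
    windows = x[..., starts[:, None] + np.arange(spec.size)]  # (..., n_out, size)
    return windows.max(axis=-1) if spec.kind == "max" else windows.mean(axis=-1)


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Arithmetic mean over positions, one value per channel."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] == 0:
        raise ValueError("cannot average an empty channel")
    return x.mean(axis=-1)


def dense_forward(v: np.ndarray, params: DenseParams) -> float:
    """Linear output neuron: weights . v + bias."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size != params.weights.size:
        raise ValueError(
            f"feature length mismatch: expected {params.weights.size}, got {v.size}"
        )
    return float(params.weights @ v + params.bias)


def forward(model: TrainedModel, x: np.ndarray) -> float:
    """Full forward pass on one standardized spectrum -> standardized Fv/Fm."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < model.config.min_input_length():
        raise ValueError(
            f"input length {x.size} below the minimum consumable "
            f"{model.config.min_input_length()}"
        )
    h = x[None, :]  # (1 channel, W)
    for layer in model.conv_layers:
        h = relu(conv1d_forward(h, layer))
    h = pool1d(h, model.config.pool)
    v = global_avg_pool(h)
    return dense_forward(v, model.dense)


# ---------------------------------------------------------------------------
# batched internals (im2col convolution + hand-derived backprop)


def _im2col(x: np.ndarray, K: int) -> np.ndarray:
    """(B, C, W) -> (B, W', C*K) patch matrix for kernel length K."""
    B, C, W = x.shape
    win = sliding_window_view(x, K, axis=2)  # (B, C, W', K)
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, W - K + 1, C * K)


def _conv_batch(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray):
    """Batched valid cross-correlation: (B, C, W) -> (B, F, W')."""
    F, C, K = kernels.shape
    cols = _im2col(x, K)  # (B, W', C*K)
    out = cols @ kernels.reshape(F, C * K).T + bias  # (B, W', F)
    return out.transpose(0, 2, 1)


def _conv_batch_cached(x, kernels, bias):
    F, C, K = kernels.shape
    cols = _im2col(x, K)
    out = cols @ kernels.reshape(F, C * K).T + bias
    return out.transpose(0, 2, 1), cols


def _conv_backward(grad_out, cols, kernels, x_shape):
    """Gradients of the im2col convolution.

    grad_out: (B, F, W'); cols: (B, W', C*K).  Returns (grad_x, grad_k, grad_b).
    """
    F, C, K = kernels.shape
    B, _, W = x_shape
    Wp = grad_out.shape[2]
    g = np.ascontiguousarray(grad_out.transpose(0, 2, 1))  # (B, W', F)
    g2 = g.reshape(B * Wp, F)
    grad_k = (g2.T @ cols.reshape(B * Wp, C * K)).reshape(F, C, K)
    grad_b = g2.sum(axis=0)
    grad_cols = (g2 @ kernels.reshape(F, C * K)).reshape(B, Wp, C, K)
    grad_x = np.zeros(x_shape)
    for k in range(K):
        grad_x[:, :, k : k + Wp] += grad_cols[:, :, :, k].transpose(0, 2, 1)
    return grad_x, grad_k, grad_b


def _forward_batch(model_params, config: CNNConfig, x: np.ndarray, want_cache=False):
    """Batched forward pass on standardized (B, W) inputs -> (B,) outputs."""
    conv_layers, dense = model_params
    h = x[:, None, :]
    cache = []
    for layer in conv_layers:
        z, cols = _conv_batch_cached(h, layer.kernels, layer.bias)
        a = np.maximum(0.0, z)
        if want_cache:
            cache.append((h.shape, cols, z > 0))
        h = a
    # max pool (window/stride from config); remember argmax for backprop
    spec = config.pool
    W = h.shape[-1]
    starts = np.arange(0, W - spec.size + 1, spec.stride)
    windows = h[..., starts[:, None] + np.arange(spec.size)]
    if spec.kind == "max":
        arg = windows.argmax(axis=-1)
        pooled = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
    else:
        arg = None
        pooled = windows.mean(axis=-1)
    v = pooled.mean(axis=-1)  # global average pool -> (B, F)
    out = v @ dense.weights + dense.bias
    if not want_cache:
        return out
    return out, (cache, (h.shape, starts, arg, pooled.shape), v)


def _backward_batch(model_params, config, cache_pack, grad_pred):
    """Hand-derived gradients of the whole network for a batch."""
    conv_layers, dense = model_params
    cache, (h_shape, starts, arg, pooled_shape), v = cache_pack
    B = grad_pred.shape[0]
    grad_dense_w = v.T @ grad_pred
    grad_dense_b = float(grad_pred.sum())
    grad_v = np.outer(grad_pred, dense.weights)  # (B, F)
    n_pos = pooled_shape[-1]
    grad_pooled = np.repeat(grad_v[:, :, None], n_pos, axis=2) / n_pos
    # un-pool
    grad_h = np.zeros(h_shape)
    spec = config.pool
    if spec.kind == "max":
        pos = starts[None, None, :] + arg  # (B, F, n_out) absolute positions
        np.add.at(
            grad_h,
            (
                np.arange(B)[:, None, None],
                np.arange(h_shape[1])[None, :, None],
                pos,
            ),
            grad_pooled,
        )
    else:
        for wi in range(spec.size):
            np.add.at(
                grad_h,
                (slice(None), slice(None), starts + wi),
                grad_pooled / spec.size,
            )
    grads = []
    for layer, (x_shape, cols, mask) in zip(reversed(conv_layers), reversed(cache)):
        grad_z = grad_h * mask
        grad_h, gk, gb = _conv_backward(grad_z, cols, layer.kernels, x_shape)
        grads.append((gk, gb))
    grads.reverse()
    return grads, (grad_dense_w, grad_dense_b)


# ---------------------------------------------------------------------------
# initialization, training, prediction


def _init_params(config: CNNConfig, rng: np.random.Generator):
    """Seeded uniform init scaled by fan-in (He-style bound), zero biases."""
    conv_layers = []
    c_in = 1
    for _ in range(config.n_conv_layers):
        fan_in = c_in * config.kernel_size
        bound = np.sqrt(6.0 / fan_in)
        kernels = rng.uniform(-bound, bound, (config.n_filters, c_in, config.kernel_size))
        conv_layers.append(ConvLayerParams(kernels=kernels, bias=np.zeros(config.n_filters)))
        c_in = config.n_filters
    bound = np.sqrt(6.0 / config.n_filters)
    dense = DenseParams(weights=rng.uniform(-bound, bound, config.n_filters), bias=0.0)
    return conv_layers, dense


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: CNNConfig,
    standardize: bool = True,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Train the network with mini-batch RMSProp on the MAE loss.

    ``X`` is (n_samples, n_wavelengths) raw reflectance and ``y`` raw Fv/Fm;
    both are z-scored internally and the fitted scaler is stored on the model
    so :func:`predict` can invert it.  The per-epoch mean training loss (in
    standardized units) is recorded in ``model.history``.  An optional
    ``validation`` pair (X_val, y_val in raw units) is scored every 50 epochs
    and logged for monitoring only; it never influences the fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} samples, got {n}")
    if X.shape[1] < config.min_input_length():
        raise ValueError("spectra shorter than the minimum consumable length")
    scaler = Standardizer().fit(X, y)
    Xs = scaler.transform_X(X) if standardize else X.copy()
    ys = scaler.transform_y(y) if standardize else y.copy()

    rng = np.random.default_rng(config.seed)
    conv_layers, dense = _init_params(config, rng)
    params = (conv_layers, dense)

    # RMSProp accumulators, one per tensor
    acc_conv = [
        (np.zeros_like(l.kernels), np.zeros_like(l.bias)) for l in conv_layers
    ]
    acc_dense = (np.zeros_like(dense.weights), 0.0)
    lr0, rho, eps = config.learning_rate, config.rho, config.epsilon

    history: list[float] = []
    n_batches = int(np.ceil(n / config.batch_size))
    for epoch in range(config.epochs):
        lr = lr0 / (1.0 + config.lr_decay * epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            xb, yb = Xs[idx], ys[idx]
            pred, cache = _forward_batch(params, config, xb, want_cache=True)
            err = pred - yb
            loss = float(np.mean(np.abs(err)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {b}"
                )
            epoch_loss += loss * idx.size
            grad_pred = np.sign(err) / idx.size
            conv_grads, (gdw, gdb) = _backward_batch(params, config, cache, grad_pred)
            if lr > 0.0:
                for li, (gk, gb) in enumerate(conv_grads):
                    ak, ab = acc_conv[li]
                    ak[:] = rho * ak + (1 - rho) * gk**2
                    ab[:] = rho * ab + (1 - rho) * gb**2
                    conv_layers[li].kernels -= lr * gk / np.sqrt(ak + eps)
                    conv_layers[li].bias -= lr * gb / np.sqrt(ab + eps)
                aw, ab2 = acc_dense
                aw[:] = rho * aw + (1 - rho) * gdw**2
                ab2 = rho * ab2 + (1 - rho) * gdb**2
                acc_dense = (aw, ab2)
                dense.weights -= lr * gdw / np.sqrt(aw + eps)
                dense.bias -= lr * gdb / np.sqrt(ab2 + eps)
        history.append(epoch_loss / n)
        if validation is not None and (epoch % 50 == 0 or epoch == config.epochs - 1):
            Xv = scaler.transform_X(np.asarray(validation[0], dtype=float))
            yv = scaler.transform_y(np.asarray(validation[1], dtype=float).ravel())
            val_mae = float(np.mean(np.abs(_forward_batch(params, config, Xv) - yv)))
            logging.getLogger(__name__).info(
                "epoch %d: train MAE %.5f, validation MAE %.5f",
                epoch, history[-1], val_mae,
            )
    return TrainedModel(
        config=config,
        conv_layers=conv_layers,
        dense=dense,
        scaler=scaler.state,
        history=history,
    )


def predict(model: TrainedModel, X_raw: np.ndarray) -> np.ndarray:
    """Predict Fv/Fm in original units from raw reflectance spectra."""
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if X_raw.shape[1] != model.n_features:
        raise ValueError(
            f"wavelength count mismatch: model expects {model.n_features}, "
            f"got {X_raw.shape[1]}"
        )
    sc = Standardizer()
    sc.state = model.scaler
    Xs = sc.transform_X(X_raw)
    preds = []
    for i in range(0, Xs.shape[0], 256):
        preds.append(_forward_batch((model.conv_layers, model.dense), model.config, Xs[i : i + 256]))
    return sc.inverse_y(np.concatenate(preds))


# ---------------------------------------------------------------------------
# persistence (JSON config/scaler + npz weights)


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist a trained model to a directory (config.json + weights.npz)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["pool"] = asdict(model.config.pool)
    meta = {
        "config": cfg,
        "history": model.history,
        "divide_by_variance": model.scaler.divide_by_variance,
        "y_center": model.scaler.y_center,
        "y_scale": model.scaler.y_scale,
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    arrays = {
        "x_center": model.scaler.x_center,
        "x_scale": model.scaler.x_scale,
        "dense_w": model.dense.weights,
        "dense_b": np.array([model.dense.bias]),
    }
    for i, layer in enumerate(model.conv_layers):
        arrays[f"conv{i}_k"] = layer.kernels
        arrays[f"conv{i}_b"] = layer.bias
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    cfg = dict(meta["config"])
    cfg["pool"] = PoolSpec(**cfg["pool"])
    config = CNNConfig(**cfg)
    with np.load(directory / "weights.npz") as z:
        conv_layers = [
            ConvLayerParams(kernels=z[f"conv{i}_k"], bias=z[f"conv{i}_b"])
            for i in range(config.n_conv_layers)
        ]
        dense = DenseParams(weights=z["dense_w"], bias=float(z["dense_b"][0]))
        scaler = ScalerState(
            x_center=z["x_center"],
            x_scale=z["x_scale"],
            y_center=meta["y_center"],
            y_scale=meta["y_scale"],
            divide_by_variance=meta["divide_by_variance"],
        )
    return TrainedModel(
        config=config,
        conv_layers=conv_layers,
        dense=dense,
        scaler=scaler,
        history=list(meta["history"]),
    )
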