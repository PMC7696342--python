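"""Conv-GRU gesture classifier: definition, training and inference.

The network consumes raw sEMG windows (188 samples x 8 channels) and emits
a probability distribution over the 7 gesture classes:

    Conv1D(64, k=3) -> Conv1D(64, k=3) -> MaxPool(3)
    -> Conv1D(128, k=3) -> Conv1D(128, k=3) -> Dropout(0.5)
    -> GRU(150, sequences) -> Dropout(0.5) -> GRU(150, final state)
    -> Dropout(0.5) -> Dense(7) -> softmax

Convolutions are 'valid' (no padding) with ReLU; the pool slides a window
of 3 with stride 3, so the temporal trace for a 188-sample window is
188 -> 186 -> 184 -> 61 -> 59 -> 57 into the recurrent layers.  Training
uses Adam (constant learning rate 1e-4, batch 500, 300 epochs by default)
with categorical cross-entropy on one-hot or smoothed targets, and a
temporal 75/25 train/validation split within each recording: the network
validates on later moments of the same subjects it trains on.

All layers, backpropagation (including backprop-through-time for the GRU)
and the Adam optimizer are implemented here on numpy arrays; gradients are
verified against finite differences in the test suite.  The GRU uses the
classic formulation with the reset gate applied to the previous state
before the candidate's recurrent matmul:

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    g_t = tanh(x_t Wg + (r_t * h_{t-1}) Ug + bg)
    h_t = z_t * h_{t-1} + (1 - z_t) * g_t
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .windowing import WindowSet, temporal_split

logger = logging.getLogger("semgrec")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Layer-stack hyperparameters of the Conv-GRU classifier."""

    conv_blocks: tuple[tuple[int, ...], ...] = ((64, 64), (128, 128))
    kernel_size: int = 3
    pool_size: int = 3
    conv_dropout: float = 0.5
    gru_units: tuple[int, ...] = (150, 150)
    gru_dropout: float = 0.5
    n_classes: int = 7
    padding: str = "valid"  # 'valid' or 'same'
    conv_activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for rate in (self.conv_dropout, self.gru_dropout):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        if len(self.gru_units) < 1:
            raise ValueError("need at least one GRU layer")

    @classmethod
    def reduced(cls) -> "ModelSpec":
        """A narrow variant for CPU-scale experiments and tests.

        Same topology (two conv blocks, pool, two GRU layers, softmax head)
        at roughly a quarter of the width, with lighter dropout since the
        small model has far less capacity to overfit.
        """
        return cls(
            conv_blocks=((16, 16), (32, 32)),
            gru_units=(32, 32),
            conv_dropout=0.25,
            gru_dropout=0.25,
        )

    def temporal_trace(self, input_length: int) -> list[int]:
        """Temporal lengths after each conv/pool stage, ending at GRU input."""
        trace = [input_length]
        length = input_length
        for block_idx, block in enumerate(self.conv_blocks):
            for _ in block:
                if self.padding == "valid":
                    length = length - (self.kernel_size - 1)
                trace.append(length)
            if block_idx == 0:
                length = length // self.pool_size
                trace.append(length)
        return trace

    def min_input_length(self) -> int:
        """Smallest window length that leaves >= 1 timestep for the GRUs."""
        length = 1
        while self.temporal_trace(length)[-1] < 1 or min(self.temporal_trace(length)) < 1:
            length += 1
        return length


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe: Adam with a constant learning rate."""

    learning_rate: float = 1e-4
    batch_size: int = 500
    epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def reduced(cls, epochs: int = 30, seed: int = 0) -> "TrainConfig":
        """Short-schedule recipe for the reduced model on synthetic data.

        A higher constant learning rate (2e-3) compensates for the much
        shorter schedule; batch 256 keeps per-step memory modest on a CPU.
        """
        return cls(learning_rate=2e-3, batch_size=256, epochs=epochs, seed=seed)


# ---------------------------------------------------------------------------
# Layers (forward + backward on numpy arrays)
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: parameters/gradients as dicts, cached forward state."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution over the time axis via im2col, optional ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 padding: str, activation: str, rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.kernel_size = kernel_size
        self.padding = padding
        self.activation = activation
        k_in = kernel_size * in_channels
        self.params["W"] = _glorot(rng, k_in, filters, (k_in, filters), dtype)
        self.params["b"] = np.zeros(filters, dtype=dtype)

    def forward(self, x, train, rng):
        if self.padding == "same":
            pad = self.kernel_size - 1
            x = np.pad(x, ((0, 0), (pad // 2, pad - pad // 2), (0, 0)))
        b_sz, length, cin = x.shape
        lout = length - self.kernel_size + 1
        # (B, Lout, k, Cin) -> (B, Lout, k*Cin)
        cols = sliding_window_view(x, self.kernel_size, axis=1)  # B, Lout, Cin, k
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(b_sz, lout, -1)
        z = cols @ self.params["W"] + self.params["b"]
        self._cols, self._in_len, self._cin = cols, length, cin
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0)
        self._mask = None
        return z

    def backward(self, dy):
        if self._mask is not None:
            dy = dy * self._mask
        b_sz, lout, filters = dy.shape
        k_in = self.params["W"].shape[0]
        self.grads["W"] = self._cols.reshape(-1, k_in).T @ dy.reshape(-1, filters)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dcols = (dy @ self.params["W"].T).reshape(b_sz, lout, self.kernel_size, self._cin)
        dx = np.zeros((b_sz, self._in_len, self._cin), dtype=dy.dtype)
        for k in range(self.kernel_size):
            dx[:, k : k + lout, :] += dcols[:, :, k, :]
        if self.padding == "same":
            pad = self.kernel_size - 1
            dx = dx[:, pad // 2 : self._in_len - (pad - pad // 2), :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling (stride = pool window)."""

    def __init__(self, pool_size: int) -> None:
        super().__init__()
        self.pool_size = pool_size

    def forward(self, x, train, rng):
        b_sz, length, ch = x.shape
        lout = length // self.pool_size
        trimmed = x[:, : lout * self.pool_size, :].reshape(b_sz, lout, self.pool_size, ch)
        self._argmax = trimmed.argmax(axis=2)
        self._in_shape = x.shape
        return trimmed.max(axis=2)

    def backward(self, dy):
        b_sz, lout, ch = dy.shape
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dpooled = dx[:, : lout * self.pool_size, :].reshape(b_sz, lout, self.pool_size, ch)
        b_idx, l_idx, c_idx = np.ogrid[:b_sz, :lout, :ch]
        dpooled[b_idx, l_idx, self._argmax, c_idx] = dy
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x):
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class GRU(Layer):
    """Gated recurrent unit over the time axis, with BPTT.

    Gate x-projections are packed into one matrix ``W`` (Cin x 3H, order
    z|r|g) so the input transform is a single matmul over the whole
    sequence; the recurrent transforms use ``Uzr`` (H x 2H) and, for the
    candidate, ``Ug`` (H x H) applied after the reset gate.
    """

    def __init__(self, in_channels: int, units: int, return_sequences: bool,
                 rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        h = units
        self.params["W"] = _glorot(rng, in_channels, 3 * h, (in_channels, 3 * h), dtype)
        self.params["Uzr"] = _glorot(rng, h, 2 * h, (h, 2 * h), dtype)
        self.params["Ug"] = _glorot(rng, h, h, (h, h), dtype)
        self.params["b"] = np.zeros(3 * h, dtype=dtype)

    def forward(self, x, train, rng):
        b_sz, steps, _ = x.shape
        h = self.units
        xw = x @ self.params["W"] + self.params["b"]  # B, T, 3H
        h_t = np.zeros((b_sz, h), dtype=x.dtype)
        cache = []
        outs = np.empty((b_sz, steps, h), dtype=x.dtype) if self.return_sequences else None
        for t in range(steps):
            h_prev = h_t
            uzr = h_prev @ self.params["Uzr"]
            z = _sigmoid(xw[:, t, :h] + uzr[:, :h])
            r = _sigmoid(xw[:, t, h : 2 * h] + uzr[:, h:])
            rh = r * h_prev
            g = np.tanh(xw[:, t, 2 * h :] + rh @ self.params["Ug"])
            h_t = z * h_prev + (1.0 - z) * g
            cache.append((h_prev, z, r, rh, g))
            if outs is not None:
                outs[:, t, :] = h_t
        self._x, self._cache = x, cache
        self._last = h_t
        return outs if self.return_sequences else h_t

    def backward(self, dy):
        x, cache = self._x, self._cache
        b_sz, steps, cin = x.shape
        h = self.units
        w, uzr_mat, ug = self.params["W"], self.params["Uzr"], self.params["Ug"]
        d_w = np.zeros_like(w)
        d_uzr = np.zeros_like(uzr_mat)
        d_ug = np.zeros_like(ug)
        d_b = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh = np.zeros((b_sz, h), dtype=x.dtype)
        for t in range(steps - 1, -1, -1):
            h_prev, z, r, rh, g = cache[t]
            if self.return_sequences:
                dh = dh + dy[:, t, :]
            elif t == steps - 1:
                dh = dh + dy
            dz = dh * (h_prev - g)
            dg = dh * (1.0 - z)
            dh_prev = dh * z
            # candidate: g = tanh(a_g), a_g = xw_g + rh @ Ug
            da_g = dg * (1.0 - g * g)
            d_ug += rh.T @ da_g
            drh = da_g @ ug.T
            dr = drh * h_prev
            dh_prev += drh * r
            # gates
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            da_zr = np.concatenate([da_z, da_r], axis=1)
            d_uzr += h_prev.T @ da_zr
            dh_prev += da_zr @ uzr_mat.T
            da = np.concatenate([da_zr, da_g], axis=1)  # B, 3H (z|r|g)
            d_w += x[:, t, :].T @ da
            d_b += da.sum(axis=0)
            dx[:, t, :] = da @ w.T
            dh = dh_prev
        self.grads = {"W": d_w, "Uzr": d_uzr, "Ug": d_ug, "b": d_b}
        return dx


class Dense(Layer):
    """Affine map to class logits (softmax is applied by the loss/predict)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, in_features, out_features,
                                   (in_features, out_features), dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    eps = np.finfo(probs.dtype).tiny
    return float(-(targets * np.log(probs + eps)).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ConvGRUClassifier:
    """The assembled network; built by :func:`build_model`."""

    def __init__(self, spec: ModelSpec, input_length: int, channels: int,
                 seed: int = 0, dtype=np.float32) -> None:
        trace = spec.temporal_trace(input_length)
        if min(trace) < 1:
            raise ValueError(
                f"input_length {input_length} too small for the conv/pool stack "
                f"(trace {trace}); minimum is {spec.min_input_length()}"
            )
        self.spec = spec
        self.input_length = input_length
        self.channels = channels
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
        layers: list[Layer] = []
        cin = channels
        for block_idx, block in enumerate(spec.conv_blocks):
            for filters in block:
                layers.append(Conv1D(cin, filters, spec.kernel_size, spec.padding,
                                     spec.conv_activation, rng, dtype))
                cin = filters
            if block_idx == 0:
                layers.append(MaxPool1D(spec.pool_size))
        layers.append(Dropout(spec.conv_dropout))
        for i, units in enumerate(spec.gru_units):
            last = i == len(spec.gru_units) - 1
            layers.append(GRU(cin, units, return_sequences=not last, rng=rng, dtype=dtype))
            layers.append(Dropout(spec.gru_dropout))
            cin = units
        self._head_index = len(layers)  # layers[:_head_index] end at the penultimate rep
        layers.append(Dense(cin, spec.n_classes, rng, dtype))
        self.layers = layers

    # -- forward / backward -------------------------------------------------

    def logits(self, x: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.input_length or x.shape[2] != self.channels:
            raise ValueError(
                f"expected windows of shape (B, {self.input_length}, {self.channels}), "
                f"got {x.shape}"
            )
        out = x.astype(self.dtype, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits.astype(self.dtype, copy=False)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities in inference mode (dropout disabled)."""
        chunks = [softmax(self.logits(x[i : i + batch_size]))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)

    def embed(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Penultimate representation (final GRU state, pre-softmax-head)."""
        outs = []
        for i in range(0, len(x), batch_size):
            out = x[i : i + batch_size].astype(self.dtype, copy=False)
            for layer in self.layers[: self._head_index]:
                out = layer.forward(out, train=False, rng=None)
            outs.append(out)
        return np.concatenate(outs, axis=0)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                yield (i, name), arr

    def n_parameters(self) -> int:
        return sum(arr.size for _, arr in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"layer{i}.{name}": arr for (i, name), arr in self.parameters()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for (i, name), arr in self.parameters():
            key = f"layer{i}.{name}"
            if key not in arrays:
                raise KeyError(f"checkpoint missing parameter {key}")
            if arrays[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}")
            self.layers[i].params[name] = arrays[key].astype(self.dtype)


def build_model(spec: ModelSpec = ModelSpec(), input_length: int = 188,
                channels: int = 8, seed: int = 0, dtype=np.float32) -> ConvGRUClassifier:
    """Construct an untrained Conv-GRU classifier for the given input shape."""
    return ConvGRUClassifier(spec, input_length, channels, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; hyperparameters beta1=0.9, beta2=0.999."""

    def __init__(self, model: ConvGRUClassifier, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(arr) for key, arr in model.parameters()}
        self.v = {key: np.zeros_like(arr) for key, arr in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (i, name), arr in self.model.parameters():
            grad = self.model.layers[i].grads[name]
            key = (i, name)
            self.m[key] = b1 * self.m[key] + (1 - b1) * grad
            self.v[key] = b2 * self.v[key] + (1 - b2) * grad * grad
            m_hat = self.m[key] / (1 - b1 ** self.t)
            v_hat = self.v[key] / (1 - b2 ** self.t)
            arr -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(arr.dtype)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained classifier with its spec, recipe and per-epoch history."""

    model: ConvGRUClassifier
    train_config: TrainConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec


def _epoch_eval(model: ConvGRUClassifier, x, y, batch_size: int) -> tuple[float, float]:
    probs = model.predict_proba(x, batch_size=batch_size)
    loss = cross_entropy(probs, y)
    acc = float((probs.argmax(axis=1) == y.argmax(axis=1)).mean())
    return loss, acc


def train(
    model: ConvGRUClassifier,
    windows: WindowSet | np.ndarray,
    targets: np.ndarray | None = None,
    train_config: TrainConfig = TrainConfig(),
    validation_fraction: float = 0.25,
) -> TrainedModel:
    """Fit the classifier with Adam and categorical cross-entropy.

    When ``windows`` is a :class:`~semgrec.windowing.WindowSet`, the
    validation split is temporal within each source recording: the earliest
    ``1 - validation_fraction`` of each recording's windows train, the rest
    validate (same subjects, different moments).  Plain ``(windows,
    targets)`` arrays are treated as one temporally ordered sequence.
    History records train/validation loss and accuracy per epoch.
    """
    if isinstance(windows, WindowSet):
        ws = windows
        if targets is not None:
            raise ValueError("pass either a WindowSet or (windows, targets), not both")
    else:
        if targets is None:
            raise ValueError("targets required when windows is a plain array")
        n = len(windows)
        ws = WindowSet(
            X=np.asarray(windows), y=np.asarray(targets),
            subject_ids=np.asarray(["?"] * n, dtype=object),
            recording_ids=np.zeros(n, dtype=np.int64),
            start_indices=np.arange(n, dtype=np.int64),
        )
    if len(ws.X) == 0:
        raise ValueError("empty training set")
    if len(ws.X) != len(ws.y):
        raise ValueError("windows and targets are misaligned")

    if validation_fraction > 0:
        tr_idx, va_idx = temporal_split(ws, validation_fraction)
    else:
        tr_idx = np.arange(len(ws.X))
        va_idx = np.array([], dtype=np.int64)
    x_tr, y_tr = ws.X[tr_idx], ws.y[tr_idx]
    x_va, y_va = ws.X[va_idx], ws.y[va_idx]
    if len(x_tr) == 0:
        raise ValueError("empty training set after validation split")

    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed, spawn_key=(1,)))
    optimizer = Adam(model, train_config.learning_rate)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [],
    }
    n_tr = len(x_tr)
    bs = min(train_config.batch_size, n_tr)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n_tr, bs):
            batch = order[start : start + bs]
            xb, yb = x_tr[batch], y_tr[batch]
            logits = model.logits(xb, train=True, rng=rng)
            probs = softmax(logits)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch + 1}; "
                    "reduce the learning rate or check the input scale"
                )
            model.backward((probs - yb) / len(xb))
            optimizer.step()
            epoch_loss += loss * len(xb)
            epoch_correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
        history["loss"].append(epoch_loss / n_tr)
        history["accuracy"].append(epoch_correct / n_tr)
        if len(x_va):
            va_loss, va_acc = _epoch_eval(model, x_va, y_va, bs)
        else:
            va_loss, va_acc = float("nan"), float("nan")
        history["val_loss"].append(va_loss)
        history["val_accuracy"].append(va_acc)
        logger.debug(
            "epoch %d/%d loss %.4f acc %.4f val_loss %.4f val_acc %.4f",
            epoch + 1, train_config.epochs, history["loss"][-1],
            history["accuracy"][-1], va_loss, va_acc,
        )
    return TrainedModel(model=model, train_config=train_config, history=history)


def predict(model: TrainedModel | ConvGRUClassifier, windows: np.ndarray,
            batch_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities (B x K) and argmax class index per window."""
    net = model.model if isinstance(model, TrainedModel) else model
    probs = net.predict_proba(np.asarray(windows), batch_size=batch_size)
    return probs, probs.argmax(axis=1)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Single-file checkpoint: weights + spec + recipe + history."""
    net = trained.model
    meta = {
        "spec": asdict(net.spec),
        "input_length": net.input_length,
        "channels": net.channels,
        "seed": net.seed,
        "train_config": asdict(trained.train_config),
        "history": trained.history,
    }
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_arrays())
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    spec_dict = meta["spec"]
    spec_dict["conv_blocks"] = tuple(tuple(b) for b in spec_dict["conv_blocks"])
    spec_dict["gru_units"] = tuple(spec_dict["gru_units"])
    spec = ModelSpec(**spec_dict)
    net = ConvGRUClassifier(spec, meta["input_length"], meta["channels"], seed=meta["seed"])
    net.load_state_arrays(arrays)
    return TrainedModel(
        model=net,
        train_config=TrainConfig(**meta["train_config"]),
        history=meta["history"],
    )


def history_to_csv(trained: TrainedModel, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(trained.history).rename_axis("epoch").to_csv(Path(path))
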