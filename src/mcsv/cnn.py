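"""Lightweight convolutional classifier for CSV feature-map windows.

The default network is a compact six-layer CNN (three convolutions, the
first two followed by 2x2 max-pooling, then 256/128/2 dense layers with
dropout) classifying pre-ictal vs inter-ictal windows.  It is implemented
directly on numpy — forward, backprop and Adam — which keeps the dependency
footprint small and is entirely adequate for inputs of this size (a few
hundred feature rows by a few tens of segments).

Training minimises categorical cross-entropy in batches of 100 with Adam at
learning rate 0.001, and stops early once the validation error rate has
risen for ten consecutive epochs (or at the 150-epoch cap), keeping the
best-validation weights.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CNNConfig",
    "InputTensorSpec",
    "TrainedClassifier",
    "EarlyStopping",
    "SeizureCNN",
    "SubbandEnsemble",
    "build_model",
    "train",
    "predict_proba",
    "ablation_variant",
]


@dataclass
class CNNConfig:
    """Architecture and training regime of the window classifier.

    ``conv_specs`` entries are ``(kernel_h, kernel_w, filters, stride_h,
    stride_w)``; a 2x2/stride-2 max-pool follows each convolution index
    listed in ``pool_after``.
    """

    conv_specs: list[tuple[int, int, int, int, int]] = field(
        default_factory=lambda: [(3, 3, 8, 1, 1), (5, 5, 16, 1, 3), (3, 3, 32, 1, 3)]
    )
    pool_after: tuple[int, ...] = (0, 1)
    dense_units: tuple[int, ...] = (256, 128)
    n_classes: int = 2
    dropout: float = 0.5
    lr: float = 0.001
    batch_size: int = 100
    max_epochs: int = 150
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for kh, kw, f, sh, sw in self.conv_specs:
            if min(kh, kw, f, sh, sw) < 1:
                raise ValueError("kernel sizes, filter counts and strides must be positive")
        if self.n_classes != 2:
            raise ValueError("the classifier is a two-class (pre-ictal/inter-ictal) model")


@dataclass
class InputTensorSpec:
    """Geometry of one classified window.

    ``height`` is channels x bands (band rows stacked within each channel
    block) and ``width`` the number of consecutive segments per window.
    Optional per-row standardisation statistics, fitted on training folds
    only, travel with the spec.
    """

    height: int
    width: int
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.width < 4:
            raise ValueError("windows must span at least 4 segments")

    def apply_scaling(self, windows: np.ndarray) -> np.ndarray:
        if self.scale_mean is None:
            return windows
        return (windows - self.scale_mean[:, None]) / self.scale_std[:, None]


class ModelSizingError(ValueError):
    """The input is too small to survive the stride/pool chain."""


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


class _Conv2D:
    """'Same'-padded 2-D convolution, NHWC layout, arbitrary stride."""

    def __init__(self, kh, kw, cin, cout, sh, sw, rng):
        scale = math.sqrt(2.0 / (kh * kw * cin))
        self.W = rng.normal(0.0, scale, size=(kh, kw, cin, cout))
        self.b = np.zeros(cout)
        self.stride = (sh, sw)

    def out_shape(self, h, w):
        sh, sw = self.stride
        return -(-h // sh), -(-w // sw)

    def forward(self, x, training):
        kh, kw, cin, cout = self.W.shape
        sh, sw = self.stride
        n, h, w, _ = x.shape
        oh, pt, pb = _same_pad(h, kh, sh)
        ow, pl, pr = _same_pad(w, kw, sw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = np.empty((n, oh, ow, kh * kw * cin))
        for i in range(kh):
            for j in range(kw):
                block = slice((i * kw + j) * cin, (i * kw + j + 1) * cin)
                cols[..., block] = xp[:, i : i + sh * oh : sh, j : j + sw * ow : sw, :]
        self._cols, self._xp_shape = cols, xp.shape
        self._pads, self._in_hw = (pt, pl), (h, w)
        y = cols.reshape(-1, kh * kw * cin) @ self.W.reshape(-1, cout) + self.b
        return y.reshape(n, oh, ow, cout)

    def backward(self, dy):
        kh, kw, cin, cout = self.W.shape
        sh, sw = self.stride
        n, oh, ow, _ = dy.shape
        dy2 = dy.reshape(-1, cout)
        self.dW = (self._cols.reshape(-1, kh * kw * cin).T @ dy2).reshape(self.W.shape)
        self.db = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.reshape(-1, cout).T).reshape(n, oh, ow, kh * kw * cin)
        dxp = np.zeros(self._xp_shape)
        for i in range(kh):
            for j in range(kw):
                block = slice((i * kw + j) * cin, (i * kw + j + 1) * cin)
                dxp[:, i : i + sh * oh : sh, j : j + sw * ow : sw, :] += dcols[..., block]
        pt, pl = self._pads
        h, w = self._in_hw
        return dxp[:, pt : pt + h, pl : pl + w, :]

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        if oh < 1 or ow < 1:
            raise ModelSizingError("input too small for 2x2 pooling")
        xt = x[:, : 2 * oh, : 2 * ow, :].reshape(n, oh, 2, ow, 2, c)
        windows = xt.transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
        self._arg = windows.argmax(axis=-1)
        self._in_shape = x.shape
        return windows.max(axis=-1)

    def backward(self, dy):
        n, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        dx = np.zeros((n, oh, ow, c, 4))
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=-1)
        dx = dx.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * oh, 2 * ow, c)
        out = np.zeros((n, h, w, c))
        out[:, : 2 * oh, : 2 * ow, :] = dx
        return out

    def params(self):
        return []


class _Flatten:
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class _Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class SeizureCNN:
    """Sequential numpy CNN with softmax output and Adam training step."""

    def __init__(self, spec: InputTensorSpec, config: CNNConfig):
        self.spec = spec
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.layers: list = []
        self.layer_shapes: list[tuple[int, int, int]] = [(spec.height, spec.width, 1)]
        h, w, cin = spec.height, spec.width, 1
        for idx, (kh, kw, f, sh, sw) in enumerate(config.conv_specs):
            conv = _Conv2D(kh, kw, cin, f, sh, sw, self.rng)
            self.layers += [conv, _ReLU()]
            h, w = conv.out_shape(h, w)
            cin = f
            self.layer_shapes.append((h, w, cin))
            if idx in config.pool_after:
                self.layers.append(_MaxPool2())
                h, w = h // 2, w // 2
                if h < 1 or w < 1:
                    raise ModelSizingError(
                        f"after conv{idx + 1} + pooling the map is {h}x{w}; "
                        f"window of {self.spec.width} segments is too narrow "
                        "for the stride/pool chain"
                    )
                self.layer_shapes.append((h, w, cin))
        self.layers.append(_Flatten())
        n_in = h * w * cin
        for units in config.dense_units:
            self.layers += [_Dense(n_in, units, self.rng), _ReLU(), _Dropout(config.dropout, self.rng)]
            n_in = units
        self.layers.append(_Dense(n_in, config.n_classes, self.rng))
        self._adam_state: dict | None = None

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._as_nhwc(x)
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size], training=False)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out)

    def _as_nhwc(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != (self.spec.height, self.spec.width):
            raise ValueError(
                f"windows of shape {x.shape[1:]} do not match the input spec "
                f"{self.spec.height}x{self.spec.width}"
            )
        return x

    # -- training ----------------------------------------------------------
    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward(self._as_nhwc(x), training=True)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        n = len(y)
        loss = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        grad = probs
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        self._adam_step()
        return loss

    def _param_tensors(self):
        for layer in self.layers:
            for name, owner in layer.params():
                yield name, owner

    def _adam_step(self):
        cfg = self.config
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(getattr(o, n)) for n, o in self._param_tensors()],
                "v": [np.zeros_like(getattr(o, n)) for n, o in self._param_tensors()],
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (name, owner) in enumerate(self._param_tensors()):
            g = getattr(owner, "d" + name)
            st["m"][i] = b1 * st["m"][i] + (1 - b1) * g
            st["v"][i] = b2 * st["v"][i] + (1 - b2) * g * g
            mhat = st["m"][i] / (1 - b1 ** st["t"])
            vhat = st["v"][i] / (1 - b2 ** st["t"])
            setattr(owner, name, getattr(owner, name) - cfg.lr * mhat / (np.sqrt(vhat) + eps))

    # -- weights -----------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [getattr(o, n).copy() for n, o in self._param_tensors()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (name, owner), w in zip(self._param_tensors(), weights):
            setattr(owner, name, w.copy())

    def count_parameters(self) -> int:
        return sum(getattr(o, n).size for n, o in self._param_tensors())


def build_model(spec: InputTensorSpec, config: CNNConfig | None = None) -> SeizureCNN:
    """Instantiate the window classifier, validating the stride/pool chain."""
    return SeizureCNN(spec, config or CNNConfig())


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs of rising validation error."""

    def __init__(self, patience: int = 10):
        self.patience = patience
        self.prev: float | None = None
        self.rising = 0

    def update(self, error: float) -> bool:
        """Record this epoch's validation error; True means stop now."""
        if self.prev is not None and error > self.prev:
            self.rising += 1
        else:
            self.rising = 0
        self.prev = error
        return self.rising >= self.patience


@dataclass
class TrainedClassifier:
    model: SeizureCNN
    history: dict[str, list[float]]
    stopped_epoch: int
    config: CNNConfig


def _error_rate(model: SeizureCNN, X: np.ndarray, y: np.ndarray) -> float:
    pred = model.predict_proba(X).argmax(axis=1)
    return float(np.mean(pred != y))


def train(
    model: SeizureCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: CNNConfig | None = None,
    validation_metric=None,
) -> TrainedClassifier:
    """Mini-batch Adam training with early stopping on validation error.

    ``validation_metric(model, epoch) -> error`` may replace the default
    validation error rate (used e.g. to drive the stopping rule from a
    scripted sequence in tests).  The best-validation weights are restored
    before returning.
    """
    config = config or model.config
    X, y = np.asarray(train_set[0], dtype=float), np.asarray(train_set[1], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed + 1)
    stopper = EarlyStopping(config.patience)
    history: dict[str, list[float]] = {"train_loss": [], "val_error": []}
    best_err = math.inf
    best_weights = model.get_weights()
    stopped = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            losses.append(model.train_batch(X[idx], y[idx]))
        if validation_metric is not None:
            val_err = float(validation_metric(model, epoch))
        else:
            val_err = _error_rate(model, val_set[0], np.asarray(val_set[1], dtype=int))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_error"].append(val_err)
        # <= keeps the latest among equal-validation snapshots (further
        # training at unchanged validation error means lower training loss).
        if val_err <= best_err:
            best_err = val_err
            best_weights = model.get_weights()
        stopped = epoch
        if stopper.update(val_err):
            break
    model.set_weights(best_weights)
    return TrainedClassifier(model, history, stopped, copy.deepcopy(config))


def predict_proba(model: SeizureCNN, windows: np.ndarray) -> np.ndarray:
    """Pre-ictal probability per window (column 1 of the softmax output)."""
    return model.predict_proba(windows)[:, 1]


class SubbandEnsemble:
    """Per-band classifier streams fused by majority vote or averaging.

    Each stream sees only its band's rows of the feature-map window.  With
    ``fusion='vote'`` the fused label is the modal hard label (ties break
    toward inter-ictal, favouring fewer false alarms); ``fusion='average'``
    averages the streams' probabilities.
    """

    def __init__(self, models: list[SeizureCNN], row_slices: list[slice], fusion: str = "vote"):
        if fusion not in ("vote", "average"):
            raise ValueError("fusion must be 'vote' or 'average'")
        self.models = models
        self.row_slices = row_slices
        self.fusion = fusion

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        probs = np.stack(
            [m.predict_proba(windows[:, sl, :])[:, 1] for m, sl in zip(self.models, self.row_slices)]
        )
        if self.fusion == "average":
            p = probs.mean(axis=0)
        else:
            votes = (probs > 0.5).sum(axis=0)
            p = (votes > len(self.models) / 2).astype(float)  # tie -> inter-ictal
        return np.column_stack([1 - p, p])


def ablation_variant(name: str) -> dict:
    """Pipeline settings for the ablation variants.

    ``no_multiresolution``: raw-segment periodogram features only (single
    full-band row, no MRAF).  ``no_subband_voting``: per-band streams fused
    by averaging instead of majority vote.  ``shallow``: drop the third
    convolution.
    """
    variants = {
        "full": {"bands": "all", "mraf": True, "fusion": None, "conv_layers": 3},
        "no_multiresolution": {"bands": "fb", "mraf": False, "fusion": None, "conv_layers": 3},
        "no_subband_voting": {"bands": "all", "mraf": True, "fusion": "average", "conv_layers": 3},
        "subband_voting": {"bands": "all", "mraf": True, "fusion": "vote", "conv_layers": 3},
        "shallow": {"bands": "all", "mraf": True, "fusion": None, "conv_layers": 2},
    }
    if name not in variants:
        raise ValueError(f"unknown ablation variant {name!r}; choose from {sorted(variants)}")
    return {"name": name, **variants[name]}


def shallow_config(config: CNNConfig) -> CNNConfig:
    """Two-convolution variant of a config (drops the last conv layer)."""
    return CNNConfig(
        conv_specs=config.conv_specs[:2],
        pool_after=config.pool_after,
        dense_units=config.dense_units,
        n_classes=config.n_classes,
        dropout=config.dropout,
        lr=config.lr,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=config.seed,
    )
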