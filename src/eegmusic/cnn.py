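"""A small from-scratch convolutional network for windowed EEG tensors.

An EEG window of ``N_e`` electrodes by ``N_s`` samples is treated as a
single-channel gray image ``[N_e, N_s, 1]``. The default architecture is
four convolution layers (each immediately followed by a pooling layer whose
affine parameters β, b are trainable), two fully connected stages, and a
two-unit softmax head; training is plain batch gradient descent on the
cross-entropy loss, optionally with dropout on the dense stages and an L1
weight penalty. Every gradient is exact reverse-mode differentiation and is
verified against central finite differences in the test suite.

All computation is numpy; batches are arrays of shape
``(batch, maps, height, width)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .recording import EEGRecording

__all__ = [
    "LayerSpec",
    "CNNModel",
    "default_architecture",
    "validate_architecture",
    "to_input_tensor",
    "tensor_to_recording",
    "conv_forward",
    "pool_forward",
    "softmax_out",
    "cross_entropy",
    "backward_and_update",
    "train_cnn",
    "predict_proba",
]

_ACTIVATIONS = ("relu", "sigmoid", "tanh", "linear")


# ---------------------------------------------------------------------------
# Specs and validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one network layer."""

    kind: str  # conv | pool | fc | softmax_out
    kernel: tuple[int, int] = (1, 1)  # conv kernel or pool window (h, w)
    n_filters: int = 1  # conv filters, or fc/softmax output units
    activation: str = "relu"
    pool_mode: str = "max"  # max | avg
    dropout_p: float = 0.0
    l1_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "pool", "fc", "softmax_out"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel[0] < 1 or self.kernel[1] < 1:
            raise ValueError("kernel dimensions must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be non-negative")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.pool_mode not in ("max", "avg"):
            raise ValueError(f"unknown pool_mode {self.pool_mode!r}")


def validate_architecture(specs: Sequence[LayerSpec]) -> None:
    """Enforce the conv/pool alternation and the softmax head.

    Every conv layer must be immediately followed by a pool layer, pools may
    only follow convs, dense stages come after all conv/pool pairs, and the
    last layer must be a 2-unit (or k-unit) softmax output.
    """
    if not specs or specs[-1].kind != "softmax_out":
        raise ValueError("architecture must end in a softmax_out layer")
    seen_fc = False
    for i, spec in enumerate(specs[:-1]):
        if spec.kind == "conv":
            if seen_fc:
                raise ValueError("conv layer after dense stage")
            if i + 1 >= len(specs) or specs[i + 1].kind != "pool":
                raise ValueError("every conv layer must be followed by a pool layer")
        elif spec.kind == "pool":
            if i == 0 or specs[i - 1].kind != "conv":
                raise ValueError("pool layers may only follow conv layers")
        elif spec.kind == "fc":
            seen_fc = True


def default_architecture(
    filters: Sequence[int] = (8, 16, 32, 64),
    kernel: tuple[int, int] = (1, 7),
    pool: tuple[int, int] = (1, 2),
    fc_units: Sequence[int] = (64, 16),
    dropout_p: float = 0.2,
    l1_lambda: float = 0.0,
    n_classes: int = 2,
) -> list[LayerSpec]:
    """Four conv+pool stages, two ReLU dense stages, softmax pair."""
    specs: list[LayerSpec] = []
    for f in filters:
        specs.append(LayerSpec("conv", kernel=kernel, n_filters=f, activation="relu"))
        specs.append(LayerSpec("pool", kernel=pool, n_filters=f, pool_mode="max"))
    for i, u in enumerate(fc_units):
        specs.append(
            LayerSpec(
                "fc",
                n_filters=u,
                activation="relu",
                dropout_p=dropout_p if i == 0 else 0.0,
                l1_lambda=l1_lambda,
            )
        )
    specs.append(LayerSpec("softmax_out", n_filters=n_classes, l1_lambda=l1_lambda))
    validate_architecture(specs)
    return specs


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(0.0, z)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "tanh":
        return np.tanh(z)
    return z


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "tanh":
        return 1.0 - a**2
    return np.ones_like(z)


# ---------------------------------------------------------------------------
# Layer kernels (batch-first)
# ---------------------------------------------------------------------------


class _ConvLayer:
    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        kh, kw = spec.kernel
        self.spec = spec
        # He-style fan-in scaling
        scale = np.sqrt(2.0 / (n_in * kh * kw))
        self.W = rng.normal(0.0, scale, size=(spec.n_filters, n_in, kh, kw))
        self.b = np.zeros(spec.n_filters)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        kh, kw = self.spec.kernel
        if kh > h or kw > w:
            raise ValueError(f"kernel {self.spec.kernel} larger than input {(h, w)}")
        return (self.spec.n_filters, h - kh + 1, w - kw + 1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        kh, kw = self.spec.kernel
        if kh > x.shape[2] or kw > x.shape[3]:
            raise ValueError(f"kernel {self.spec.kernel} larger than input {x.shape[2:]}")
        windows = sliding_window_view(x, (kh, kw), axis=(2, 3))
        z = np.einsum("bcijhw,fchw->bfij", windows, self.W, optimize=True)
        z += self.b[None, :, None, None]
        a = _act(z, self.spec.activation)
        self._cache = (x, z, a)
        return a

    def backward(self, da: np.ndarray):
        x, z, a = self._cache
        kh, kw = self.spec.kernel
        dz = da * _act_grad(z, a, self.spec.activation)
        windows = sliding_window_view(x, (kh, kw), axis=(2, 3))
        self.dW = np.einsum("bcijhw,bfij->fchw", windows, dz, optimize=True)
        self.db = dz.sum(axis=(0, 2, 3))
        pad = ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1))
        dz_pad = np.pad(dz, pad)
        win2 = sliding_window_view(dz_pad, (kh, kw), axis=(2, 3))
        w_flip = self.W[:, :, ::-1, ::-1]
        return np.einsum("bfijhw,fchw->bcij", win2, w_flip, optimize=True)

    def params(self):
        return [("W", self.W, "dW", self.spec.l1_lambda), ("b", self.b, "db", 0.0)]


class _PoolLayer:
    """Max/avg pooling followed by the trainable affine β·pooled + b per map.

    Inputs whose spatial dims are not multiples of the pool window are
    zero-padded on the right/bottom before pooling.
    """

    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        self.spec = spec
        self.beta = np.ones(n_in)
        self.b = np.zeros(n_in)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        ph, pw = self.spec.kernel
        return (c, -(-h // ph), -(-w // pw))

    def _pad(self, x):
        ph, pw = self.spec.kernel
        h, w = x.shape[2], x.shape[3]
        pad_h = (-h) % ph
        pad_w = (-w) % pw
        if pad_h or pad_w:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
        return x

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ph, pw = self.spec.kernel
        xp = self._pad(x)
        B, C, H, W = xp.shape
        xr = xp.reshape(B, C, H // ph, ph, W // pw, pw).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // ph, W // pw, ph * pw)
        if self.spec.pool_mode == "max":
            idx = np.argmax(xr, axis=-1)
            pooled = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
            self._idx = idx
        else:
            pooled = xr.mean(axis=-1)
        self._in_shape = x.shape
        self._pad_shape = xp.shape
        self._pooled = pooled
        return pooled * self.beta[None, :, None, None] + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray):
        ph, pw = self.spec.kernel
        B, C, H, W = self._pad_shape
        self.dbeta = np.einsum("bcij,bcij->c", dout, self._pooled)
        self.db = dout.sum(axis=(0, 2, 3))
        dpooled = dout * self.beta[None, :, None, None]
        dxr = np.zeros((B, C, H // ph, W // pw, ph * pw))
        if self.spec.pool_mode == "max":
            np.put_along_axis(dxr, self._idx[..., None], dpooled[..., None], axis=-1)
        else:
            dxr[...] = (dpooled / (ph * pw))[..., None]
        dxp = dxr.reshape(B, C, H // ph, W // pw, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        dxp = dxp.reshape(B, C, H, W)
        _, _, h0, w0 = self._in_shape
        return dxp[:, :, :h0, :w0]

    def params(self):
        return [("beta", self.beta, "dbeta", 0.0), ("b", self.b, "db", 0.0)]


class _DenseLayer:
    """Fully connected layer with optional inverted dropout on its output."""

    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        self.spec = spec
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, spec.n_filters))
        self.b = np.zeros(spec.n_filters)

    def out_shape(self, in_shape):
        return (self.spec.n_filters,)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        flat = x.reshape(x.shape[0], -1)
        z = flat @ self.W + self.b
        a = _act(z, self.spec.activation)
        mask = None
        if train and self.spec.dropout_p > 0.0 and rng is not None:
            mask = (rng.random(a.shape) >= self.spec.dropout_p) / (1.0 - self.spec.dropout_p)
            a = a * mask
        self._cache = (x.shape, flat, z, _act(z, self.spec.activation), mask)
        return a

    def backward(self, da: np.ndarray):
        in_shape, flat, z, a, mask = self._cache
        if mask is not None:
            da = da * mask
        dz = da * _act_grad(z, a, self.spec.activation)
        self.dW = flat.T @ dz
        self.db = dz.sum(axis=0)
        return (dz @ self.W.T).reshape(in_shape)

    def params(self):
        return [("W", self.W, "dW", self.spec.l1_lambda), ("b", self.b, "db", 0.0)]


class _SoftmaxOutLayer(_DenseLayer):
    """Linear map to class logits; softmax/loss handled by the model."""

    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        spec = LayerSpec(
            kind="softmax_out",
            n_filters=spec.n_filters,
            activation="linear",
            l1_lambda=spec.l1_lambda,
        )
        super().__init__(spec, n_in, rng)


_LAYER_CLASSES = {
    "conv": _ConvLayer,
    "pool": _PoolLayer,
    "fc": _DenseLayer,
    "softmax_out": _SoftmaxOutLayer,
}


# ---------------------------------------------------------------------------
# Functional surface (single sample), reused by the model internals
# ---------------------------------------------------------------------------


def to_input_tensor(rec: EEGRecording) -> np.ndarray:
    """Recording -> ``[N_e, N_s, 1]`` tensor (values copied unchanged)."""
    return rec.data[:, :, None].copy()


def tensor_to_recording(tensor: np.ndarray, fs: float, channel_labels=()) -> EEGRecording:
    """Inverse of :func:`to_input_tensor`."""
    t = np.asarray(tensor)
    if t.ndim != 3 or t.shape[2] != 1:
        raise ValueError("expected a tensor of shape (N_e, N_s, 1)")
    return EEGRecording(data=t[:, :, 0].copy(), fs=fs, channel_labels=tuple(channel_labels))


def conv_forward(maps: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "relu") -> np.ndarray:
    """Valid-mode convolution of input maps with shared weights.

    ``maps``: (n_in, H, W); ``W``: (n_out, n_in, kh, kw); ``b``: (n_out,).
    Output map j is ``activation(sum_i maps_i * W_j,i + b_j)``.
    """
    maps = np.asarray(maps, dtype=float)
    W = np.asarray(W, dtype=float)
    kh, kw = W.shape[2], W.shape[3]
    if kh > maps.shape[1] or kw > maps.shape[2]:
        raise ValueError(f"kernel {(kh, kw)} larger than input {maps.shape[1:]}")
    windows = sliding_window_view(maps, (kh, kw), axis=(1, 2))
    z = np.einsum("cijhw,fchw->fij", windows, W, optimize=True) + np.asarray(b)[:, None, None]
    return _act(z, activation)


def pool_forward(
    maps: np.ndarray,
    size: tuple[int, int],
    mode: str = "max",
    beta: float | np.ndarray = 1.0,
    b: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Per-window max/avg pooling then the affine ``beta * pooled + b``."""
    maps = np.asarray(maps, dtype=float)[None]  # fake batch dim
    spec = LayerSpec("pool", kernel=tuple(size), pool_mode=mode, n_filters=maps.shape[1])
    layer = _PoolLayer(spec, maps.shape[1], np.random.default_rng(0))
    layer.beta = np.broadcast_to(np.asarray(beta, dtype=float), (maps.shape[1],)).copy()
    layer.b = np.broadcast_to(np.asarray(b, dtype=float), (maps.shape[1],)).copy()
    return layer.forward(maps, train=False)[0]


def softmax_out(features: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine map to logits then a numerically stable softmax."""
    logits = np.asarray(features, dtype=float) @ np.asarray(W) + np.asarray(b)
    return _softmax(np.atleast_2d(logits))[0] if logits.ndim == 1 else _softmax(logits)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy ``-(1/N) sum_n sum_i y_i log a_i``.

    ``predictions`` are probability rows, ``labels`` one-hot rows (or integer
    class ids). Probabilities are clipped at 1e-12 with a warning-free floor.
    """
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    y = np.asarray(labels)
    if y.ndim == 1 and y.shape[0] == p.shape[0]:
        onehot = np.zeros_like(p)
        onehot[np.arange(p.shape[0]), y.astype(int)] = 1.0
        y = onehot
    y = np.atleast_2d(y)
    p = np.clip(p, 1e-12, 1.0)
    return float(-(y * np.log(p)).sum() / p.shape[0])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class CNNModel:
    """Layer specs + live layer objects + training state."""

    specs: list[LayerSpec]
    input_shape: tuple[int, int]  # (N_e, N_s)
    learning_rate: float = 0.01
    seed: int = 0
    layers: list = field(default_factory=list, repr=False)
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_architecture(self.specs)
        if not self.layers:
            rng = np.random.default_rng(self.seed)
            shape = (1, *self.input_shape)  # one input map
            flat_from = None
            for spec in self.specs:
                if spec.kind in ("fc", "softmax_out"):
                    n_in = int(np.prod(shape)) if flat_from is None else flat_from
                    layer = _LAYER_CLASSES[spec.kind](spec, n_in, rng)
                    flat_from = spec.n_filters
                else:
                    layer = _LAYER_CLASSES[spec.kind](spec, shape[0], rng)
                    shape = layer.out_shape(shape)
                self.layers.append(layer)
        self._dropout_rng = np.random.default_rng(self.seed + 1)

    # -- forward/backward ---------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities for a batch of windows ``(B, N_e, N_s)``."""
        a = np.asarray(X, dtype=float)[:, None, :, :]  # single input map
        for layer in self.layers:
            if isinstance(layer, _DenseLayer):
                a = layer.forward(a, train, rng=self._dropout_rng if train else None)
            else:
                a = layer.forward(a, train)
        return _softmax(a)

    def features(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations (input to the softmax head), eval mode."""
        a = np.asarray(X, dtype=float)[:, None, :, :]
        for layer in self.layers[:-1]:
            a = layer.forward(a, train=False)
        return a.reshape(a.shape[0], -1)

    def l1_penalty(self) -> float:
        total = 0.0
        for layer in self.layers:
            for _, arr, _, lam in layer.params():
                if lam > 0:
                    total += lam * float(np.abs(arr).sum())
        return total

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, train: bool = False) -> float:
        """Forward + backward; leaves gradients on the layers, returns loss."""
        probs = self.forward(X, train=train)
        B = probs.shape[0]
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), np.asarray(y, dtype=int)] = 1.0
        loss = cross_entropy(probs, onehot) + self.l1_penalty()
        grad = (probs - onehot) / B  # d loss / d logits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        # add L1 subgradients
        for layer in self.layers:
            for name, arr, gname, lam in layer.params():
                if lam > 0:
                    g = getattr(layer, gname)
                    g += lam * np.sign(arr)
        return loss

    def sgd_step(self) -> None:
        for layer in self.layers:
            for name, arr, gname, _ in layer.params():
                g = getattr(layer, gname)
                if not np.isfinite(g).all():
                    raise FloatingPointError(f"non-finite gradient in {gname}; aborting training")
                arr -= self.learning_rate * g

    def sum_abs_weights(self) -> float:
        return float(sum(np.abs(arr).sum() for layer in self.layers for _, arr, _, _ in layer.params()))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "specs": [vars(s) | {"kernel": list(s.kernel)} for s in self.specs],
            "input_shape": list(self.input_shape),
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "trained": self.trained,
            "loss_history": self.loss_history,
            "params": [
                {name: arr.tolist() for name, arr, _, _ in layer.params()}
                for layer in self.layers
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CNNModel":
        specs = [
            LayerSpec(**{**s, "kernel": tuple(s["kernel"])}) for s in d["specs"]
        ]
        model = cls(
            specs=specs,
            input_shape=tuple(d["input_shape"]),
            learning_rate=d["learning_rate"],
            seed=d["seed"],
        )
        for layer, saved in zip(model.layers, d["params"]):
            for name, arr, _, _ in layer.params():
                arr[...] = np.asarray(saved[name])
        model.trained = d["trained"]
        model.loss_history = list(d["loss_history"])
        return model

    @classmethod
    def load(cls, path) -> "CNNModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def backward_and_update(model: CNNModel, batch: tuple[np.ndarray, np.ndarray]) -> float:
    """One full forward/backward pass and gradient-descent update.

    Returns the (pre-update) training loss on the batch.
    """
    X, y = batch
    loss = model.loss_and_grads(X, y, train=True)
    model.sgd_step()
    return loss


def train_cnn(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[LayerSpec] | None = None,
    epochs: int = 100,
    learning_rate: float = 0.01,
    seed: int = 0,
) -> CNNModel:
    """Train on windows ``(B, N_e, N_s)`` with binary labels by batch GD.

    Deterministic under ``seed`` (weight init and dropout streams both derive
    from it). Raises on single-class data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 3:
        raise ValueError("X must be (batch, channels, samples)")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    specs = specs or default_architecture()
    model = CNNModel(
        specs=specs,
        input_shape=(X.shape[1], X.shape[2]),
        learning_rate=learning_rate,
        seed=seed,
    )
    for _ in range(epochs):
        loss = backward_and_update(model, (X, y))
        model.loss_history.append(loss)
    model.trained = True
    return model


def predict_proba(model: CNNModel, X: np.ndarray) -> np.ndarray:
    """Class-probability rows for a batch of windows (eval mode, no dropout)."""
    return model.forward(np.asarray(X, dtype=float), train=False)
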