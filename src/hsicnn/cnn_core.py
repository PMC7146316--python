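"""Convolutional network primitives and the 1D/2D architectures.

Everything is implemented directly on numpy arrays (forward and backward
passes, Adam updates) so each layer is an auditable formula:

* ``convp`` block = convolution with kernel 2 (1D) or 2×2 (2D), batch
  normalization, ReLU, and non-overlapping maxpooling of stride 2;
* batch normalization computes the per-feature mini-batch mean and
  (population) variance, normalizes with an ``eps`` guard, and applies
  the learned affine scale/offset (gamma, beta); inference uses running
  statistics so predictions do not depend on batch composition;
* the classification head is a fully connected layer into a softmax,
  trained with cross-entropy.

Both architectures cascade ``depth`` convp blocks of 20 filters: the
first takes the raw channel count (1 spectrum channel, or Q principal
components), the rest take 20 feature maps, and the fully connected
layer has ``20 * N''`` (1D) or ``20 * R'' * R''`` (2D) inputs, where
``N''``/``R''`` is the spatial size left after the pooling cascade.
Convolutions use same-size output via edge-replicate padding, and a
trailing partial pooling window is floor-truncated, which makes the
shape arithmetic exact: each block halves the spatial size (floor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .preprocess import Preprocessor, make_batches

__all__ = [
    "BatchNormState",
    "NetworkSpec",
    "ConvBlockSpec",
    "TrainConfig",
    "TrainedModel",
    "DivergenceError",
    "batch_norm_forward",
    "relu",
    "maxpool",
    "conv1d_forward",
    "conv2d_forward",
    "softmax",
    "build_spec_1d",
    "build_spec_2d",
    "Network",
    "train",
    "predict_proba",
    "predict_labels",
    "save_model",
    "load_model",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


# --------------------------------------------------------------------------
# Functional layer primitives
# --------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, y = max{0, x}, elementwise."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalized exponential along ``axis``, computed stably (max shift)."""
    x = np.asarray(x, dtype=float)
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def maxpool(x: np.ndarray, ell: int = 2) -> np.ndarray:
    """Non-overlapping max pooling with window/stride ``ell``.

    1D input pools along its only axis; 2D input pools an ``ell``×``ell``
    window over both axes.  A trailing partial window is floor-truncated;
    the pooled size is ``floor(len / ell)`` per pooled axis, which must
    be at least 1.
    """
    if ell < 2:
        raise ValueError(f"pooling window must be >= 2, got {ell}")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        n = x.shape[0] // ell
        if n < 1:
            raise ValueError(f"input of length {x.shape[0]} is shorter than the pooling window {ell}")
        return x[: n * ell].reshape(n, ell).max(axis=1)
    if x.ndim == 2:
        h, w = x.shape[0] // ell, x.shape[1] // ell
        if h < 1 or w < 1:
            raise ValueError(f"input {x.shape} is smaller than the pooling window {ell}x{ell}")
        return x[: h * ell, : w * ell].reshape(h, ell, w, ell).max(axis=(1, 3))
    raise ValueError("maxpool expects a 1D or 2D array")


def _windows_1d(x: np.ndarray) -> np.ndarray:
    """Kernel-2 sliding windows with edge-replicate right padding.

    x: (B, C, L) → (B, C, L, 2); output position i covers x[i], x[i+1]
    with x[L] replicated from x[L-1], so the output length equals L.
    """
    xp = np.concatenate([x, x[:, :, -1:]], axis=2)
    return np.stack([xp[:, :, :-1], xp[:, :, 1:]], axis=3)


def _windows_2d(x: np.ndarray) -> np.ndarray:
    """2×2 sliding windows with edge-replicate right/bottom padding.

    x: (B, C, H, W) → (B, C, H, W, 2, 2).
    """
    xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)), mode="edge")
    h, w = x.shape[2], x.shape[3]
    return np.stack(
        [
            np.stack([xp[:, :, :h, :w], xp[:, :, :h, 1 : w + 1]], axis=4),
            np.stack([xp[:, :, 1 : h + 1, :w], xp[:, :, 1 : h + 1, 1 : w + 1]], axis=4),
        ],
        axis=4,
    )


def conv1d_forward(inputs: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Cross-correlation of C input maps with n kernels of size 2 ("same").

    inputs (C, L), weights (n, C, 2), bias (n,) → (n, L).  Edge-replicate
    padding keeps the output length equal to the input length.
    """
    inputs = np.asarray(inputs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if inputs.ndim != 2:
        raise ValueError("inputs must be (channels, length)")
    if weights.ndim != 3 or weights.shape[2] != 2:
        raise ValueError("weights must be (filters, channels, 2)")
    if inputs.shape[0] != weights.shape[1]:
        raise ValueError(
            f"channel mismatch: inputs have {inputs.shape[0]}, filters expect {weights.shape[1]}"
        )
    win = _windows_1d(inputs[None])[0]  # (C, L, 2)
    return np.einsum("clk,nck->nl", win, weights) + np.asarray(bias, dtype=float)[:, None]


def conv2d_forward(inputs: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Cross-correlation with n kernels of size 2×2 ("same" output).

    inputs (C, H, W), weights (n, C, 2, 2), bias (n,) → (n, H, W).
    """
    inputs = np.asarray(inputs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if inputs.ndim != 3:
        raise ValueError("inputs must be (channels, height, width)")
    if weights.ndim != 4 or weights.shape[2:] != (2, 2):
        raise ValueError("weights must be (filters, channels, 2, 2)")
    if inputs.shape[0] != weights.shape[1]:
        raise ValueError(
            f"channel mismatch: inputs have {inputs.shape[0]}, filters expect {weights.shape[1]}"
        )
    win = _windows_2d(inputs[None])[0]  # (C, H, W, 2, 2)
    return np.einsum("chwij,ncij->nhw", win, weights) + np.asarray(bias, dtype=float)[:, None, None]


# --------------------------------------------------------------------------
# Batch normalization
# --------------------------------------------------------------------------

@dataclass
class BatchNormState:
    """Learned affine (gamma, beta) plus running statistics per feature."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.1

    @classmethod
    def create(cls, n_features: int, eps: float = 1e-5, momentum: float = 0.1) -> "BatchNormState":
        if eps <= 0:
            raise ValueError("eps must be positive")
        return cls(
            gamma=np.ones(n_features),
            beta=np.zeros(n_features),
            running_mean=np.zeros(n_features),
            running_var=np.ones(n_features),
            eps=eps,
            momentum=momentum,
        )


def batch_norm_forward(
    batch: np.ndarray, state: BatchNormState, mode: str = "train"
) -> np.ndarray:
    """Batch-normalize a mini-batch of feature vectors or feature maps.

    The feature axis is axis 1 (a plain (M', F) batch of vectors has one
    statistic per feature; conv feature maps (B, C, ...) share statistics
    over batch and spatial positions, one per channel).  Train mode uses
    the mini-batch mean and population variance and updates the running
    statistics in place; infer mode uses the stored running statistics.
    """
    x = np.asarray(batch, dtype=float)
    if x.ndim < 2:
        raise ValueError("batch must have at least (samples, features) axes")
    axes = (0,) + tuple(range(2, x.ndim))
    shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError("train-mode batch normalization needs at least 2 samples")
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        m = state.momentum
        state.running_mean = (1 - m) * state.running_mean + m * mean
        state.running_var = (1 - m) * state.running_var + m * var
    elif mode == "infer":
        mean, var = state.running_mean, state.running_var
    else:
        raise ValueError(f"unknown mode {mode!r}")
    xhat = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + state.eps)
    return state.gamma.reshape(shape) * xhat + state.beta.reshape(shape)


# --------------------------------------------------------------------------
# Network specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """One convp block: conv(kernel 2 / 2×2) + BN + ReLU + maxpool(2)."""

    in_channels: int
    filters: int


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of a 1D or 2D architecture.

    ``feature_size`` is the spatial size surviving the pooling cascade
    (N'' for 1D, R'' per side for 2D); the fully connected layer then has
    ``filters * N''`` or ``filters * R''**2`` inputs and M outputs.
    """

    dimensionality: str  # "1d" | "2d"
    input_size: int | tuple[int, int, int]
    n_classes: int
    blocks: tuple[ConvBlockSpec, ...]
    feature_size: int
    fc_in: int

    def to_dict(self) -> dict:
        return {
            "dimensionality": self.dimensionality,
            "input_size": self.input_size if isinstance(self.input_size, int) else list(self.input_size),
            "n_classes": self.n_classes,
            "blocks": [[b.in_channels, b.filters] for b in self.blocks],
            "feature_size": self.feature_size,
            "fc_in": self.fc_in,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        input_size = d["input_size"]
        if isinstance(input_size, list):
            input_size = tuple(input_size)
        return cls(
            dimensionality=d["dimensionality"],
            input_size=input_size,
            n_classes=d["n_classes"],
            blocks=tuple(ConvBlockSpec(c, f) for c, f in d["blocks"]),
            feature_size=d["feature_size"],
            fc_in=d["fc_in"],
        )


def build_spec_1d(N: int, M: int, depth: int = 4, filters: int = 20) -> NetworkSpec:
    """The 1D chain: convp-20(1×2), then depth−1 convp-20(20×2), then FC.

    Same-padding convolutions keep the length, each pooling halves it
    (floor), so N'' after the cascade is N floor-halved ``depth`` times;
    the FC layer has ``filters * N''`` inputs and M outputs.
    """
    if M < 2:
        raise ValueError(f"need at least 2 classes, got {M}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    size = int(N)
    if size < 1:
        raise ValueError(f"input length must be >= 1, got {N}")
    blocks = []
    for d in range(depth):
        blocks.append(ConvBlockSpec(in_channels=1 if d == 0 else filters, filters=filters))
        size //= 2
        if size < 1:
            raise ValueError(
                f"input length {N} collapses below 1 at conv block {d + 1} of {depth}"
            )
    return NetworkSpec("1d", int(N), M, tuple(blocks), size, filters * size)


def build_spec_2d(R: int, Q: int, M: int, depth: int = 4, filters: int = 20) -> NetworkSpec:
    """The 2D chain: convp-20(Q×2×2), then depth−1 convp-20(20×2×2), then FC.

    The FC layer has ``filters * R'' * R''`` inputs, where R'' is the side
    left after ``depth`` floor-halvings of R.
    """
    if M < 2:
        raise ValueError(f"need at least 2 classes, got {M}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if R < 1 or R % 2 == 0:
        raise ValueError(f"R must be an odd positive integer, got {R}")
    if Q < 1:
        raise ValueError(f"Q must be >= 1, got {Q}")
    size = int(R)
    blocks = []
    for d in range(depth):
        blocks.append(ConvBlockSpec(in_channels=Q if d == 0 else filters, filters=filters))
        size //= 2
        if size < 1:
            raise ValueError(
                f"patch side {R} collapses below 1 at conv block {d + 1} of {depth}"
            )
    return NetworkSpec("2d", (int(R), int(R), int(Q)), M, tuple(blocks), size, filters * size * size)


# --------------------------------------------------------------------------
# Layers with backprop
# --------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Conv1d:
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * 2))
        self.w = _Param(rng.normal(0.0, scale, size=(in_ch * 2, out_ch)))
        self.b = _Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        B, C, L = x.shape
        win = _windows_1d(x)  # (B, C, L, 2)
        cols = win.transpose(0, 2, 1, 3).reshape(B * L, C * 2)
        self._cache = (cols, (B, C, L))
        y = cols @ self.w.value + self.b.value
        return y.reshape(B, L, self.out_ch).transpose(0, 2, 1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (B, C, L) = self._cache
        g = gy.transpose(0, 2, 1).reshape(B * L, self.out_ch)
        self.w.grad += cols.T @ g
        self.b.grad += g.sum(axis=0)
        gwin = (g @ self.w.value.T).reshape(B, L, C, 2).transpose(0, 2, 1, 3)
        gxp = np.zeros((B, C, L + 1))
        gxp[:, :, :L] += gwin[..., 0]
        gxp[:, :, 1:] += gwin[..., 1]
        gx = gxp[:, :, :L].copy()
        gx[:, :, L - 1] += gxp[:, :, L]  # fold the replicated edge back
        return gx

    def params(self):
        return [self.w, self.b]


class _Conv2d:
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * 4))
        self.w = _Param(rng.normal(0.0, scale, size=(in_ch * 4, out_ch)))
        self.b = _Param(np.zeros(out_ch))
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        B, C, H, W = x.shape
        win = _windows_2d(x)  # (B, C, H, W, 2, 2)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * 4)
        self._cache = (cols, (B, C, H, W))
        y = cols @ self.w.value + self.b.value
        return y.reshape(B, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W) = self._cache
        g = gy.transpose(0, 2, 3, 1).reshape(B * H * W, self.out_ch)
        self.w.grad += cols.T @ g
        self.b.grad += g.sum(axis=0)
        gwin = (g @ self.w.value.T).reshape(B, H, W, C, 2, 2).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros((B, C, H + 1, W + 1))
        gxp[:, :, :H, :W] += gwin[..., 0, 0]
        gxp[:, :, :H, 1:] += gwin[..., 0, 1]
        gxp[:, :, 1:, :W] += gwin[..., 1, 0]
        gxp[:, :, 1:, 1:] += gwin[..., 1, 1]
        gx = gxp[:, :, :H, :W].copy()
        gx[:, :, H - 1, :] += gxp[:, :, H, :W]
        gx[:, :, :, W - 1] += gxp[:, :, :H, W]
        gx[:, :, H - 1, W - 1] += gxp[:, :, H, W]
        return gx

    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.state = BatchNormState.create(channels, eps=eps, momentum=momentum)
        self.gamma = _Param(self.state.gamma)
        self.beta = _Param(self.state.beta)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        st = self.state
        st.gamma, st.beta = self.gamma.value, self.beta.value
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
        if train:
            if x.shape[0] < 2:
                raise ValueError("train-mode batch normalization needs at least 2 samples")
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = st.momentum
            st.running_mean = (1 - m) * st.running_mean + m * mean
            st.running_var = (1 - m) * st.running_var + m * var
        else:
            mean, var = st.running_mean, st.running_var
        std = np.sqrt(var + st.eps)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        self._cache = (xhat, std, axes, shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, std, axes, shape = self._cache
        m = float(np.prod([gy.shape[a] for a in axes]))
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        gxhat = gy * self.gamma.value.reshape(shape)
        # gradient through the batch statistics (train mode)
        mean_g = gxhat.mean(axis=axes).reshape(shape)
        mean_gx = (gxhat * xhat).mean(axis=axes).reshape(shape)
        return (gxhat - mean_g - xhat * mean_gx) / std.reshape(shape)

    def params(self):
        return [self.gamma, self.beta]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask

    def params(self):
        return []


class _MaxPool1d:
    def __init__(self, ell: int = 2):
        self.ell = ell

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        n = L // self.ell
        if n < 1:
            raise RuntimeError(
                f"feature map of length {L} is shorter than the pooling window "
                f"{self.ell}; the architecture builder should have prevented this"
            )
        xt = x[:, :, : n * self.ell].reshape(B, C, n, self.ell)
        self._idx = xt.argmax(axis=3)
        self._shape = (B, C, L, n)
        return np.take_along_axis(xt, self._idx[..., None], axis=3)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, L, n = self._shape
        gxt = np.zeros((B, C, n, self.ell))
        np.put_along_axis(gxt, self._idx[..., None], gy[..., None], axis=3)
        gx = np.zeros((B, C, L))
        gx[:, :, : n * self.ell] = gxt.reshape(B, C, n * self.ell)
        return gx

    def params(self):
        return []


class _MaxPool2d:
    def __init__(self, ell: int = 2):
        self.ell = ell

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        h, w = H // self.ell, W // self.ell
        if h < 1 or w < 1:
            raise RuntimeError(
                f"feature map {H}x{W} is smaller than the pooling window "
                f"{self.ell}x{self.ell}; the architecture builder should have prevented this"
            )
        xt = (
            x[:, :, : h * self.ell, : w * self.ell]
            .reshape(B, C, h, self.ell, w, self.ell)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, h, w, self.ell * self.ell)
        )
        self._idx = xt.argmax(axis=4)
        self._shape = (B, C, H, W, h, w)
        return np.take_along_axis(xt, self._idx[..., None], axis=4)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, H, W, h, w = self._shape
        ell = self.ell
        gxt = np.zeros((B, C, h, w, ell * ell))
        np.put_along_axis(gxt, self._idx[..., None], gy[..., None], axis=4)
        gx = np.zeros((B, C, H, W))
        gx[:, :, : h * ell, : w * ell] = (
            gxt.reshape(B, C, h, w, ell, ell).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, h * ell, w * ell)
        )
        return gx

    def params(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = _Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = _Param(np.zeros(n_out))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.w.value.shape[0]:
            raise ValueError(
                f"fully connected layer expects {self.w.value.shape[0]} inputs, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T

    def params(self):
        return [self.w, self.b]


# --------------------------------------------------------------------------
# Network assembly
# --------------------------------------------------------------------------

class Network:
    """A concrete parameterized network built from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, eps: float = 1e-5, momentum: float = 0.1):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list = []
        conv_cls = _Conv1d if spec.dimensionality == "1d" else _Conv2d
        pool_cls = _MaxPool1d if spec.dimensionality == "1d" else _MaxPool2d
        for block in spec.blocks:
            self.layers.append(conv_cls(block.in_channels, block.filters, rng))
            self.layers.append(_BatchNorm(block.filters, eps=eps, momentum=momentum))
            self.layers.append(_ReLU())
            self.layers.append(pool_cls(2))
        self.layers.append(_Flatten())
        self.layers.append(_Dense(spec.fc_in, spec.n_classes, rng))

    def _shape_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.spec.dimensionality == "1d":
            if X.ndim != 2 or X.shape[1] != self.spec.input_size:
                raise ValueError(
                    f"1D network expects (batch, {self.spec.input_size}) inputs, got {X.shape}"
                )
            return X[:, None, :]  # one input channel
        R, _, Q = self.spec.input_size
        if X.ndim != 4 or X.shape[1:] != (R, R, Q):
            raise ValueError(f"2D network expects (batch, {R}, {R}, {Q}) inputs, got {X.shape}")
        return X.transpose(0, 3, 1, 2)  # channels first

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        h = self._shape_inputs(X)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h  # logits (batch, M)

    def backward(self, glogits: np.ndarray) -> None:
        g = glogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self) -> list[_Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- serialization ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.value
        bn_i = 0
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                arrays[f"bn_mean_{bn_i}"] = layer.state.running_mean
                arrays[f"bn_var_{bn_i}"] = layer.state.running_var
                bn_i += 1
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            value = arrays[f"param_{i}"]
            if value.shape != p.value.shape:
                raise ValueError(f"param_{i} shape {value.shape} != expected {p.value.shape}")
            p.value[...] = value
        bn_i = 0
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.state.running_mean = arrays[f"bn_mean_{bn_i}"].copy()
                layer.state.running_var = arrays[f"bn_var_{bn_i}"].copy()
                bn_i += 1


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the benchmark protocol
    (mini-batches of 16 over 200 epochs) with an Adam optimizer."""

    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 2:
            raise ValueError(f"batch_size must be >= 2, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


class _Adam:
    def __init__(self, params: list[_Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits, axis=1)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), targets] + eps))
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


def train(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[TrainConfig] = None,
) -> tuple[Network, list[float]]:
    """Fit a network by mini-batch gradient descent on cross-entropy.

    ``y`` holds 1-based class labels.  Deterministic for a given config
    seed (weight init and batch shuffling both derive from it).  Returns
    the fitted network and the per-epoch mean training loss.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class; need at least 2")
    if y.min() < 1 or y.max() > spec.n_classes:
        raise ValueError(f"labels must lie in 1..{spec.n_classes}")
    ss = np.random.SeedSequence(config.seed)
    init_ss, batch_ss = ss.spawn(2)
    net = Network(
        spec,
        seed=int(init_ss.generate_state(1)[0] % 2**31),
        eps=config.bn_eps,
        momentum=config.bn_momentum,
    )
    optimizer = _Adam(net.parameters(), lr=config.learning_rate)
    targets = y - 1
    batch_rng = np.random.default_rng(batch_ss)
    history: list[float] = []
    for epoch in range(config.epochs):
        losses = []
        for idx in make_batches(len(X), config.batch_size, batch_rng):
            net.zero_grad()
            logits = net.forward(X[idx], train=True)
            loss, glogits = _cross_entropy(logits, targets[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch + 1}")
            net.backward(glogits)
            optimizer.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return net, history


def predict_proba(net: Network, X: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Class probability rows (softmax of the logits), in inference mode."""
    X = np.asarray(X, dtype=float)
    out = []
    for i in range(0, len(X), chunk):
        logits = net.forward(X[i : i + chunk], train=False)
        out.append(softmax(logits, axis=1))
    return np.concatenate(out) if out else np.empty((0, net.spec.n_classes))


def predict_labels(net: Network, X: np.ndarray, chunk: int = 512) -> np.ndarray:
    """1-based argmax labels; exact ties break toward the lowest class."""
    return np.argmax(predict_proba(net, X, chunk=chunk), axis=1) + 1


# --------------------------------------------------------------------------
# The trained-model bundle
# --------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted network plus the preprocessing state that feeds it."""

    spec: NetworkSpec
    network: Network
    preprocessor: Preprocessor
    class_names: list[str]
    loss_history: list[float] = field(default_factory=list)

    def predict_pixels(
        self, cube, pixels: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Labels and probability rows for raw (row, col, ...) cube pixels."""
        X = self.preprocessor.transform(cube, pixels)
        proba = predict_proba(self.network, X)
        return np.argmax(proba, axis=1) + 1, proba

    def predict_inputs(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and probability rows for already-preprocessed inputs."""
        proba = predict_proba(self.network, X)
        return np.argmax(proba, axis=1) + 1, proba


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Serialize spec + parameters + preprocessing state as one .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "spec": model.spec.to_dict(),
        "class_names": model.class_names,
        "preprocessor": model.preprocessor.meta(),
        "loss_history": model.loss_history,
    }
    arrays = dict(model.network.state_arrays())
    arrays.update(model.preprocessor.state_arrays())
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        arrays = {k: archive[k] for k in archive.files if k != "meta"}
    spec = NetworkSpec.from_dict(meta["spec"])
    net = Network(spec, seed=0)
    net.load_state_arrays(arrays)
    pp = Preprocessor.from_state(meta["preprocessor"], arrays)
    return TrainedModel(
        spec=spec,
        network=net,
        preprocessor=pp,
        class_names=list(meta["class_names"]),
        loss_history=list(meta.get("loss_history", [])),
    )
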