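"""Minimal 3D-CNN building blocks in numpy.

Implements exactly the layers the stability-prediction architectures need —
3D convolution, 3D max-pooling, ReLU/GELU, dense layers — with hand-written
backward passes, plus MSE / logistic losses and an Adam optimizer.  Convolution
is evaluated as an im2col matrix product; the gradient with respect to the
input of a stride-1 convolution is itself a (full-padded, kernel-flipped)
convolution, so the backward pass is matrix products as well.

Everything is deterministic given the initialization RNG and the batch order.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Layer",
    "Conv3d",
    "MaxPool3d",
    "ReLU",
    "GELU",
    "Flatten",
    "Linear",
    "Sequential",
    "mse_loss",
    "bce_with_logits_loss",
    "Adam",
]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, D, H, W) → (B, L, C·k³) patch matrix; L = number of positions."""
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    b, c, do, ho, wo = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b, do * ho * wo, c * k**3)
    return np.ascontiguousarray(cols), (do, ho, wo)


class Layer:
    """Base layer: parameter/gradient registry plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv3d(Layer):
    """3D cross-correlation, kernel k³, optional additive bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel**3
        bound = 1.0 / math.sqrt(fan_in)
        self.params["weight"] = rng.uniform(
            -bound, bound, size=(out_channels, in_channels, kernel, kernel, kernel)
        )
        if bias:
            self.params["bias"] = rng.uniform(-bound, bound, size=out_channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols, (do, ho, wo) = _im2col(x, self.k, self.stride)
        self._cols = cols
        self._in_shape = x.shape  # padded shape
        w = self.params["weight"].reshape(self.out_channels, -1)
        out = cols @ w.T
        if "bias" in self.params:
            out = out + self.params["bias"]
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.out_channels, do, ho, wo)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        b, oc, do, ho, wo = grad.shape
        g = grad.reshape(b, oc, -1).transpose(0, 2, 1)  # (B, L, out)
        nfeat = self._cols.shape[2]
        gw = g.reshape(-1, oc).T @ self._cols.reshape(-1, nfeat)  # (out, C·k³)
        self.grads["weight"] = gw.reshape(self.params["weight"].shape)
        if "bias" in self.params:
            self.grads["bias"] = g.sum(axis=(0, 1))
        if not need_input_grad:
            return None
        if self.stride != 1:
            raise NotImplementedError("input gradient implemented for stride 1 only")
        # grad wrt input = full correlation of grad with the flipped kernel
        k, p = self.k, self.padding
        w_flip = self.params["weight"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        pad = k - 1
        gp = np.pad(grad, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
        cols, (dd, hh, ww) = _im2col(gp, k, 1)
        gx = cols @ w_flip.reshape(self.in_channels, -1).T
        gx = gx.transpose(0, 2, 1).reshape(b, self.in_channels, dd, hh, ww)
        if p:
            gx = gx[:, :, p:-p, p:-p, p:-p]
        return gx


class MaxPool3d(Layer):
    """3D max pooling with optional (−inf) padding."""

    def __init__(self, kernel: int, stride: int, padding: int = 0) -> None:
        super().__init__()
        self.k = kernel
        self.stride = stride
        self.padding = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, k, s = self.padding, self.k, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)),
                       constant_values=-np.inf)
        self._pad_shape = x.shape
        b, c = x.shape[:2]
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]
        do, ho, wo = win.shape[2:5]
        flat = win.reshape(b, c, do * ho * wo, k**3)
        self._argmax = flat.argmax(axis=3)  # (B, C, L)
        out = np.take_along_axis(flat, self._argmax[..., None], axis=3)[..., 0]
        self._out_dims = (do, ho, wo)
        return out.reshape(b, c, do, ho, wo)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        k, s, p = self.k, self.stride, self.padding
        b, c = grad.shape[:2]
        do, ho, wo = self._out_dims
        dp, hp, wp = self._pad_shape[2:]
        # window start corners for each output position
        iz, iy, ix = np.meshgrid(
            np.arange(do) * s, np.arange(ho) * s, np.arange(wo) * s, indexing="ij"
        )
        starts = (iz * hp * wp + iy * wp + ix).reshape(-1)  # (L,)
        am = self._argmax  # (B, C, L) in [0, k³)
        dz, rem = np.divmod(am, k * k)
        dy, dx = np.divmod(rem, k)
        offs = dz * hp * wp + dy * wp + dx
        flat_idx = starts[None, None, :] + offs  # (B, C, L)
        size = dp * hp * wp
        bc_offsets = (np.arange(b * c) * size).reshape(b, c, 1)
        total = np.bincount(
            (flat_idx + bc_offsets).ravel(),
            weights=grad.reshape(b, c, -1).ravel(),
            minlength=b * c * size,
        )
        gx = total.reshape(b, c, dp, hp, wp)
        if p:
            gx = gx[:, :, p:-p, p:-p, p:-p]
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        return grad * self._mask


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        return x * self._cdf

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        x = self._x
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return grad * (self._cdf + x * pdf)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / math.sqrt(in_features)
        self.params["weight"] = rng.uniform(
            -bound, bound, size=(out_features, in_features)
        )
        if bias:
            self.params["bias"] = rng.uniform(-bound, bound, size=out_features)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.params["weight"].T
        if "bias" in self.params:
            out = out + self.params["bias"]
        return out

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        self.grads["weight"] = grad.T @ self._x
        if "bias" in self.params:
            self.grads["bias"] = grad.sum(axis=0)
        if not need_input_grad:
            return None
        return grad @ self.params["weight"]


class Sequential:
    """A feed-forward stack of layers with a joint parameter registry."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for i in range(len(self.layers) - 1, -1, -1):
            grad = self.layers[i].backward(grad, need_input_grad=i > 0)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params.values()]

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append(layer.grads[name])
        return out

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match the parameter registry")
        for p, s in zip(params, state):
            if p.shape != s.shape:
                raise ValueError("state shape mismatch")
            p[...] = s


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient wrt pred."""
    pred = pred.reshape(-1)
    target = target.reshape(-1)
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 / len(diff)) * diff

def bce_with_logits_loss(
    logits: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits (numerically stable) and its gradient."""
    z = logits.reshape(-1)
    y = target.reshape(-1)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, (p - y) / len(z)


class Adam:
    """Adam with the standard moment coefficients (0.9, 0.999)."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: Sequence[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameters")
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
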