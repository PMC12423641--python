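"""Minimal NumPy layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
exposes its parameters and gradients as aligned dicts (``P`` / ``G``) for
the optimizer.  Everything runs in float32; gradients are exact (verified
against central differences in the test suite).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from scipy.special import erf

F32 = np.float32


class Layer:
    """Base class: parameter container plus forward/backward protocol."""

    def __init__(self) -> None:
        self.P: Dict[str, np.ndarray] = {}
        self.G: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.P:
            self.G[k] = np.zeros_like(self.P[k])


def im2col(
    x: np.ndarray, kh: int, kw: int, stride: int, pad: int
) -> Tuple[np.ndarray, int, int]:
    """Unfold (B, C, H, W) into (B, OH*OW, C*kh*kw) patches."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, C, H, W = x.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (B, C, oh, ow, kh, kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, C * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def col2im(
    dcols: np.ndarray,
    x_shape: Tuple[int, int, int, int],
    kh: int,
    kw: int,
    stride: int,
    pad: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Fold patch gradients back onto the (padded) input grid."""
    B, C, H, W = x_shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(B, oh, ow, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + H, pad : pad + W]
    return dxp


class Conv2D(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.P["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel)).astype(F32)
        self.P["b"] = np.zeros(out_ch, dtype=F32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        cols, oh, ow = im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        w = self.P["w"].reshape(self.P["w"].shape[0], -1)
        out = cols @ w.T + self.P["b"]
        return out.transpose(0, 2, 1).reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, K, oh, ow = dout.shape
        dflat = dout.reshape(B, K, oh * ow).transpose(0, 2, 1)  # (B, L, K)
        w = self.P["w"].reshape(K, -1)
        self.G["w"] += (
            np.einsum("blk,blc->kc", dflat, self._cols).reshape(self.P["w"].shape)
        )
        self.G["b"] += dflat.sum(axis=(0, 1))
        dcols = dflat @ w  # (B, L, C*kh*kw)
        return col2im(
            dcols, self._xshape, self.kernel, self.kernel, self.stride, self.pad, oh, ow
        )


class ELU(Layer):
    """Exponential linear unit: identity for x > 0, exp(x) - 1 otherwise."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = elu(x)
        self._pos = x > 0
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * np.where(self._pos, 1.0, self._y + 1.0).astype(dout.dtype)


def elu(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))).astype(x.dtype if x.dtype.kind == "f" else F32)


class GELU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return (x * self._cdf).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pdf = np.exp(-0.5 * self._x**2) / np.sqrt(2.0 * np.pi)
        return (dout * (self._cdf + self._x * pdf)).astype(dout.dtype)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.P["w"] = rng.normal(0.0, np.sqrt(1.0 / n_in), (n_in, n_out)).astype(F32)
        self.P["b"] = np.zeros(n_out, dtype=F32)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.P["w"] + self.P["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.G["w"] += x2.T @ d2
        self.G["b"] += d2.sum(axis=0)
        return dout @ self.P["w"].T


class LayerNorm(Layer):
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.P["g"] = np.ones(dim, dtype=F32)
        self.P["b"] = np.zeros(dim, dtype=F32)
        self.eps = eps
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return (self._xhat * self.P["g"] + self.P["b"]).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.G["g"] += (dout * xhat).reshape(-1, dout.shape[-1]).sum(axis=0)
        self.G["b"] += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        dxhat = dout * self.P["g"]
        n = dout.shape[-1]
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        return dx.astype(dout.dtype)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, dout: np.ndarray, axis: int = -1) -> np.ndarray:
    return p * (dout - (dout * p).sum(axis=axis, keepdims=True))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64), axis=-1)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)


def collect_params(layers: List[Layer]):
    """Flat (param, grad-dict, key) triples for the optimizer."""
    out = []
    for layer in layers:
        for k in layer.P:
            out.append((layer, k))
    return out
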