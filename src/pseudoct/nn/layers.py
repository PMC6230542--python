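"""Minimal NCHW layer kit with explicit forward/backward passes.

Everything the encoder-decoder needs: same-padded 3×3 convolution
(im2col + BLAS matmul), batch normalisation with running statistics,
ReLU, 2×2 stride-2 max pooling, and ×2 bilinear un-pooling implemented
as a pair of 1D interpolation matrices (so its adjoint is exact).

Layers are stateful: ``forward`` caches what ``backward`` needs, and the
two must be called in matched order, which the network driver
guarantees.  Trainable arrays live in ``params`` with matching
``grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2x2", "BilinearUp2x"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) → (N·H·W, C·k·k) patch matrix with same padding."""
    n, c, h, wd = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * k * k)


def _same_corr(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
               cols: np.ndarray | None = None) -> np.ndarray:
    """Same-padded stride-1 cross-correlation; w is (O, C, k, k)."""
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    if cols is None:
        cols = _im2col(x, k)
    wm = w.transpose(1, 2, 3, 0).reshape(c * k * k, o)
    y = cols @ wm
    if b is not None:
        y += b
    return y.reshape(n, h, wd, o).transpose(0, 3, 1, 2)


class Conv2d:
    """kxk same-padded convolution, stride 1, with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3,
                 dtype=np.float32):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel_size
        self.dtype = dtype
        self.params = {
            "W": np.zeros((out_ch, in_ch, kernel_size, kernel_size), dtype=dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def init_he(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.k * self.k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=self.params["W"].shape).astype(self.dtype)
        self.params["b"] = np.zeros(self.out_ch, dtype=self.dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            # cache the patch matrix: backward reuses it for the weight grad
            self._cols = _im2col(x, self.k)
            self._shape = x.shape
            return _same_corr(x, self.params["W"], self.params["b"],
                              cols=self._cols)
        return _same_corr(x, self.params["W"], self.params["b"])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, wd = self._shape
        k, o = self.k, self.out_ch
        cols = self._cols
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(n * h * wd, o)
        dwm = cols.T @ dy_flat  # (C*k*k, O)
        self.grads["W"] += dwm.reshape(c, k, k, o).transpose(3, 0, 1, 2)
        self.grads["b"] += dy_flat.sum(axis=0)
        # dx: correlate dy with the spatially flipped, channel-swapped kernel
        w_back = self.params["W"].transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        return _same_corr(dy, w_back, None)


class BatchNorm2d:
    """Per-channel batch normalisation over (N, H, W).

    Training uses batch statistics and updates exponential running
    moments (momentum 0.99); inference uses the running statistics and
    is therefore deterministic.
    """

    def __init__(self, n_ch: int, momentum: float = 0.99, eps: float = 1e-5,
                 dtype=np.float32):
        self.n_ch, self.momentum, self.eps = n_ch, momentum, eps
        self.dtype = dtype
        self.params = {"gamma": np.ones(n_ch, dtype=dtype),
                       "beta": np.zeros(n_ch, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=x.dtype)
            var = x.var(axis=(0, 2, 3), dtype=x.dtype)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        # standard batch-norm gradient w.r.t. the input
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return term * inv[None, :, None, None]


class ReLU:
    params: dict = {}
    grads: dict = {}

    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2:
    """2×2 window, stride 2; input sides must be even."""

    params: dict = {}
    grads: dict = {}

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even sides, got {h}x{w}")
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        n, c, h, w = shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(out, idx[..., None], dy[..., None], axis=-1)
        return (out.reshape(n, c, h // 2, w // 2, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, h, w))


def _up2_matrix(n_in: int) -> np.ndarray:
    """Dense (2n × n) 1D bilinear upsampling operator (half-pixel centres)."""
    out = np.zeros((2 * n_in, n_in))
    for i in range(2 * n_in):
        src = np.clip((i + 0.5) / 2.0 - 0.5, 0.0, n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        w = src - lo
        out[i, lo] += 1.0 - w
        out[i, hi] += w
    return out


class BilinearUp2x:
    """×2 bilinear un-pooling; the backward pass is the exact adjoint."""

    params: dict = {}
    grads: dict = {}
    _mats: dict[tuple, np.ndarray] = {}

    @classmethod
    def _mat(cls, n: int, dtype) -> np.ndarray:
        key = (n, np.dtype(dtype).name)
        if key not in cls._mats:
            cls._mats[key] = _up2_matrix(n).astype(dtype)
        return cls._mats[key]

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        if train:
            self._shape = (h, w)
        return self._mat(h, x.dtype) @ x @ self._mat(w, x.dtype).T

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._shape
        return self._mat(h, dy.dtype).T @ dy @ self._mat(w, dy.dtype)
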