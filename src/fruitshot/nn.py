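"""Minimal trainable convolutional-network engine (NumPy, CPU).

Implements exactly what the grid detectors need: 2-D convolution via
im2col/GEMM, PReLU activation, max pooling, and the Adam optimizer, each
with hand-written backward passes.  Data layout is NCHW float32
throughout.  This is a self-contained engine, small enough to audit,
not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "PReLU", "MaxPool2D", "Sequential", "Adam"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold k x k patches into rows: (N*Ho*Wo, C*k*k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    N, C, H, W = x.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # N, C, Ho, Wo, k, k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
    return np.ascontiguousarray(cols), Ho, Wo


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    Ho: int,
    Wo: int,
) -> np.ndarray:
    """Scatter-add column gradients back onto the (padded) input."""
    N, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    dx = np.zeros((N, C, Hp, Wp), dtype=dcols.dtype)
    d6 = dcols.reshape(N, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += d6[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2D:
    """2-D convolution (cross-correlation) with bias.

    Weight shape (out_channels, in_channels, k, k); He-normal init scaled
    for the PReLU slope that typically follows.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.W = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.frozen = False
        self._cache: tuple | None = None

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [] if self.frozen else [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, Ho, Wo = _im2col(x, self.kernel, self.stride, self.pad)
        out_ch = self.W.shape[0]
        Wmat = self.W.reshape(out_ch, -1)
        y = cols @ Wmat.T + self.b
        y = y.reshape(x.shape[0], Ho, Wo, out_ch).transpose(0, 3, 1, 2)
        if train:
            self._cache = (x.shape, cols, Ho, Wo)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols, Ho, Wo = self._cache
        out_ch = dy.shape[1]
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, out_ch)
        self.dW += (dyf.T @ cols).reshape(self.W.shape)
        self.db += dyf.sum(axis=0)
        dcols = dyf @ self.W.reshape(out_ch, -1)
        return _col2im(dcols, x_shape, self.kernel, self.stride, self.pad, Ho, Wo)


class PReLU:
    """Parametric ReLU: max(alpha * x, x), alpha in (0, 1).

    alpha is a fixed hyperparameter by default (trainable=False); the
    detectors ship with alpha = 0.1.
    """

    def __init__(self, alpha: float = 0.1, trainable: bool = False):
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        self.alpha = np.float32(alpha)
        self.trainable = trainable
        self.da = np.zeros(1, dtype=np.float32)
        self._alpha_arr = np.array([alpha], dtype=np.float32)
        self._mask: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def params(self):
        return [(self._alpha_arr, self.da)] if self.trainable else []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = np.float32(self._alpha_arr[0]) if self.trainable else self.alpha
        y = np.where(x > 0, x, a * x)
        if train:
            self._mask = x > 0
            if self.trainable:
                self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        a = np.float32(self._alpha_arr[0]) if self.trainable else self.alpha
        if self.trainable:
            self.da += np.where(self._mask, 0.0, self._x * dy).sum()
        return np.where(self._mask, dy, a * dy)


class MaxPool2D:
    """Max pooling with window F and stride S; no padding.

    Output size follows (n - F) / S + 1 exactly (non-integer is a caller
    error caught at spec validation).
    """

    def __init__(self, size: int = 2, stride: int = 2):
        self.size, self.stride = size, stride
        self._cache: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s = self.size, self.stride
        N, C, H, W = x.shape
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(N, C, Ho, Wo, k * k)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, arg, Ho, Wo)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, arg, Ho, Wo = self._cache
        k, s = self.size, self.stride
        N, C, H, W = x_shape
        dx = np.zeros(x_shape, dtype=dy.dtype)
        ki, kj = np.divmod(arg, k)
        rows = (np.arange(Ho) * s)[None, None, :, None] + ki
        colz = (np.arange(Wo) * s)[None, None, None, :] + kj
        n_idx = np.arange(N)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        np.add.at(dx, (n_idx, c_idx, rows, colz), dy)
        return dx


class Sequential:
    """An ordered stack of layers with forward/backward passes."""

    def __init__(self, layers: list):
        self.layers = layers

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def zero_grad(self) -> None:
        for l in self.layers:
            if isinstance(l, Conv2D):
                l.dW[...] = 0
                l.db[...] = 0
            elif isinstance(l, PReLU) and l.trainable:
                l.da[...] = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam optimizer over (param, grad) pairs from a Sequential."""

    def __init__(self, params, lr: float = 0.002, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.pairs = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
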