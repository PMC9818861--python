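"""Minimal convolutional-network engine (forward + backprop) on numpy.

Implements exactly the pieces the spectral classifier needs: 2-D "same"
convolution with stride 1 (odd kernels only), ReLU, non-overlapping max
pooling with floor semantics, flatten, a dense layer, sigmoid + binary
cross-entropy, and Adam. Everything runs in float32 on the CPU.

Conventions: activations have shape (N, H, W, C); convolution weights have
shape (kh, kw, c_in, c_out).

The convolution uses two equivalent evaluation strategies chosen by channel
count: classic im2col (one big matmul) when the patch is tiny, and a sum of
kh*kw shifted-view matmuls otherwise — the latter avoids materializing the
kh*kw-fold patch matrix, which is what dominates run time at this problem's
image sizes on one CPU core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Patches of a 'same'-padded batch: (N*H*W, kh*kw*C)."""
    n, h, w, c = x.shape
    xp = _pad_same(x, kh, kw)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, kh * kw * c)


def _conv_same_shift(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """'Same' convolution as a sum of shifted channel matmuls."""
    n, h, w, _ = x.shape
    kh, kw = weights.shape[:2]
    xp = _pad_same(x, kh, kw)
    out: np.ndarray | None = None
    for di in range(kh):
        for dj in range(kw):
            term = np.matmul(xp[:, di : di + h, dj : dj + w, :], weights[di, dj])
            out = term if out is None else out + term
    return out


class Conv2DSame:
    """Odd-kernel convolution, stride 1, zero 'same' padding.

    ``first_layer=True`` skips the input-gradient computation (nothing below
    needs it), which is a large saving at full image resolution.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        first_layer: bool = False,
    ):
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dimensions must be odd")
        fan_in = kh * kw * c_in
        scale = np.sqrt(2.0 / fan_in)  # He init, ReLU follows
        self.W = rng.normal(0.0, scale, size=(kh, kw, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = (kh, kw)
        self.first_layer = first_layer
        self._small_patch = kh * kw * c_in <= 9

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        kh, kw = self.kernel
        c_out = self.W.shape[-1]
        if self._small_patch:
            col = _im2col(x, kh, kw)
            out = (col @ self.W.reshape(-1, c_out) + self.b).reshape(n, h, w, c_out)
            if train:
                self._cache = ("col", col, x.shape)
        else:
            out = _conv_same_shift(x, self.W) + self.b
            if train:
                self._cache = ("pad", _pad_same(x, kh, kw), x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        kind, cached, x_shape = self._cache
        n, h, w, c_in = x_shape
        kh, kw = self.kernel
        g2 = grad.reshape(n * h * w, -1)
        if kind == "col":
            self.dW = (cached.T @ g2).reshape(self.W.shape)
        else:
            dW = np.empty_like(self.W)
            for di in range(kh):
                for dj in range(kw):
                    dW[di, dj] = np.tensordot(
                        cached[:, di : di + h, dj : dj + w, :],
                        grad,
                        axes=([0, 1, 2], [0, 1, 2]),
                    )
            self.dW = dW
        self.db = g2.sum(axis=0)
        if self.first_layer:
            return None
        # input gradient = 'same' conv of grad with spatially flipped,
        # channel-transposed weights (exact for odd kernels)
        w_flip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)
        return _conv_same_shift(grad, np.ascontiguousarray(w_flip))

    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def grads(self):
        return []


class MaxPool:
    """Non-overlapping max pooling; trailing rows/columns that do not fill a
    window are dropped (floor semantics). Ties route the gradient to the
    first maximum, as mainstream frameworks do."""

    def __init__(self, pool: tuple[int, int] = (2, 2)):
        self.pool = pool

    def params(self):
        return []

    def _windows(self, x: np.ndarray) -> np.ndarray:
        ph, pw = self.pool
        n, h, w, c = x.shape
        h2, w2 = h // ph, w // pw
        xr = x[:, : h2 * ph, : w2 * pw, :].reshape(n, h2, ph, w2, pw, c)
        return xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, ph * pw)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        win = self._windows(x)
        if train:
            self._argmax = win.argmax(axis=-1)
            self._x_shape = x.shape
            return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]
        return win.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ph, pw = self.pool
        n, h, w, c = self._x_shape
        h2, w2 = h // ph, w // pw
        win_grad = np.zeros((n, h2, w2, c, ph * pw), dtype=grad.dtype)
        np.put_along_axis(win_grad, self._argmax[..., None], grad[..., None], axis=-1)
        out = np.zeros(self._x_shape, dtype=grad.dtype)
        out[:, : h2 * ph, : w2 * pw, :] = (
            win_grad.reshape(n, h2, w2, c, ph, pw)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * ph, w2 * pw, c)
        )
        return out

    def grads(self):
        return []


class Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def grads(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def grads(self):
        return [self.dW, self.db]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """Plain layer stack ending in a single logit."""

    def __init__(self, layers: list):
        self.layers = layers

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x  # logits, shape (N, 1)

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
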