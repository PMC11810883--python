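"""Minimal NumPy CNN primitives with hand-derived backprop.

Just enough machinery for a small 2D U-Net trained on CPU: im2col-based
convolutions (gradients via the transposed/rotated-kernel convolution),
2x2 max pooling, nearest-neighbor x2 upsampling, channel concatenation,
ReLU, a fused sigmoid + binary-cross-entropy head, and Adam.

Layout: arrays are (N, C, H, W) float32.  All layers cache what their
backward pass needs; parameters and gradients live on the layer objects.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Adam",
    "bce_with_logits",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    # (N, C, H, W) -> (N*H*W, C*k*k), stride 1
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return v.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2d:
    """Same-padded stride-1 convolution (correlation), k in {1, 3}."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.w = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.cin, self.cout = k, cin, cout
        self.pad = k // 2
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.compute_input_grad = True  # first layer of a net can skip dx
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        out = cols @ self.w.T + self.b
        if train:
            self._cols = cols
            self._shape = x.shape
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, f, h, w = g.shape
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, f)
        self.gw += (g2.T @ self._cols).astype(np.float32)
        self.gb += g2.sum(axis=0).astype(np.float32)
        if not self.compute_input_grad:
            self._cols = None
            return np.zeros(self._shape, dtype=np.float32)
        # dx = conv of g with the 180deg-rotated kernels, channels swapped
        w4 = self.w.reshape(self.cout, self.cin, self.k, self.k)
        w_rot = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.cin, -1)
        gcols = _im2col(g, self.k, self.pad)
        dx = (gcols @ w_rot.T).reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        self._cols = None
        return dx.astype(np.float32)


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; gradient routed to (all tied) argmax cells."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gr = np.where(self._mask, g[:, :, :, None, :, None], 0.0)
        return gr.reshape(n, c, h, w).astype(np.float32)


class Upsample2:
    """Nearest-neighbor x2 upsampling; gradient sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(np.float32)


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(z) vs y, and dL/dz.

    Uses the softplus form log(1+e^z) - y z for numerical stability.
    """
    zf = z.astype(np.float64)
    with np.errstate(over="ignore", invalid="ignore"):
        loss = float(np.mean(np.logaddexp(0.0, zf) - y * zf))
        grad = ((expit(zf) - y) / z.size).astype(np.float32)
    return loss, grad


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
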