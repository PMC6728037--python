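"""Minimal numpy building blocks for the segmentation network.

Implements exactly the operations the quarter-VGG16 encoder and FCN-8s
decoder need — 2D convolution (stride 1, "same" or "valid" padding via
im2col and a single BLAS matmul), ReLU, 2x2 max pooling, separable
bilinear resampling with its exact adjoint, pixel-wise softmax
cross-entropy and SGD with momentum.  All tensors are float32 in
(N, C, H, W) layout.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2d:
    """Stride-1 2D convolution with symmetric zero padding.

    Weights use He initialisation (appropriate for ReLU) unless
    ``zero_init`` is set — score/skip layers start at zero, the usual
    choice for FCN decoders so that early training is driven by the
    coarse path rather than amplified random skip noise.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, zero_init: bool = False):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        if zero_init:
            self.weight = np.zeros((out_ch, in_ch, kernel, kernel), dtype=np.float32)
        else:
            self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel)).astype(np.float32)
        self.bias = np.zeros(out_ch, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self.pad = kernel // 2
        self._cols: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    @staticmethod
    def _im2col(x: np.ndarray, kernel: int, pad: int) -> np.ndarray:
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(x, (kernel, kernel), axis=(2, 3))
        n, c, ho, wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kernel * kernel)
        return np.ascontiguousarray(cols, dtype=np.float32), (n, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (n, ho, wo) = self._im2col(x, self.kernel, self.pad)
        self._cols, self._x_shape = cols, x.shape
        wmat = self.weight.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.bias
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, _, ho, wo = grad_out.shape
        gcols = np.ascontiguousarray(grad_out.transpose(0, 2, 3, 1).reshape(-1, self.out_ch))
        self.grad_weight[...] = (gcols.T @ self._cols).reshape(self.weight.shape)
        self.grad_bias[...] = gcols.sum(axis=0)
        # dx is the full correlation of grad_out with the rotated kernels
        w_rot = self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
        pad_back = self.kernel - 1 - self.pad
        cols_b, (nb, hb, wb) = self._im2col(grad_out, self.kernel, pad_back)
        dx = cols_b @ w_rot.reshape(self.in_ch, -1).T
        dx = dx.reshape(nb, hb, wb, self.in_ch).transpose(0, 3, 1, 2)
        self._cols = None
        return dx

    def parameters(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]


class LeakyReLU:
    """Rectifier with a small negative slope.

    A strict ReLU makes short from-scratch training of this network
    collapse for some seeds (whole blocks die early and the output
    degenerates to an input-independent average mask); the leak lets
    dead units recover and makes the short schedules reliable.
    """

    def __init__(self, slope: float = 0.05):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, self.slope * grad_out)

    def parameters(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; requires even spatial dimensions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling needs even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, ho, wo = grad_out.shape
        g4 = np.zeros((n, c, ho, wo, 4), dtype=grad_out.dtype)
        np.put_along_axis(g4, self._argmax[..., None], grad_out[..., None], axis=-1)
        return g4.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(self._in_shape)

    def parameters(self):
        return []


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1D linear-interpolation matrix (n_out x n_in)."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (src - i0).astype(np.float32)
    mat[np.arange(n_out), i0] += 1.0 - frac
    mat[np.arange(n_out), i1] += frac
    return mat


class BilinearResize:
    """Separable bilinear resampling to a fixed spatial size.

    The operation is linear, so its backward pass is the exact adjoint
    (transposed interpolation matrices).
    """

    def __init__(self, out_hw: Tuple[int, int]):
        self.out_hw = out_hw
        self._mats = {}

    def _matrices(self, h: int, w: int):
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (_interp_matrix(self.out_hw[0], h), _interp_matrix(self.out_hw[1], w))
        return self._mats[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_hw = x.shape[2:]
        ah, aw = self._matrices(*self._in_hw)
        return np.ascontiguousarray((ah @ x) @ aw.T)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        ah, aw = self._matrices(*self._in_hw)
        return np.ascontiguousarray((ah.T @ grad_out) @ aw)

    def parameters(self):
        return []


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over axis 1 of an (N, C, H, W) tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: Optional[np.ndarray] = None
) -> Tuple[float, np.ndarray]:
    """Mean pixel-wise cross-entropy and its gradient w.r.t. the logits.

    ``labels`` is an (N, H, W) integer map; ``class_weights`` optionally
    re-weights the per-pixel losses by true class (the mean stays a
    weighted mean, so gradients are normalised by the weight total).
    """
    n, c, h, w = logits.shape
    p = softmax(logits.astype(np.float64))
    onehot = np.eye(c, dtype=np.float64)[labels].transpose(0, 3, 1, 2)
    if class_weights is None:
        wpix = np.ones((n, h, w))
    else:
        wpix = np.asarray(class_weights, dtype=np.float64)[labels]
    total = wpix.sum()
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(wpix * (onehot * logp).sum(axis=1)).sum() / total)
    grad = ((p - onehot) * wpix[:, None]) / total
    return loss, grad.astype(np.float32)


class SGDMomentum:
    """Classic momentum SGD: v <- m v - lr g;  w <- w + v.

    Gradients are clipped by global norm before the update, which keeps
    the occasional large batch from destabilising short schedules.
    """

    def __init__(self, parameters, momentum: float = 0.9, clip_norm: Optional[float] = 10.0):
        self._params = parameters
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p) for p, _ in parameters]

    def step(self, lr: float):
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for _, g in self._params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for (param, grad), vel in zip(self._params, self._velocity):
            vel *= self.momentum
            vel -= lr * scale * grad
            param += vel
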