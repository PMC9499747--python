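"""Minimal NumPy neural-network layers with manual backpropagation.

Just enough machinery for the dual-head U-Net: same-padded convolution
(im2col), 2x2 max pooling, stride-2 transposed convolution, ReLU, dropout,
channel concatenation, global average pooling, a linear head, softmax
cross-entropy and sigmoid binary cross-entropy, plus Adam. Tensors are
``(N, C, H, W)`` float64; every layer caches what its backward pass needs.

Written because no deep-learning framework is available in the runtime; the
layer set is deliberately small and CPU-oriented (desk-scale training on
small phantoms).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Layer:
    """Base: parameters in ``params``/``grads`` dicts keyed by name."""

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x, k):
    """(N, C, H, W) -> (N*H*W, C*k*k) with same padding for odd k."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(dcols, x_shape, k):
    """Scatter-add column gradients back to the padded input, then crop."""
    n, c, h, w = x_shape
    pad = k // 2
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    dcols = dcols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class Conv2D(Layer):
    """Same-padded convolution with an odd square kernel."""

    def __init__(self, in_ch, out_ch, kernel=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        # He initialisation, ReLU-friendly
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (fan_in, out_ch))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cols = _im2col(x, self.kernel)
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.grads["W"] = cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = dflat @ self.params["W"].T
        return _col2im(dcols, x_shape, self.kernel)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; requires even spatial sides."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial sides")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._x_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class ConvTranspose2(Layer):
    """Stride-2 transposed convolution (kernel 3): doubles spatial sides.

    Implemented as zero-interleaving to (2H, 2W) followed by a same-padded
    convolution, i.e. a transposed conv with output padding 1.
    """

    def __init__(self, in_ch, out_ch, kernel=3, rng=None):
        super().__init__()
        self.conv = Conv2D(in_ch, out_ch, kernel, rng=rng)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        up = np.zeros((n, c, 2 * h, 2 * w))
        up[:, :, ::2, ::2] = x
        return self.conv.forward(up, train=train)

    def backward(self, dout):
        dup = self.conv.backward(dout)
        self.grads = self.conv.grads
        return dup[:, :, ::2, ::2]


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class GlobalMaxPool(Layer):
    """(N, C, H, W) -> (N, C); backward routes to the (first) argmax."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], -1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h * w))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], -1)
        return dflat.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_dim, out_dim, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_dim),
                                      (in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, targets):
    """Mean CE over one-hot integer targets; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


def sigmoid_bce(logits, targets):
    """Mean binary CE over pixel logits; returns (loss, dlogits)."""
    p = expit(logits)
    eps = 1e-12
    loss = -(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps)).mean()
    return loss, (p - targets) / logits.size


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in self.layers]

    def step(self):
        self.t += 1
        for i, ly in enumerate(self.layers):
            for k, p in ly.params.items():
                g = ly.grads.get(k)
                if g is None:
                    continue
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1**self.t)
                vhat = self.v[i][k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
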