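"""NumPy neural-network layers with explicit forward/backward passes.

Convolutions use im2col (sliding_window_view) so forward and backward are
single matrix multiplications per layer.  Every layer caches what its
backward pass needs; ``backward`` returns the input gradient and stores
parameter gradients on the layer (``dW``, ``db``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "Linear", "global_avg_pool", "global_avg_pool_backward"]


class Conv2d:
    """2D convolution, square kernel, 'same'-style zero padding."""

    def __init__(self, in_channels, out_channels, kernel_size=3, stride=1, padding=1, rng=None, scale=None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = scale if scale is not None else np.sqrt(2.0 / fan_in)  # He init
        self.W = rng.normal(scale=scale, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.b = np.zeros(out_channels)
        self.stride = stride
        self.padding = padding
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x):
        n, c, h, w = x.shape
        k = self.W.shape[-1]
        p, s = self.padding, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        return cols, (n, c, h, w, ho, wo)

    def forward(self, x):
        cols, meta = self._im2col(x)
        n, c, h, w, ho, wo = meta
        co = self.W.shape[0]
        out = cols @ self.W.reshape(co, -1).T + self.b
        self._cache = (cols, meta)
        return out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w, ho, wo) = self._cache
        co, k = self.W.shape[0], self.W.shape[-1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        self.dW[...] = (dmat.T @ cols).reshape(self.W.shape)
        self.db[...] = dmat.sum(axis=0)
        dcols = dmat @ self.W.reshape(co, -1)  # (n*ho*wo, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        # scatter-add the column gradients back onto the (padded) image
        p, s = self.padding, self.stride
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    params = ()
    grads = ()

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Linear:
    def __init__(self, in_features, out_features, rng=None, scale=None):
        rng = rng or np.random.default_rng(0)
        scale = scale if scale is not None else np.sqrt(2.0 / in_features)
        self.W = rng.normal(scale=scale, size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W


def global_avg_pool(x):
    """(n, c, h, w) -> (n, c)."""
    return x.mean(axis=(2, 3))


def global_avg_pool_backward(dout, shape):
    n, c, h, w = shape
    return np.broadcast_to(dout[:, :, None, None], shape) / (h * w)
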