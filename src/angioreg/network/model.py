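"""Residual CNN regressing a 6-parameter rigid correction from an image pair.

Input is a 2-channel stack (moving DRR, fixed DSA/DRR); output is a pose
chart vector: axis-angle rotation (radians) and translation (mm), obtained
from two parallel linear heads whose raw outputs are multiplied by fixed
scales so a unit head activation corresponds to a plausible offset.  The
final-layer weights start near zero, so an untrained network predicts
(almost) the identity correction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layers import Conv2d, Linear, ReLU, global_avg_pool, global_avg_pool_backward

__all__ = ["PoseRegressionCNN"]


class _ResBlock:
    """conv-relu-conv with a strided 1x1 projection skip, post-activation."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, rng=rng)
        self.proj = Conv2d(cin, cout, 1, stride=stride, padding=0, rng=rng)
        self.relu2 = ReLU()

    @property
    def layers(self):
        return [self.conv1, self.conv2, self.proj]

    def forward(self, x):
        out = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x)
        return self.relu2.forward(out + skip)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dx = self.proj.backward(d)
        d = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return dx + d


class PoseRegressionCNN:
    """Compact residual backbone + two linear pose heads.

    ``widths`` sets the channel progression (one stem conv + one residual
    block per extra width, each halving resolution).  ``rotation_scale`` /
    ``translation_scale`` convert raw head outputs into radians and mm.
    """

    def __init__(
        self,
        in_channels: int = 2,
        widths: tuple = (16, 32, 64),
        rotation_scale: float = 0.1,
        translation_scale: float = 10.0,
        input_size: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.rotation_scale = float(rotation_scale)
        self.translation_scale = float(translation_scale)
        self.seed = int(seed)
        self.input_size = int(input_size)
        self.in_channels = in_channels
        self.stem = Conv2d(in_channels, widths[0], 3, stride=2, padding=1, rng=rng)
        self.stem_relu = ReLU()
        self.blocks = [_ResBlock(widths[i], widths[i + 1], 2, rng) for i in range(len(widths) - 1)]
        self.head_rot = Linear(widths[-1], 3, rng=rng, scale=0.01)
        self.head_trans = Linear(widths[-1], 3, rng=rng, scale=0.01)
        self._cache = None

    # -- parameter plumbing ---------------------------------------------------

    @property
    def _layers(self):
        layers = [self.stem]
        for b in self.blocks:
            layers.extend(b.layers)
        layers.extend([self.head_rot, self.head_trans])
        return layers

    @property
    def params(self):
        return [p for layer in self._layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self._layers for g in layer.grads]

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(n, 2, H, W) image pairs -> (n, 6) pose chart vectors."""
        x = np.asarray(x, dtype=float)
        h = self.stem_relu.forward(self.stem.forward(x))
        for b in self.blocks:
            h = b.forward(h)
        self._pool_shape = h.shape
        feat = global_avg_pool(h)
        rot = self.head_rot.forward(feat) * self.rotation_scale
        trans = self.head_trans.forward(feat) * self.translation_scale
        return np.concatenate([rot, trans], axis=1)

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients from (n, 6) output gradients."""
        dout = np.asarray(dout, dtype=float)
        dfeat = self.head_rot.backward(dout[:, :3] * self.rotation_scale)
        dfeat = dfeat + self.head_trans.backward(dout[:, 3:] * self.translation_scale)
        dh = global_avg_pool_backward(dfeat, self._pool_shape)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        self.stem.backward(self.stem_relu.backward(dh))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass for a single (2, H, W) pair -> (6,) chart vector."""
        out = self.forward(np.asarray(x)[None])
        return out[0]

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        meta = dict(
            widths=np.asarray(self.widths),
            rotation_scale=self.rotation_scale,
            translation_scale=self.translation_scale,
            seed=self.seed,
            input_size=self.input_size,
            in_channels=self.in_channels,
        )
        np.savez(path, **arrays, **meta)

    @classmethod
    def load(cls, path: str | Path) -> "PoseRegressionCNN":
        data = np.load(path)
        net = cls(
            in_channels=int(data["in_channels"]),
            widths=tuple(int(w) for w in data["widths"]),
            rotation_scale=float(data["rotation_scale"]),
            translation_scale=float(data["translation_scale"]),
            input_size=int(data["input_size"]),
            seed=int(data["seed"]),
        )
        for i, p in enumerate(net.params):
            p[...] = data[f"p{i}"]
        return net
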