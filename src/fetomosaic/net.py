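"""A small convolutional regression network in pure numpy.

The network regresses the 8 corner displacements of the 4-point
homography from a 2-channel stack of grayscale patches, in the spirit
of the VGG-like deep-image-homography regressor (stacked 3x3
convolutions + ReLU, two fully connected layers, Euclidean loss,
adaptive-moment optimizer).  It is deliberately compact and
dependency-free: training runs deterministically on a single CPU at
desk scale, which is what the controlled-vs-perturbed comparison in
this package needs.

Shapes follow the (batch, channels, height, width) convention.  The
Euclidean loss is ``L2 = 0.5 * ||gt - pred||^2`` per sample, averaged
over the batch; targets are the corner displacements divided by
``disp_scale`` so the regression operates on O(1) values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = ["RegressionNetSpec", "HomographyNet"]

_DTYPE = np.float32  # training runs in single precision (plenty for 8-value regression)


@dataclass(frozen=True)
class RegressionNetSpec:
    """Architecture + optimizer settings for the regression network.

    ``conv`` is a sequence of (out_channels, stride) for 3x3 same-pad
    convolutions; ``fc_hidden`` the width of the hidden fully connected
    layer; output is always 8 (4 corners x 2 displacements).

    ``full()`` mirrors the 8-conv / 2-FC layout of the original
    deep-homography regressor at 128x128 input with its published
    learning rate; ``desk()`` is the scaled-down preset (32x32 input,
    4 convolutions) that trains in minutes on one CPU and is used by
    the package's own experiments.
    """

    input_size: int = 32
    conv: Tuple[Tuple[int, int], ...] = ((16, 1), (16, 2), (32, 2), (32, 2))
    fc_hidden: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 32
    disp_scale: float = 32.0

    @classmethod
    def desk(cls) -> "RegressionNetSpec":
        return cls()

    @classmethod
    def full(cls) -> "RegressionNetSpec":
        return cls(
            input_size=128,
            conv=((64, 1), (64, 2), (64, 1), (64, 2), (128, 1), (128, 2), (128, 1), (128, 2)),
            fc_hidden=1024,
            learning_rate=1e-4,
        )


class _Adam:
    """Adaptive-moment optimizer state for a list of parameter arrays."""

    def __init__(self, params: List[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _Conv3x3:
    """3x3 same-padded convolution with stride, He-initialized."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        fan_in = cin * 9
        self.w = (rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.stride = stride

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stride
        b, c, h, w = x.shape
        ho, wo = (h + s - 1) // s, (w + s - 1) // s
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp_shape = xp.shape
        self._xp = xp
        out = np.empty((b, self.w.shape[0], ho, wo), dtype=_DTYPE)
        out[:] = self.b[None, :, None, None]
        for dy in range(3):
            for dx in range(3):
                sl = xp[:, :, dy : dy + s * ho : s, dx : dx + s * wo : s]
                out += np.einsum("oc,bcij->boij", self.w[:, :, dy, dx], sl, optimize=True)
        return out

    def backward(self, gout: np.ndarray):
        s = self.stride
        _, _, ho, wo = gout.shape
        xp = self._xp
        gw = np.zeros_like(self.w)
        gxp = np.zeros(self._xp_shape, dtype=_DTYPE)
        for dy in range(3):
            for dx in range(3):
                sl = xp[:, :, dy : dy + s * ho : s, dx : dx + s * wo : s]
                gw[:, :, dy, dx] = np.einsum("boij,bcij->oc", gout, sl, optimize=True)
                gxp[:, :, dy : dy + s * ho : s, dx : dx + s * wo : s] += np.einsum(
                    "oc,boij->bcij", self.w[:, :, dy, dx], gout, optimize=True
                )
        gb = gout.sum(axis=(0, 2, 3))
        self._xp = None
        return gxp[:, :, 1:-1, 1:-1], [gw, gb]


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, out_zero: bool = False):
        if out_zero:
            # near-zero head: an untrained network predicts ~no displacement
            self.w = (rng.standard_normal((nout, nin)) * 1e-3).astype(_DTYPE)
        else:
            self.w = (rng.standard_normal((nout, nin)) * np.sqrt(2.0 / nin)).astype(_DTYPE)
        self.b = np.zeros(nout, dtype=_DTYPE)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gout: np.ndarray):
        gw = gout.T @ self._x
        gb = gout.sum(axis=0)
        gx = gout @ self.w
        self._x = None
        return gx, [gw, gb]


class HomographyNet:
    """Convolutional 4-point homography regressor (numpy forward/backward).

    Input: (batch, 2, S, S) patch stacks scaled to [-1, 1].
    Output: (batch, 8) normalized displacements (multiply by
    ``spec.disp_scale`` for pixels), order (du1, dv1, ..., du4, dv4).
    """

    def __init__(self, spec: RegressionNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.convs: List[_Conv3x3] = []
        cin, size = 2, spec.input_size
        for cout, stride in spec.conv:
            self.convs.append(_Conv3x3(cin, cout, stride, rng))
            cin = cout
            size = (size + stride - 1) // stride
        self.flat_dim = cin * size * size
        self.fc1 = _Dense(self.flat_dim, spec.fc_hidden, rng)
        self.fc2 = _Dense(spec.fc_hidden, 8, rng, out_zero=True)
        self.opt = _Adam(self.parameters(), lr=spec.learning_rate)

    def parameters(self) -> List[np.ndarray]:
        ps: List[np.ndarray] = []
        for c in self.convs:
            ps.extend(c.params)
        ps.extend(self.fc1.params)
        ps.extend(self.fc2.params)
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        acts = []
        for conv in self.convs:
            x = conv.forward(x)
            mask = x > 0
            x = x * mask
            acts.append(mask)
        b = x.shape[0]
        shape_before_flat = x.shape
        x = x.reshape(b, -1)
        h = self.fc1.forward(x)
        hmask = h > 0
        h = h * hmask
        out = self.fc2.forward(h)
        if train:
            self._cache = (acts, shape_before_flat, hmask)
        return out

    def train_step(self, x: np.ndarray, target: np.ndarray) -> float:
        """One Euclidean-loss gradient step; returns the batch loss."""
        pred = self.forward(x, train=True)
        diff = pred - target.astype(_DTYPE)
        n = x.shape[0]
        loss = 0.5 * float((diff**2).sum()) / n
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss: {loss}")
        acts, shape_before_flat, hmask = self._cache
        self._cache = None
        grads_rev: List[np.ndarray] = []
        g = diff / n
        g, gp = self.fc2.backward(g)
        grads_rev.extend(reversed(gp))
        g = g * hmask
        g, gp = self.fc1.backward(g)
        grads_rev.extend(reversed(gp))
        g = g.reshape(shape_before_flat)
        for conv, mask in zip(reversed(self.convs), reversed(acts)):
            g = g * mask
            g, gp = conv.backward(g)
            grads_rev.extend(reversed(gp))
        self.opt.step(self.parameters(), list(reversed(grads_rev)))
        return loss

    def predict_displacements(self, x: np.ndarray) -> np.ndarray:
        """Forward pass returning pixel displacements, shape (batch, 8)."""
        return self.forward(x) * self.spec.disp_scale

    # --- checkpointing -------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, *self.parameters(), allow_pickle=False)

    def load(self, path) -> None:
        with np.load(path) as data:
            for p, key in zip(self.parameters(), data.files):
                p[...] = data[key]
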