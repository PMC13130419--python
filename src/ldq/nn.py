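"""Minimal 3D convolutional network primitives in numpy (float32).

All activations are arrays shaped ``(channels, x, y, z)``. Convolutions
run as sums of shifted GEMMs over kernel offsets, keeping the heavy
lifting in BLAS without materialising im2col patch matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Conv3d", "InstanceNorm", "ReLU", "MaxPool2", "Upsample2", "Adam", "bce_with_logits"]


class Conv3d:
    """Same-padding 3D convolution with bias.

    Implemented as a sum of shifted GEMMs over kernel offsets — faster in
    numpy than im2col because the shifted slices of the padded input stay
    near-contiguous instead of materialising a huge patch matrix.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        scale: float | None = None,
        bias_init: np.ndarray | None = None,
    ):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel**3
        std = scale if scale is not None else np.sqrt(2.0 / fan_in)  # He init for ReLU
        self.W = rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel, kernel)).astype(np.float32)
        self.b = (
            np.asarray(bias_init, dtype=np.float32).copy()
            if bias_init is not None
            else np.zeros(out_ch, dtype=np.float32)
        )
        self._xp: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        return np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        spatial = x.shape[1:]
        if self.k == 1:
            if train:
                self._xp = x
            out = np.tensordot(self.W.reshape(self.out_ch, self.in_ch), x, axes=(1, 0))
            return out + self.b[:, None, None, None]
        nx, ny, nz = spatial
        xp = self._pad(x)
        if train:
            self._xp = xp
        out = np.empty((self.out_ch, nx * ny * nz), dtype=np.float32)
        out[:] = self.b[:, None]
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    xs = xp[:, i : i + nx, j : j + ny, l : l + nz].reshape(self.in_ch, -1)
                    out += self.W[:, :, i, j, l] @ xs
        return out.reshape((self.out_ch,) + spatial)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward before forward"
        spatial = dout.shape[1:]
        v = int(np.prod(spatial))
        d2 = np.ascontiguousarray(dout.reshape(self.out_ch, v))
        self.db[...] = d2.sum(axis=1)
        if self.k == 1:
            self.dW[...] = (d2 @ xp.reshape(self.in_ch, v).T).reshape(self.W.shape)
            dx = np.tensordot(self.W.reshape(self.out_ch, self.in_ch).T, dout, axes=(1, 0))
            self._xp = None
            return np.ascontiguousarray(dx)
        nx, ny, nz = spatial
        dout4 = d2.reshape((self.out_ch,) + spatial)
        dp = self._pad(dout4)
        dx = np.zeros((self.in_ch, nx * ny * nz), dtype=np.float32)
        kk = self.k - 1
        # dW from shifted input slices; dx as correlation of padded dout
        # with the flipped, transposed kernel (same GEMM pattern as forward,
        # avoiding a strided scatter-add)
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    xs = xp[:, i : i + nx, j : j + ny, l : l + nz].reshape(self.in_ch, -1)
                    self.dW[:, :, i, j, l] = d2 @ xs.T
                    ds = dp[:, i : i + nx, j : j + ny, l : l + nz].reshape(self.out_ch, -1)
                    dx += self.W[:, :, kk - i, kk - j, kk - l].T @ ds
        self._xp = None
        return dx.reshape((self.in_ch,) + spatial)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class InstanceNorm:
    """Per-channel normalisation over the spatial dims, learned scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.g = np.ones(channels, dtype=np.float32)
        self.b = np.zeros(channels, dtype=np.float32)
        self.eps = eps
        self.dg = np.zeros_like(self.g)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.g.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv
        if train:
            self._cache = (xhat, inv, x.shape)
        out = self.g[:, None] * xhat + self.b[:, None]
        return out.reshape(x.shape).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        c = shape[0]
        d2 = dout.reshape(c, -1)
        self.dg[...] = (d2 * xhat).sum(axis=1)
        self.db[...] = d2.sum(axis=1)
        dxhat = d2 * self.g[:, None]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        self._cache = None
        return dx.reshape(shape).astype(np.float32)

    def params(self):
        return [(self.g, self.dg), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0)
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, 0.0)
        self._mask = None
        return dx


class MaxPool2:
    """2x2x2 max pooling; spatial dims must be even."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        c, nx, ny, nz = x.shape
        return (
            x.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, nx // 2, ny // 2, nz // 2, 8)
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        blocks = self._blocks(x)
        idx = np.argmax(blocks, axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, nx, ny, nz = self._shape
        blocks = np.zeros((c, nx // 2, ny // 2, nz // 2, 8), dtype=dout.dtype)
        np.put_along_axis(blocks, self._idx[..., None], dout[..., None], axis=-1)
        dx = (
            blocks.reshape(c, nx // 2, ny // 2, nz // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, nx, ny, nz)
        )
        self._idx = self._shape = None
        return np.ascontiguousarray(dx)


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2x2 block."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, nx, ny, nz = dout.shape
        return dout.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2).sum(axis=(2, 4, 6))


class Adam:
    """Adam optimiser over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-channel binary cross-entropy against one-hot targets.

    Returns (mean loss, gradient wrt logits). Uses the numerically stable
    form ``max(z,0) - z*t + log(1 + exp(-|z|))``.
    """
    z = logits.astype(np.float32)
    t = targets.astype(np.float32)
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    sig = expit(z)
    return float(loss.mean()), (sig - t) / n
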