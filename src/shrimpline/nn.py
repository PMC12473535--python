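"""Small CPU neural-network layers with explicit backward passes.

Dense-prediction layers (dilated 2-D convolution, average pooling, nearest
upsampling, ReLU, channel concat) over single samples laid out as
(channels, height, width) float64 arrays, plus momentum SGD with a
multi-step learning-rate schedule.  Deliberately minimal: exactly what the
centerline network needs, deterministic given a seeded generator.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.velocity = np.zeros_like(value)


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) with same-size zero padding."""
    c, h, w = x.shape
    pad = dilation * (k // 2)
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            r0 = i * dilation
            c0 = j * dilation
            cols[:, i * k + j] = xp[:, r0 : r0 + h, c0 : c0 + w]
    return cols.reshape(c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple[int, int, int], k: int, dilation: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back to the padded image)."""
    c, h, w = shape
    pad = dilation * (k // 2)
    xp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(c, k * k, h, w)
    for i in range(k):
        for j in range(k):
            r0 = i * dilation
            c0 = j * dilation
            xp[:, r0 : r0 + h, c0 : c0 + w] += cols[:, i * k + j]
    return xp[:, pad : pad + h, pad : pad + w] if pad else xp


class Conv2d:
    """Same-padding convolution with optional dilation (stride 1)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: int,
        rng: np.random.Generator,
        dilation: int = 1,
    ):
        self.in_ch, self.out_ch, self.k, self.dilation = in_ch, out_ch, ksize, dilation
        fan_in = in_ch * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.W = Param(w)
        self.b = Param(np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k, self.dilation)
        out = self.W.value @ self._cols + self.b.value[:, None]
        return out.reshape(self.out_ch, x.shape[1], x.shape[2])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyf = dy.reshape(self.out_ch, -1)
        self.W.grad += dyf @ self._cols.T
        self.b.grad += dyf.sum(axis=1)
        dcols = self.W.value.T @ dyf
        return _col2im(dcols, self._shape, self.k, self.dilation)

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def avg_pool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def avg_pool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SGD:
    """Momentum SGD with a multi-step learning-rate schedule."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        momentum: float = 0.9,
        milestones: tuple[int, ...] = (),
        gamma: float = 0.1,
        clip_grad_norm: float | None = None,
        warmup_epochs: int = 0,
    ):
        self.params = params
        self.base_lr = lr
        self.momentum = momentum
        self.milestones = tuple(milestones)
        self.gamma = gamma
        self.clip_grad_norm = clip_grad_norm
        self.warmup_epochs = warmup_epochs

    def lr_at(self, epoch: int) -> float:
        if epoch < self.warmup_epochs:
            # linear warmup keeps early momentum steps from saturating
            return self.base_lr * (epoch + 1) / (self.warmup_epochs + 1)
        drops = sum(1 for m in self.milestones if epoch >= m)
        return self.base_lr * self.gamma**drops

    def step(self, epoch: int) -> None:
        lr = self.lr_at(epoch)
        if self.clip_grad_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params))
            if total > self.clip_grad_norm:
                scale = self.clip_grad_norm / total
                for p in self.params:
                    p.grad *= scale
        for p in self.params:
            p.velocity = self.momentum * p.velocity - lr * p.grad
            p.value += p.velocity

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
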