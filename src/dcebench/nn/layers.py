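"""Numpy layers with explicit forward/backward passes.

Tensors are ``(batch, channels, *spatial)`` float32.  Convolutions are
stride-1, zero-padded to "same" size, computed as a sum of channel-GEMMs
over kernel offsets (memory-friendly for 3D inputs, unlike an im2col
expansion of the full window tensor).
"""

from __future__ import annotations

import itertools

import numpy as np


class Layer:
    """Base class: stateless unless it has ``params``/``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConvND(Layer):
    """N-dimensional "same" convolution (stride 1) with optional bias.

    Weight shape ``(out_ch, in_ch, *kernel)``; He-normal initialization from
    the supplied generator keeps runs reproducible.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: tuple[int, ...],
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.kernel = tuple(kernel)
        fan_in = in_ch * int(np.prod(kernel))
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, *kernel)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = len(self.kernel)
        pads = [(k // 2, k // 2) for k in self.kernel]
        xp = np.pad(x, [(0, 0), (0, 0)] + pads)
        spatial = x.shape[2:]
        out_ch, in_ch = self.w.shape[:2]
        # im2col: one GEMM instead of a per-offset loop
        win = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=tuple(range(2, 2 + nd))
        )  # (B, C, *spatial, *kernel)
        perm = [0] + list(range(2, 2 + nd)) + [1] + list(range(2 + nd, 2 + 2 * nd))
        cols = np.ascontiguousarray(win.transpose(perm)).reshape(
            -1, in_ch * int(np.prod(self.kernel))
        )
        self._cols = cols
        self._in_shape = x.shape
        wmat = self.w.reshape(out_ch, -1)
        out = cols @ wmat.T + self.b
        return np.ascontiguousarray(
            np.moveaxis(out.reshape(x.shape[0], *spatial, out_ch), -1, 1)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        assert cols is not None, "backward before forward"
        nd = len(self.kernel)
        spatial = dout.shape[2:]
        out_ch, in_ch = self.w.shape[:2]
        dl = np.ascontiguousarray(np.moveaxis(dout, 1, -1)).reshape(-1, out_ch)
        self.grads[1][...] = dl.sum(axis=0)
        self.grads[0][...] = (dl.T @ cols).reshape(self.w.shape)
        # dcols -> scatter-add over kernel offsets into the padded gradient
        dcols = (dl @ self.w.reshape(out_ch, -1)).reshape(
            dout.shape[0], *spatial, in_ch, *self.kernel
        )
        pad_sp = tuple(s + k - 1 for s, k in zip(spatial, self.kernel))
        dxp_l = np.zeros((dout.shape[0], *pad_sp, in_ch), dtype=np.float32)
        for off in itertools.product(*(range(k) for k in self.kernel)):
            sl = tuple(slice(o, o + s) for o, s in zip(off, spatial))
            dxp_l[(slice(None),) + sl] += dcols[(Ellipsis,) + off]
        crop = tuple(
            slice(k // 2, p - (k - 1 - k // 2))
            for k, p in zip(self.kernel, pad_sp)
        )
        self._cols = None
        dx = dxp_l[(slice(None),) + crop]
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool(Layer):
    """Max pooling with a per-axis factor tuple, e.g. (2, 2) or (1, 2, 2)."""

    def __init__(self, factors: tuple[int, ...]) -> None:
        super().__init__()
        self.factors = tuple(factors)

    def _blocked(self, x: np.ndarray) -> np.ndarray:
        b, c = x.shape[:2]
        spatial = x.shape[2:]
        shape = [b, c]
        for s, f in zip(spatial, self.factors):
            if s % f:
                raise ValueError(f"spatial dim {s} not divisible by pool factor {f}")
            shape += [s // f, f]
        xr = x.reshape(shape)
        nd = len(spatial)
        perm = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
        xt = xr.transpose(perm)
        out_sp = tuple(s // f for s, f in zip(spatial, self.factors))
        return xt.reshape(b, c, *out_sp, int(np.prod(self.factors)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        blocked = self._blocked(x)
        self._arg = blocked.argmax(axis=-1)
        return np.take_along_axis(blocked, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c = self._in_shape[:2]
        spatial = self._in_shape[2:]
        nd = len(spatial)
        out_sp = dout.shape[2:]
        blocked = np.zeros((b, c, *out_sp, int(np.prod(self.factors))), np.float32)
        np.put_along_axis(blocked, self._arg[..., None], dout[..., None], axis=-1)
        shape = [b, c] + [s // f for s, f in zip(spatial, self.factors)] + list(
            self.factors
        )
        bt = blocked.reshape(shape)
        perm = [0, 1]
        for i in range(nd):
            perm += [2 + i, 2 + nd + i]
        return bt.transpose(perm).reshape(self._in_shape)


class Upsample(Layer):
    """Nearest-neighbour upsampling by per-axis integer factors."""

    def __init__(self, factors: tuple[int, ...]) -> None:
        super().__init__()
        self.factors = tuple(factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for ax, f in enumerate(self.factors):
            if f > 1:
                out = np.repeat(out, f, axis=2 + ax)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c = dout.shape[:2]
        spatial = dout.shape[2:]
        shape = [b, c]
        for s, f in zip(spatial, self.factors):
            shape += [s // f, f]
        nd = len(spatial)
        dr = dout.reshape(shape)
        return dr.sum(axis=tuple(3 + 2 * i for i in range(nd)))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    # log(1 + exp(z)) computed stably
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - t) / z.size
    return float(loss), grad.astype(np.float32)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
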