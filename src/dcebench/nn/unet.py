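"""U-Net encoder-decoder built from the numpy layers.

The same class covers the 2D and 3D arms: spatial rank, depth (number of
resolution levels), base filter count and pooling factors are configuration.
For 3D inputs the pooling can be restricted to the in-plane axes, the usual
choice when lesions span too few slices to pool axially.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..errors import StateError
from .layers import Adam, ConvND, MaxPool, ReLU, Upsample, bce_with_logits, sigmoid


@dataclass(frozen=True)
class UNetConfig:
    ndim: int = 2
    in_channels: int = 1
    base_filters: int = 16
    levels: int = 3  # resolution levels, including the bottleneck
    axial_pool: bool = False  # 3D only: also pool along the slice axis
    lr: float = 1e-3

    def kernel(self) -> tuple[int, ...]:
        return (3,) * self.ndim

    def pool_factors(self) -> tuple[int, ...]:
        if self.ndim == 2:
            return (2, 2)
        return (2, 2, 2) if self.axial_pool else (1, 2, 2)


class _Sequential:
    def __init__(self, layers) -> None:
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]


def _block(in_ch, out_ch, kernel, rng) -> _Sequential:
    return _Sequential(
        [ConvND(in_ch, out_ch, kernel, rng), ReLU(),
         ConvND(out_ch, out_ch, kernel, rng), ReLU()]
    )


class UNet:
    """Encoder-decoder with skip connections and a 1-channel logit output."""

    def __init__(self, config: UNetConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0E7]))
        k = config.kernel()
        pf = config.pool_factors()
        ch = [config.base_filters * 2**i for i in range(config.levels)]

        self.enc: list[_Sequential] = []
        self.pools: list[MaxPool] = []
        prev = config.in_channels
        for i in range(config.levels - 1):
            self.enc.append(_block(prev, ch[i], k, rng))
            self.pools.append(MaxPool(pf))
            prev = ch[i]
        self.bottleneck = _block(prev, ch[-1], k, rng)

        self.ups: list[Upsample] = []
        self.upconvs: list[_Sequential] = []
        self.dec: list[_Sequential] = []
        prev = ch[-1]
        for i in reversed(range(config.levels - 1)):
            self.ups.append(Upsample(pf))
            self.upconvs.append(
                _Sequential([ConvND(prev, ch[i], k, rng), ReLU()])
            )
            self.dec.append(_block(2 * ch[i], ch[i], k, rng))
            prev = ch[i]
        self.out_conv = ConvND(prev, 1, (1,) * config.ndim, rng)
        self.trained = False

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        mods = list(self.enc) + [self.bottleneck] + self.upconvs + self.dec
        return mods + [self.out_conv]

    @property
    def params(self):
        out = []
        for m in self._modules():
            out += m.params
        return out

    @property
    def grads(self):
        out = []
        for m in self._modules():
            out += m.grads
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, (up, upconv, dec) in enumerate(zip(self.ups, self.upconvs, self.dec)):
            skip = skips[-(i + 1)]
            h = up.forward(h)
            h = upconv.forward(h)
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h)
        return self.out_conv.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out_conv.backward(dlogits)
        d_skips = []
        for i in reversed(range(len(self.dec))):
            d = self.dec[i].backward(d)
            c = self._skip_channels[-(i + 1)]
            d_skip, d_main = d[:, :c], d[:, c:]
            d_skips.append(d_skip)
            d = self.upconvs[i].backward(np.ascontiguousarray(d_main))
            d = self.ups[i].backward(d)
        d = self.bottleneck.backward(d)
        d_skips.reverse()  # now ordered deepest-skip-first
        for i in reversed(range(len(self.enc))):
            d = self.pools[i].backward(d)
            d = d + d_skips[len(self.enc) - 1 - i]
            d = self.enc[i].backward(d)

    # -- training / inference ----------------------------------------------
    def train_step(self, x: np.ndarray, t: np.ndarray, opt: Adam) -> float:
        logits = self.forward(x)
        loss, dlogits = bce_with_logits(logits, t)
        self.backward(dlogits)
        opt.step()
        return loss

    def make_optimizer(self) -> Adam:
        return Adam(self.params, self.grads, lr=self.config.lr)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError("model has not been trained")
        return sigmoid(self.forward(x))

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez_compressed(
            path,
            _config=json.dumps(asdict(self.config)),
            _seed=self.seed,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path, allow_pickle=False) as data:
            config = UNetConfig(**json.loads(str(data["_config"])))
            model = cls(config, seed=int(data["_seed"]))
            for i, p in enumerate(model.params):
                p[...] = data[f"p{i}"]
        model.trained = True
        return model
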