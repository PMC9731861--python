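"""Backbone registry for the cascade's image classifiers.

Every backbone has a fully convolutional body ending in global average
pooling, so the same weights accept any input size >= the receptive
field: patch-level weights can initialize ROI-level models directly.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, upsample2x
from .layers import Conv2d, Dense, Module, SEBlock, global_avg_pool


class TinyCNN(Module):
    """Three-conv body + GAP; the desk-scale test backbone."""

    def __init__(self, rng: np.random.Generator, in_ch: int = 3,
                 width: int = 8, n_out: int = 1):
        self.c1 = Conv2d(rng, in_ch, width, 3, stride=2)
        self.c2 = Conv2d(rng, width, 2 * width, 3, stride=2)
        self.c3 = Conv2d(rng, 2 * width, 2 * width, 3, stride=1)
        self.feature_dim = 2 * width
        self.head = Dense(rng, self.feature_dim, n_out)
        self.n_out = n_out

    def features(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        h = self.c2(h).relu()
        h = self.c3(h).relu()
        return global_avg_pool(h)

    def logits(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))

    def body_state(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.state_dict().items()
                if not k.startswith("head.")}


class _SEResBlock(Module):
    def __init__(self, rng, channels: int):
        self.c1 = Conv2d(rng, channels, channels, 3)
        self.c2 = Conv2d(rng, channels, channels, 3)
        self.se = SEBlock(rng, channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c2(self.c1(x).relu())
        return (x + self.se(h)).relu()


class SECNN(Module):
    """Squeeze-excitation residual CNN, a reduced-depth SE-ResNet variant."""

    def __init__(self, rng: np.random.Generator, in_ch: int = 3,
                 width: int = 16, n_out: int = 1):
        self.stem = Conv2d(rng, in_ch, width, 3, stride=2)
        self.block1 = _SEResBlock(rng, width)
        self.down = Conv2d(rng, width, 2 * width, 3, stride=2)
        self.block2 = _SEResBlock(rng, 2 * width)
        self.feature_dim = 2 * width
        self.head = Dense(rng, self.feature_dim, n_out)
        self.n_out = n_out

    def features(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        h = self.block1(h)
        h = self.down(h).relu()
        h = self.block2(h)
        return global_avg_pool(h)

    def logits(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))

    def body_state(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.state_dict().items()
                if not k.startswith("head.")}


BACKBONES = {
    "tiny_cnn": TinyCNN,
    "se_cnn": SECNN,
}


def make_backbone(name: str, rng: np.random.Generator, **kwargs):
    if name not in BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; available: {sorted(BACKBONES)}")
    return BACKBONES[name](rng, **kwargs)


class TinyUNet(Module):
    """Small encoder-decoder with one skip connection for pixelwise
    tissue/background segmentation. Input (N,3,H,W) with even H,W;
    output logits (N,1,H,W)."""

    def __init__(self, rng: np.random.Generator, width: int = 8):
        self.enc1 = Conv2d(rng, 3, width, 3)
        self.enc2 = Conv2d(rng, width, 2 * width, 3, stride=2)
        self.mid = Conv2d(rng, 2 * width, 2 * width, 3)
        self.dec1 = Conv2d(rng, 2 * width, width, 3)
        self.out = Conv2d(rng, 2 * width, 1, 1, pad=0)

    def __call__(self, x: Tensor) -> Tensor:
        s1 = self.enc1(x).relu()
        h = self.enc2(s1).relu()
        h = self.mid(h).relu()
        h = self.dec1(upsample2x(h)).relu()
        return self.out(concat([s1, h], axis=1))
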