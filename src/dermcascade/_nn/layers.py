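"""Layer/module abstractions over the autodiff core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d


class Module:
    """Base class: recursive parameter collection and named state dicts."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in vars(self).items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(f"{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{name}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, arr in state.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k!r}")
            if params[k].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            params[k].data = np.array(arr, dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, k: int = 3,
                 stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.w = _he(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Dense(Module):
    def __init__(self, rng, in_dim: int, out_dim: int):
        self.w = _he(rng, (in_dim, out_dim), in_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class SEBlock(Module):
    """Squeeze-and-excitation channel recalibration."""

    def __init__(self, rng, channels: int, reduction: int = 4):
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(rng, channels, hidden)
        self.fc2 = Dense(rng, hidden, channels)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        s = x.mean(axis=(2, 3))                     # squeeze: (N,C)
        e = self.fc2(self.fc1(s).relu()).sigmoid()  # excite:  (N,C)
        return x * e.reshape(n, self.channels, 1, 1)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C)."""
    return x.mean(axis=(2, 3))
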