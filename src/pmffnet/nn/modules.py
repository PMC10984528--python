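"""Module/parameter containers over the autograd engine."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal_(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal at ±2 std (resampling rejection)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(np.float32)


def kaiming_conv(rng: np.random.Generator, shape) -> np.ndarray:
    """Fan-out-scaled normal init for conv weights (Cout,Cin,Kh,Kw)."""
    fan_out = shape[0] * shape[2] * shape[3]
    std = float(np.sqrt(2.0 / fan_out))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def _walk(value, prefix: str):
    """Yield (name, Parameter) pairs from nested modules/lists/tuples."""
    if isinstance(value, Parameter):
        yield prefix, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix)
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk(item, f"{prefix}.{i}")


class Module:
    """Minimal parameter container with named recursion."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            yield from _walk(value, full)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)[:5]}, "
                           f"unexpected={sorted(unexpected)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 *, stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        shape = (out_channels, in_channels, kernel_size, kernel_size)
        self.weight = Parameter(kaiming_conv(rng, shape))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(trunc_normal_(rng, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError(f"groups ({groups}) must divide channels ({channels})")
        self.groups, self.eps = groups, eps
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.group_norm(x, self.weight, self.bias, self.groups, self.eps)


class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of (B,C,H,W) maps."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        xt = x.transpose(0, 2, 3, 1)
        yt = F.layer_norm(xt, self.weight, self.bias, self.eps)
        return yt.transpose(0, 3, 1, 2)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
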