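"""V2S encoder: a four-stage hybrid CNN-transformer pyramid backbone.

Each stage is a reduction cell (RC — strided convolutional embedding with a
parallel dilated-convolution path for locality bias) followed by a stack of
normal cells (NC — windowed self-attention plus a parallel 3x3 convolution
and a feed-forward block, pre-norm residual wiring).  The four stages
down-sample by 4x, 2x, 2x, 2x, so a 384x384 input yields pyramid taps with
spatial sides 96, 48, 24 and 12 (strides 4/8/16/32), taken after the last
NC of each stage.

Attention is window-based.  With ``vsa=True`` (default) the fixed key/value
windows are replaced by Varied-Size Window Attention: a small regression
head pools each default window and predicts a per-head scale and offset;
keys and values are then re-sampled from the scaled/offset window by
bilinear interpolation, clamped to the feature extent.  The regression
output layer is zero-initialized, so an untrained VSA layer reproduces
fixed-window attention exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .nn import (ChannelLayerNorm, Conv2d, GroupNorm, Linear, Module,
                 Parameter, Tensor, pad2d, trunc_normal_)
from .nn import functional as F

STAGE_FACTORS = (4, 2, 2, 2)


@dataclass
class StagePlan:
    """Per-stage widths/depths of the backbone (four stages, strides 4/8/16/32)."""

    channels: tuple = (64, 128, 256, 384)
    depths: tuple = (2, 2, 7, 2)
    heads: tuple = (2, 4, 8, 12)
    window: int = 7
    vsa: bool = True
    mlp_ratio: float = 2.75

    def __post_init__(self):
        for name in ("channels", "depths", "heads"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} must list exactly 4 stages")
        for c, h in zip(self.channels, self.heads):
            if c % h:
                raise ValueError(f"heads ({h}) must divide channels ({c})")


@lru_cache(maxsize=32)
def _relative_index(win_eff: int, win_max: int) -> np.ndarray:
    """(ws, ws) index into a flattened (2*win_max-1)^2 bias table."""
    coords = np.stack(np.meshgrid(np.arange(win_eff), np.arange(win_eff),
                                  indexing="ij"), axis=-1).reshape(-1, 2)
    rel = coords[:, None, :] - coords[None, :, :] + (win_max - 1)
    return (rel[..., 0] * (2 * win_max - 1) + rel[..., 1]).astype(np.int64)


def _window_split(t: Tensor, heads: int, w: int) -> Tensor:
    """(B, heads*hd, Hp, Wp) -> (B, heads, nWin, w*w, hd)."""
    B, C, Hp, Wp = t.shape
    hd = C // heads
    nH, nW = Hp // w, Wp // w
    t = t.reshape(B, heads, hd, nH, w, nW, w)
    t = t.transpose(0, 1, 3, 5, 4, 6, 2)
    return t.reshape(B, heads, nH * nW, w * w, hd)


def _window_merge(t: Tensor, Hp: int, Wp: int, w: int) -> Tensor:
    """(B, heads, nWin, w*w, hd) -> (B, heads*hd, Hp, Wp)."""
    B, heads, nWin, ws, hd = t.shape
    nH, nW = Hp // w, Wp // w
    t = t.reshape(B, heads, nH, nW, w, w, hd)
    t = t.transpose(0, 1, 6, 2, 4, 3, 5)
    return t.reshape(B, heads * hd, Hp, Wp)


class WindowAttention(Module):
    """Window multi-head self-attention with optional varied-size windows."""

    def __init__(self, channels: int, heads: int, window: int = 7, *,
                 vsa: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if channels % heads:
            raise ValueError("heads must divide channels")
        self.channels, self.heads, self.window, self.vsa = channels, heads, window, vsa
        self.qkv = Conv2d(channels, 3 * channels, 1, rng=rng)
        self.proj = Conv2d(channels, channels, 1, rng=rng)
        self.rel_bias = Parameter(
            trunc_normal_(rng, (heads, (2 * window - 1) ** 2)))
        if vsa:
            hidden = max(channels // 4, 8)
            self.reg1 = Linear(channels, hidden, rng=rng)
            self.reg2 = Linear(hidden, heads * 4, rng=rng)
            # zero-init so that scale = exp(0) = 1, offset = 0: identity windows
            self.reg2.weight.data[:] = 0.0
            self.reg2.bias.data[:] = 0.0

    def _varied_kv(self, kv: Tensor, pooled: Tensor, w: int,
                   Hp: int, Wp: int) -> tuple:
        """Sample per-head varied windows of k and v by bilinear interpolation."""
        B, _, _, _ = kv.shape
        heads, hd = self.heads, self.channels // self.heads
        nH, nW = Hp // w, Wp // w
        nWin = nH * nW
        reg = F.linear(pooled, self.reg1.weight, self.reg1.bias).silu()
        reg = F.linear(reg, self.reg2.weight, self.reg2.bias)  # (B,nWin,heads*4)
        reg = reg.reshape(B, nWin, heads, 4).transpose(0, 2, 1, 3)
        scale_y = reg[:, :, :, 0].clip(-4.0, 4.0).exp()   # (B,heads,nWin)
        scale_x = reg[:, :, :, 1].clip(-4.0, 4.0).exp()
        off_y = reg[:, :, :, 2]
        off_x = reg[:, :, :, 3]
        half = (w - 1) / 2.0
        cy = (np.repeat(np.arange(nH), nW) * w + half).astype(np.float32)
        cx = (np.tile(np.arange(nW), nH) * w + half).astype(np.float32)
        rel = (np.arange(w) - half).astype(np.float32)
        # (B,heads,nWin,w): varied row / column coordinates
        ys = scale_y.reshape(B, heads, nWin, 1) * rel.reshape(1, 1, 1, w) \
            + (off_y + Tensor(cy)).reshape(B, heads, nWin, 1)
        xs = scale_x.reshape(B, heads, nWin, 1) * rel.reshape(1, 1, 1, w) \
            + (off_x + Tensor(cx)).reshape(B, heads, nWin, 1)
        # full grid: ys over rows, xs over cols -> (B,heads,nWin,w,w)
        ones = np.ones((1, 1, 1, 1, w), np.float32)
        yg = ys.reshape(B, heads, nWin, w, 1) * Tensor(ones)
        xg = xs.reshape(B, heads, nWin, 1, w) * Tensor(np.ones((1, 1, 1, w, 1),
                                                              np.float32))
        P = nWin * w * w
        yf = yg.reshape(B * heads, P)
        xf = xg.reshape(B * heads, P)
        k_grid, v_grid = kv[:, :heads * hd], kv[:, heads * hd:]

        def sample(grid):
            samp = F.bilinear_gather(grid.reshape(B * heads, hd, Hp, Wp), yf, xf)
            samp = samp.reshape(B, heads, hd, nWin, w * w)
            return samp.transpose(0, 1, 3, 4, 2)         # (B,heads,nWin,ws,hd)

        return sample(k_grid), sample(v_grid)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        w = min(self.window, H, W)
        if w < 1:
            raise ValueError("empty feature map")
        pad_h = (-H) % w
        pad_w = (-W) % w
        xp = pad2d(x, (0, pad_h, 0, pad_w))
        Hp, Wp = H + pad_h, W + pad_w
        heads, hd = self.heads, C // self.heads
        qkv = self.qkv(xp)                                # (B,3C,Hp,Wp)
        q = _window_split(qkv[:, :C], heads, w)           # (B,heads,nWin,ws,hd)
        if self.vsa:
            nH, nW = Hp // w, Wp // w
            pooled = xp.reshape(B, C, nH, w, nW, w).mean(axis=(3, 5))
            pooled = pooled.reshape(B, C, nH * nW).transpose(0, 2, 1)
            k, v = self._varied_kv(qkv[:, C:], pooled, w, Hp, Wp)
        else:
            k = _window_split(qkv[:, C:2 * C], heads, w)
            v = _window_split(qkv[:, 2 * C:], heads, w)
        attn = (q @ k.transpose(0, 1, 2, 4, 3)) * (hd ** -0.5)
        idx = _relative_index(w, self.window)
        bias = F.take_last(self.rel_bias, idx)            # (heads, ws, ws)
        attn = attn + bias.reshape(1, heads, 1, w * w, w * w)
        attn = F.softmax(attn, axis=-1)
        out = _window_merge(attn @ v, Hp, Wp, w)
        if pad_h or pad_w:
            out = out[:, :, :H, :W]
        return self.proj(out)


class ReductionCell(Module):
    """RC: strided conv stem + parallel dilated conv (locality bias) + mixing."""

    def __init__(self, in_channels: int, out_channels: int, factor: int, *,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.factor = factor
        k = 2 * factor - 1
        self.stem = Conv2d(in_channels, out_channels, k, stride=factor,
                           padding=(k - 1) // 2, rng=rng)
        self.pyr = Conv2d(in_channels, out_channels, 3, stride=factor,
                          padding=2, dilation=2, rng=rng)
        self.norm = GroupNorm(8, out_channels)
        self.mix = Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] % self.factor or x.shape[-2] % self.factor:
            raise ValueError(f"spatial side {x.shape[-2:]} not divisible by "
                             f"stage factor {self.factor}")
        y = self.stem(x) + self.pyr(x)
        y = self.norm(y).silu()
        return y + self.mix(y).silu()


class NormalCell(Module):
    """NC: pre-norm window attention + parallel conv path + feed-forward."""

    def __init__(self, channels: int, heads: int, window: int, *,
                 vsa: bool = True, mlp_ratio: float = 2.75,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.ln1 = ChannelLayerNorm(channels)
        self.attn = WindowAttention(channels, heads, window, vsa=vsa, rng=rng)
        self.pcm = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.ln2 = ChannelLayerNorm(channels)
        hidden = int(channels * mlp_ratio)
        self.ffn1 = Conv2d(channels, hidden, 1, rng=rng)
        self.ffn2 = Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x)) + self.pcm(x).silu()
        return x + self.ffn2(self.ffn1(self.ln2(x)).silu())


class V2SBackbone(Module):
    """Four-stage pyramid encoder; taps after the last NC of each stage."""

    def __init__(self, plan: StagePlan | None = None, in_channels: int = 3, *,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.plan = plan or StagePlan()
        p = self.plan
        self.rcs, self.ncs = [], []
        prev = in_channels
        for s in range(4):
            self.rcs.append(ReductionCell(prev, p.channels[s],
                                          STAGE_FACTORS[s], rng=rng))
            self.ncs.append([NormalCell(p.channels[s], p.heads[s], p.window,
                                        vsa=p.vsa, mlp_ratio=p.mlp_ratio,
                                        rng=rng)
                             for _ in range(p.depths[s])])
            prev = p.channels[s]

    def rc_forward(self, x: Tensor, stage: int) -> Tensor:
        return self.rcs[stage](x)

    def nc_forward(self, x: Tensor, stage: int) -> Tensor:
        for nc in self.ncs[stage]:
            x = nc(x)
        return x

    def forward(self, image) -> list:
        """Image (B,3,H,W) with H, W divisible by 32 -> 4 pyramid taps."""
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected a (B,3,H,W) image batch")
        if x.shape[-1] % 32 or x.shape[-2] % 32:
            raise ValueError(f"input side {x.shape[-2:]} must be divisible by "
                             "32; resize the image (e.g. to 384x384) first")
        taps = []
        for s in range(4):
            x = self.rc_forward(x, s)
            x = self.nc_forward(x, s)
            taps.append(x)
        return taps

    def load_pretrained(self, state: dict):
        """Load externally supplied backbone weights (same stage plan)."""
        self.load_state_dict(state)
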