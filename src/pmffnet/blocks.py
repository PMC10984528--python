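"""Convolutional building blocks and the multi-scale feature fusion block.

Block vocabulary (all 3x3, stride 1, spatial-size preserving):

* ``ConvBlock`` (CB): dilated conv -> group norm -> SiLU -> residual add
  (with a learned 1x1 projection when the channel count changes);
* ``ResBlock`` (RB): two cascaded CBs at dilation 1;
* ``DilatedBlock`` (DB): three cascaded CBs following a hybrid-dilated-
  convolution schedule, by default dilations (1, 2, 5);
* ``ERFBranch``: two cascaded DBs — the expanded-receptive-field branch
  (33x33 input footprint);
* ``LocalEmphasis`` (LE): two cascaded RBs — local detail branch
  (9x9 footprint);
* ``MultiScaleFusionBlock`` (MFB): ERF and LE in parallel on one pyramid
  level, channel-concatenated and fused by two RBs down to ``width``
  channels.

Every branch first projects the backbone channels to ``width`` (default 64)
so the decoder's skip concatenations are always 64 + 64 = 128 channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import hdc
from .nn import Conv2d, GroupNorm, Module, Tensor, cat

DEFAULT_DILATIONS = (1, 2, 5)


@dataclass
class BlockConfig:
    in_channels: int
    out_channels: int
    dilation: int = 1
    groups_for_norm: int = 8
    use_norm: bool = True

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.use_norm and self.out_channels % self.groups_for_norm:
            raise ValueError("groups_for_norm must divide out_channels")


class ConvBlock(Module):
    """CB: 3x3 dilated conv + group norm + SiLU + residual connection."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.conv = Conv2d(cfg.in_channels, cfg.out_channels, 3,
                           padding=cfg.dilation, dilation=cfg.dilation, rng=rng)
        self.norm = GroupNorm(cfg.groups_for_norm, cfg.out_channels) \
            if cfg.use_norm else None
        self.proj = None
        if cfg.in_channels != cfg.out_channels:
            self.proj = Conv2d(cfg.in_channels, cfg.out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, "
                             f"got {x.shape[1]}")
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        y = y.silu()
        res = self.proj(x) if self.proj is not None else x
        return y + res


class ResBlock(Module):
    """RB: two cascaded CBs, both at dilation 1."""

    def __init__(self, in_channels: int, out_channels: int, *,
                 groups_for_norm: int = 8, use_norm: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cb1 = ConvBlock(BlockConfig(in_channels, out_channels, 1,
                                         groups_for_norm, use_norm), rng)
        self.cb2 = ConvBlock(BlockConfig(out_channels, out_channels, 1,
                                         groups_for_norm, use_norm), rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.cb2(self.cb1(x))


class DilatedBlock(Module):
    """DB: three cascaded CBs following an HDC dilation schedule.

    The schedule must satisfy the hard HDC rules (no common divisor > 1, no
    constant dilation, M2 <= K, M1 == 1); a merely monotone schedule only
    warns inside :func:`pmffnet.hdc.rule_check`.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 dilations=DEFAULT_DILATIONS, *, groups_for_norm: int = 8,
                 use_norm: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if len(dilations) != 3:
            raise ValueError("DilatedBlock expects a 3-layer dilation schedule")
        schedule = hdc.DilationSchedule.from_dilations(dilations)
        report = hdc.rule_check(schedule)
        if not report.passed:
            raise ValueError(f"dilation schedule {tuple(dilations)} violates HDC "
                             f"rules: {report.violations}")
        self.dilations = tuple(dilations)
        chans = [in_channels] + [out_channels] * 3
        self.cbs = [ConvBlock(BlockConfig(chans[i], chans[i + 1], d,
                                          groups_for_norm, use_norm), rng)
                    for i, d in enumerate(dilations)]

    def forward(self, x: Tensor) -> Tensor:
        for cb in self.cbs:
            x = cb(x)
        return x


class ERFBranch(Module):
    """Expanded-receptive-field branch: two cascaded DBs."""

    def __init__(self, in_channels: int, width: int = 64,
                 dilations=DEFAULT_DILATIONS, *, use_norm: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.db1 = DilatedBlock(in_channels, width, dilations,
                                use_norm=use_norm, rng=rng)
        self.db2 = DilatedBlock(width, width, dilations,
                                use_norm=use_norm, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.db2(self.db1(x))


class LocalEmphasis(Module):
    """Local-emphasis branch: two cascaded RBs (all dilation 1)."""

    def __init__(self, in_channels: int, width: int = 64, *,
                 use_norm: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.rb1 = ResBlock(in_channels, width, use_norm=use_norm, rng=rng)
        self.rb2 = ResBlock(width, width, use_norm=use_norm, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.rb2(self.rb1(x))


class MultiScaleFusionBlock(Module):
    """MFB: parallel ERF + LE, concatenated, fused by two RBs to ``width``."""

    def __init__(self, in_channels: int, width: int = 64,
                 dilations=DEFAULT_DILATIONS, *,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.erf = ERFBranch(in_channels, width, dilations, rng=rng)
        self.le = LocalEmphasis(in_channels, width, rng=rng)
        self.fuse1 = ResBlock(2 * width, width, rng=rng)
        self.fuse2 = ResBlock(width, width, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        merged = cat([self.erf(x), self.le(x)], axis=1)
        return self.fuse2(self.fuse1(merged))


# aliases matching the architecture diagrams
CB = ConvBlock
RB = ResBlock
DB = DilatedBlock
MFB = MultiScaleFusionBlock
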