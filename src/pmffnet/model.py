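"""PMFFNet assembly: backbone pyramid -> per-scale MFB -> decoder -> head.

The decoder fuses the four 64-channel MFB outputs coarse-to-fine: each step
up-samples by exactly 2x (bilinear), concatenates with the next-shallower
MFB output (64 + 64 = 128 channels) and applies two RBs (128 -> 64,
64 -> 64).  After the stride-4 step the 64-channel map is up-sampled to the
input resolution and a prediction head (two RBs and a 1x1 convolution)
emits one logit per pixel; sigmoid/thresholding happen in the loss and
inference layers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .backbone import StagePlan, V2SBackbone
from .blocks import DEFAULT_DILATIONS, MultiScaleFusionBlock, ResBlock
from .nn import Conv2d, Module, Tensor, cat, no_grad
from .nn import functional as F

__all__ = ["ModelConfig", "Decoder", "PredictionHead", "PMFFNet",
           "count_parameters", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    channels: tuple = (64, 128, 256, 384)
    depths: tuple = (2, 2, 7, 2)
    heads: tuple = (2, 4, 8, 12)
    window: int = 7
    vsa: bool = True
    mlp_ratio: float = 2.75
    mfb_width: int = 64
    dilations: tuple = DEFAULT_DILATIONS
    in_channels: int = 3

    def stage_plan(self) -> StagePlan:
        return StagePlan(tuple(self.channels), tuple(self.depths),
                         tuple(self.heads), self.window, self.vsa,
                         self.mlp_ratio)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        cfg = cls(**d)
        for name in ("channels", "depths", "heads", "dilations"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


class Decoder(Module):
    """Progressive 2x fusion of the four MFB maps down to stride 4."""

    def __init__(self, width: int = 64, *, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.width = width
        self.steps = [[ResBlock(2 * width, width, rng=rng),
                       ResBlock(width, width, rng=rng)] for _ in range(3)]

    def forward(self, maps: list, out_size: tuple, taps: dict | None = None):
        if len(maps) != 4:
            raise ValueError("decoder expects 4 pyramid maps")
        for m in maps:
            if m.shape[1] != self.width:
                raise ValueError(f"decoder expects {self.width}-channel maps, "
                                 f"got {m.shape[1]}")
        x = maps[3]
        for i, skip in enumerate((maps[2], maps[1], maps[0])):
            x = F.bilinear_resize(x, skip.shape[2], skip.shape[3])
            x = cat([x, skip], axis=1)          # 64 + 64 = 128 channels
            rb1, rb2 = self.steps[i]
            x = rb2(rb1(x))
            if taps is not None:
                taps[f"decoder_{i}"] = x
        return F.bilinear_resize(x, out_size[0], out_size[1])


class PredictionHead(Module):
    """Two RBs and a 1x1 convolution producing one logit channel."""

    def __init__(self, width: int = 64, *, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.rb1 = ResBlock(width, width, rng=rng)
        self.rb2 = ResBlock(width, width, rng=rng)
        self.out = Conv2d(width, 1, 1, rng=rng)
        # start at p = 0.5 everywhere: well-scaled initial loss and gradients
        self.out.weight.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.rb2(self.rb1(x)))


class PMFFNet(Module):
    """Encoder-decoder segmentation network for ovarian-tumor ultrasound."""

    def __init__(self, config: ModelConfig | None = None,
                 seed: int | None = None):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.backbone = V2SBackbone(cfg.stage_plan(), cfg.in_channels, rng=rng)
        self.mfbs = [MultiScaleFusionBlock(c, cfg.mfb_width, cfg.dilations,
                                           rng=rng)
                     for c in cfg.channels]
        self.decoder = Decoder(cfg.mfb_width, rng=rng)
        self.head = PredictionHead(cfg.mfb_width, rng=rng)

    def forward(self, image, return_taps: bool = False):
        x = image if isinstance(image, Tensor) else Tensor(image)
        pyramid = self.backbone(x)
        taps = {} if return_taps else None
        if return_taps:
            for s, t in enumerate(pyramid):
                taps[f"v2s_{s}"] = t
        mfb_maps = []
        for s, (mfb, t) in enumerate(zip(self.mfbs, pyramid)):
            if return_taps:
                taps[f"le_{s}"] = mfb.le(t)
                taps[f"erf_{s}"] = mfb.erf(t)
                merged = cat([taps[f"erf_{s}"], taps[f"le_{s}"]], axis=1)
                m = mfb.fuse2(mfb.fuse1(merged))
                taps[f"mfb_{s}"] = m
            else:
                m = mfb(t)
            mfb_maps.append(m)
        dec = self.decoder(mfb_maps, (x.shape[2], x.shape[3]), taps)
        logits = self.head(dec)
        return (logits, taps) if return_taps else logits

    def predict_proba(self, image) -> np.ndarray:
        """Sigmoid probabilities in eval (no-grad) mode."""
        with no_grad():
            logits = self.forward(image)
            return logits.sigmoid().numpy()


def count_parameters(model: Module) -> int:
    """Number of trainable scalar parameters."""
    return model.num_parameters()


def save_checkpoint(path, model: PMFFNet, extra: dict | None = None):
    """Serialize weights + config (+ a small JSON metadata dict) to .npz."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    arrays["__extra__"] = np.frombuffer(
        json.dumps(extra or {}).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple:
    """Restore a model from :func:`save_checkpoint`; returns (model, extra)."""
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        extra = json.loads(bytes(data["__extra__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    model = PMFFNet(cfg, seed=0)
    model.load_state_dict(state)
    return model, extra
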