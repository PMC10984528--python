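"""Training, evaluation and prediction pipeline.

The optimization protocol: AdamW (initial lr 1e-4), compound BCE + Dice
loss, batch size 8 for 100 epochs, validation mDice monitored every epoch;
when it fails to improve for ``plateau_patience`` (10) consecutive epochs
the learning rate is halved, and the checkpoint with the best validation
mDice is kept as the final model.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import data as data_mod
from .losses import total_loss_from_logits
from .metrics import confusion, mean_metrics, metrics_from_counts, write_metrics_csv
from .model import PMFFNet, save_checkpoint
from .nn import AdamW, ReduceLROnPlateau, no_grad

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    lr: float = 1e-4
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 0.01
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0,1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


@dataclass
class RunLog:
    train_loss: list = field(default_factory=list)
    val_mdice: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    best_mdice: float = -1.0
    best_checksum: str = ""


def _state_checksum(state: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name]).tobytes())
    return h.hexdigest()


def _batches(pairs, batch_size, rng, do_augment):
    order = rng.permutation(len(pairs))
    for start in range(0, len(pairs), batch_size):
        chunk = [pairs[i] for i in order[start:start + batch_size]]
        if do_augment:
            chunk = [data_mod.augment(x, m, rng) for x, m in chunk]
        xs = np.stack([c[0] for c in chunk])
        ms = np.stack([c[1] for c in chunk])
        yield xs, ms


def fit(model: PMFFNet, train_set, val_set, cfg: TrainConfig,
        checkpoint_path=None, steps_per_epoch: int | None = None,
        val_metric_fn=None):
    """Optimize the compound loss; returns ``(RunLog, best_state_dict)``.

    ``train_set``/``val_set`` are lists of preprocessed ``(image, mask)``
    pairs ((3,S,S) float32, (S,S) {0,1} float32).  ``val_metric_fn``, when
    given, replaces validation evaluation by ``val_metric_fn(epoch)`` — a
    diagnostic hook used to exercise the plateau schedule against scripted
    metric sequences.  ``steps_per_epoch`` caps optimizer steps per epoch.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, mode="max", factor=cfg.plateau_factor,
                              patience=cfg.plateau_patience)
    runlog = RunLog()
    best_state = None
    for epoch in range(cfg.epochs):
        losses = []
        for step, (xs, ms) in enumerate(_batches(train_set, cfg.batch_size,
                                                 rng, cfg.augment)):
            if steps_per_epoch is not None and step >= steps_per_epoch:
                break
            opt.zero_grad()
            logits = model(xs).reshape(ms.shape)
            loss = total_loss_from_logits(ms, logits)
            lv = loss.item()
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"training diverged: loss={lv} at epoch {epoch}, step {step}")
            loss.backward()
            opt.step()
            losses.append(lv)
        if val_metric_fn is not None:
            mdice = float(val_metric_fn(epoch))
        else:
            mdice = evaluate(model, val_set)[0].m_dice
        sched.step(mdice)
        runlog.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
        runlog.val_mdice.append(mdice)
        runlog.lr.append(opt.lr)
        if mdice > runlog.best_mdice:
            runlog.best_mdice = mdice
            runlog.best_epoch = epoch
            best_state = model.state_dict()
            if checkpoint_path is not None:
                save_checkpoint(checkpoint_path, model,
                                extra={"epoch": epoch, "val_mdice": mdice})
        log.info("epoch %d: loss=%.4f val_mDice=%.4f lr=%.2e",
                 epoch, runlog.train_loss[-1], mdice, opt.lr)
    runlog.best_checksum = _state_checksum(best_state)
    return runlog, best_state


def evaluate(model, test_set, ids=None, csv_path=None, smooth: float = 1.0,
             batch_size: int = 4):
    """Threshold predictions at 0.5 and report per-image + mean metrics.

    ``model`` needs only a ``predict_proba(batch) -> (B,1,S,S)`` method, so
    oracle stubs can stand in for a network.  Returns
    ``(MetricReport, [ImageMetrics])`` in input order.
    """
    test_set = list(test_set)
    if not test_set:
        raise ValueError("evaluation set must be non-empty")
    per_image = []
    for start in range(0, len(test_set), batch_size):
        chunk = test_set[start:start + batch_size]
        xs = np.stack([c[0] for c in chunk])
        probs = model.predict_proba(xs).reshape(len(chunk), *chunk[0][1].shape)
        for (_, mask), p in zip(chunk, probs):
            per_image.append(metrics_from_counts(
                confusion(mask, p >= 0.5), smooth=smooth))
    report = mean_metrics(per_image)
    if csv_path is not None:
        write_metrics_csv(csv_path, ids or range(len(per_image)),
                          per_image, report)
    return report, per_image


ACTIVATION_TAPS = ("v2s", "le", "erf", "mfb", "decoder")


def _save_activation(tap: Tensor, path: Path):
    """Channel-mean of a feature map as an 8-bit grayscale PNG."""
    amap = tap.numpy()[0].mean(axis=0)
    lo, hi = amap.min(), amap.max()
    amap = (amap - lo) / (hi - lo + 1e-9)
    Image.fromarray((amap * 255).astype(np.uint8)).save(path)


def predict(model: PMFFNet, image_path, out_path, side: int = 384,
            mean=data_mod.DEFAULT_MEAN, std=data_mod.DEFAULT_STD,
            activations_dir=None) -> np.ndarray:
    """Segment one image file; writes a binary PNG at the input resolution.

    With ``activations_dir``, channel-mean activation maps of the V2S, LE,
    ERF, MFB and decoder taps are exported per pyramid scale.
    """
    try:
        with Image.open(image_path) as im:
            rgb = im.convert("RGB")
    except OSError as exc:
        raise ValueError(f"cannot read image {image_path}: {exc}") from exc
    orig_w, orig_h = rgb.size
    x = np.asarray(rgb.resize((side, side), Image.BILINEAR),
                   dtype=np.float32) / 255.0
    x = (x - np.asarray(mean, np.float32)) / np.asarray(std, np.float32)
    batch = x.transpose(2, 0, 1)[None]
    with no_grad():
        if activations_dir is not None:
            logits, taps = model.forward(batch, return_taps=True)
            adir = Path(activations_dir)
            adir.mkdir(parents=True, exist_ok=True)
            for name, tap in taps.items():
                _save_activation(tap, adir / f"{name}.png")
        else:
            logits = model.forward(batch)
        probs = logits.sigmoid().numpy()[0, 0]
    mask = (probs >= 0.5).astype(np.uint8) * 255
    out = Image.fromarray(mask).resize((orig_w, orig_h), Image.NEAREST)
    out.save(out_path)
    return (np.asarray(out) > 127).astype(np.uint8)
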