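"""Dataset I/O, preprocessing, augmentation and splits.

Directory layout (MMOTU-style)::

    <root>/<subset>/images/<id>.png     (grayscale or RGB)
    <root>/<subset>/masks/<id>.png      (8-bit; binarized at 127)
    <root>/classes.csv                  (optional: id,category — used to
                                         exclude normal-ovary samples)

Images are resized bilinearly to ``side x side`` (default 384) and
normalized; masks are resized nearest-neighbour so they stay strictly
binary.  Training-time augmentation is an independent 50% horizontal and
50% vertical flip applied identically to image and mask.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

log = logging.getLogger(__name__)

SUBSETS = ("train", "val", "test", "generalization")
NORMAL_CATEGORY = "normal ovary"

# Per-channel normalization of [0,1] intensities.  Defaults are the corpus
# statistics of the phantom generator at its default configuration; both are
# config-overridable and embedded in checkpoints via TrainConfig.
DEFAULT_MEAN = (0.5, 0.5, 0.5)
DEFAULT_STD = (0.25, 0.25, 0.25)


@dataclass
class SampleRecord:
    id: str
    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    subset: str = "train"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(f"{self.id}: image/mask size mismatch")


def _load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _load_mask(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def read_class_manifest(path) -> dict:
    """classes.csv with columns (id, category) -> {id: category}."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if len(row) >= 2 and row[0].strip().lower() != "id":
                out[row[0].strip()] = row[1].strip()
    return out


def load_dataset(root, subset: str = "train",
                 exclude_categories=(NORMAL_CATEGORY,)) -> list:
    """Load paired image/mask records; skips unpaired files with a warning.

    When ``<root>/classes.csv`` exists, samples whose category matches
    ``exclude_categories`` (case-insensitive) are dropped — the analogue of
    removing normal-ovary samples from a binary lesion-segmentation task.
    """
    root = Path(root)
    img_dir = root / subset / "images"
    mask_dir = root / subset / "masks"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images directory at {img_dir}")
    manifest = {}
    if (root / "classes.csv").exists():
        manifest = read_class_manifest(root / "classes.csv")
    excluded = {c.lower() for c in exclude_categories}
    records = []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        sid = img_path.stem
        mask_path = None
        for ext in (".png", ".jpg", ".jpeg"):
            cand = mask_dir / (sid + ext)
            if cand.exists():
                mask_path = cand
                break
        if mask_path is None:
            warnings.warn(f"no mask for image {img_path.name}; skipping")
            continue
        if manifest.get(sid, "").lower() in excluded:
            log.info("excluding %s (category %r)", sid, manifest[sid])
            continue
        records.append(SampleRecord(sid, _load_image(img_path),
                                    _load_mask(mask_path), subset))
    if not records:
        raise ValueError(f"no image/mask pairs found under {root}/{subset}")
    return records


def preprocess(rec: SampleRecord, side: int = 384,
               mean=DEFAULT_MEAN, std=DEFAULT_STD) -> tuple:
    """Resize + normalize one record.

    Returns ``(image, mask)`` with image (3, side, side) float32 and mask
    (side, side) float32 in {0, 1}.
    """
    img = Image.fromarray(rec.image).resize((side, side), Image.BILINEAR)
    x = np.asarray(img, dtype=np.float32) / 255.0
    x = (x - np.asarray(mean, np.float32)) / np.asarray(std, np.float32)
    x = np.ascontiguousarray(x.transpose(2, 0, 1))
    msk = Image.fromarray(rec.mask * 255).resize((side, side), Image.NEAREST)
    m = (np.asarray(msk) > 127).astype(np.float32)
    assert set(np.unique(m)) <= {0.0, 1.0}, "mask must stay binary"
    return x, m


def augment(image: np.ndarray, mask: np.ndarray,
            rng: np.random.Generator) -> tuple:
    """Independent 50% horizontal / 50% vertical flips (image+mask in sync)."""
    if rng.random() < 0.5:
        image = image[..., ::-1]
        mask = mask[..., ::-1]
    if rng.random() < 0.5:
        image = image[..., ::-1, :]
        mask = mask[..., ::-1, :] if mask.ndim > 1 else mask
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def split_train_val(records, fraction: float = 0.8, seed: int = 0) -> tuple:
    """Seeded shuffle, then an 80/20 (by default) train/validation split."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0,1)")
    idx = np.random.default_rng(seed).permutation(len(records))
    n_train = int(round(fraction * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    train = [records[i] for i in idx[:n_train]]
    val = [records[i] for i in idx[n_train:]]
    return train, val
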