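"""Synthetic speckle-ultrasound phantoms.

Each phantom emulates the gross appearance of a B-mode ovarian ultrasound
frame: a smooth low-frequency echogenicity field multiplied by gamma-
distributed unit-mean speckle, containing exactly one hypoechoic (darker)
lesion — an ellipse whose boundary radius is perturbed sinusoidally and
whose edge is blurred, as lesion margins are in ultrasound.  The paired
mask is the exact perturbed-ellipse interior, so segmentation targets are
pixel-accurate by construction.

The generator is fully deterministic given (config, seed) and writes
corpora in the same directory layout :func:`pmffnet.data.load_dataset`
reads, so the whole pipeline can be exercised without any downloads.  A
``shifted=True`` corpus changes speckle heaviness and lesion contrast to
emulate evaluating on a different acquisition (a generalization set).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data import SampleRecord

__all__ = ["PhantomConfig", "generate_phantom", "generate_corpus"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic corpus.

    ``image_size`` is a (min, max) range of sides drawn per phantom (MMOTU
    frames vary in size); lesion area is drawn uniformly from
    ``area_fraction`` of the image; ``contrast`` multiplies the lesion
    interior (hypoechoic < 1); ``speckle_shape`` is the gamma shape of the
    unit-mean multiplicative speckle (larger = milder noise);
    ``boundary_amplitude`` scales the sinusoidal radius perturbation.
    """

    image_size: tuple = (192, 320)
    area_fraction: tuple = (0.05, 0.25)
    contrast: float = 0.45
    speckle_shape: float = 4.0
    boundary_amplitude: float = 0.12
    edge_blur: float = 2.0
    seed: int = 0

    def __post_init__(self):
        f_min, f_max = self.area_fraction
        if not 0.0 < f_min < f_max < 0.6:
            raise ValueError("area_fraction must satisfy 0 < f_min < f_max < 0.6")
        if self.image_size[0] > self.image_size[1] or self.image_size[0] < 32:
            raise ValueError("image_size must be (min, max) with min >= 32")


def _lesion_mask(h: int, w: int, frac: float, amp: float,
                 rng: np.random.Generator) -> np.ndarray:
    """One perturbed-ellipse interior with the requested area fraction."""
    area = frac * h * w
    ratio = rng.uniform(0.6, 1.0)               # minor/major axis ratio
    a = np.sqrt(area / (np.pi * ratio))          # major semi-axis
    b = a * ratio
    theta0 = rng.uniform(0, 2 * np.pi)           # orientation
    margin_y = min(1.3 * a, h / 2 - 1)
    margin_x = min(1.3 * a, w / 2 - 1)
    cy = rng.uniform(margin_y, h - margin_y)
    cx = rng.uniform(margin_x, w - margin_x)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ry = dy * np.cos(theta0) - dx * np.sin(theta0)
    rx = dy * np.sin(theta0) + dx * np.cos(theta0)
    r = np.sqrt((ry / b) ** 2 + (rx / a) ** 2)   # 1.0 on the base ellipse
    phi = np.arctan2(ry, rx)
    wobble = np.zeros_like(phi)
    for k, (ak, pk) in enumerate(zip(rng.uniform(0.3, 1.0, 3),
                                     rng.uniform(0, 2 * np.pi, 3)), start=2):
        wobble += ak * np.sin(k * phi + pk)
    boundary = 1.0 + amp * wobble / 3.0
    return (r <= boundary).astype(np.uint8)


def generate_phantom(cfg: PhantomConfig, seed: int | None = None) -> SampleRecord:
    """One reproducible phantom; ``seed`` overrides ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.image_size
    h = int(rng.integers(lo, hi + 1))
    w = int(rng.integers(lo, hi + 1))
    frac = rng.uniform(*cfg.area_fraction)
    if frac * h * w < 16:
        raise ValueError("area fraction infeasible for this image size")
    # smooth echogenicity background in [0.35, 0.8]
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8)
    field = (field - field.min()) / (np.ptp(field) + 1e-9)
    background = 0.35 + 0.45 * field
    mask = _lesion_mask(h, w, frac, cfg.boundary_amplitude, rng)
    soft = ndimage.gaussian_filter(mask.astype(np.float64), sigma=cfg.edge_blur)
    tissue = background * (1.0 - (1.0 - cfg.contrast) * soft)
    speckle = rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape, size=(h, w))
    img = np.clip(tissue * speckle, 0.0, 1.0)
    img8 = (img * 255).astype(np.uint8)
    sid = f"phantom_{(cfg.seed if seed is None else seed):06d}"
    return SampleRecord(sid, np.repeat(img8[..., None], 3, axis=2), mask)


def shifted_config(cfg: PhantomConfig) -> PhantomConfig:
    """Distribution-shifted variant (milder contrast, heavier speckle)."""
    return replace(cfg, contrast=min(cfg.contrast + 0.25, 0.95),
                   speckle_shape=max(cfg.speckle_shape / 2, 1.0))


def generate_corpus(n: int, cfg: PhantomConfig, out_root, subset: str = "train",
                    shifted: bool = False, force: bool = False) -> list:
    """Write ``n`` phantoms under ``out_root/subset/{images,masks}``.

    Phantom ``i`` uses seed ``cfg.seed + i`` (shifted corpora offset the
    seed by 10**6 so the two corpora are independent draws).  Refuses to
    write into a non-empty target unless ``force``.
    """
    if n < 1:
        raise ValueError("corpus size must be >= 1")
    if shifted:
        cfg = shifted_config(cfg)
    out_root = Path(out_root)
    img_dir = out_root / subset / "images"
    mask_dir = out_root / subset / "masks"
    if img_dir.exists() and any(img_dir.iterdir()) and not force:
        raise FileExistsError(f"{img_dir} is not empty (use force=True)")
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    ids = []
    base = cfg.seed + (10 ** 6 if shifted else 0)
    for i in range(n):
        rec = generate_phantom(cfg, seed=base + i)
        Image.fromarray(rec.image).save(img_dir / f"{rec.id}.png")
        Image.fromarray(rec.mask * 255).save(mask_dir / f"{rec.id}.png")
        ids.append(rec.id)
    return ids
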