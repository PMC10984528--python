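"""Compound training loss: binary cross-entropy + soft Dice.

``BCE(A, B) = -(A log B + (1-A) log(1-B))`` averaged over pixels (B clamped
to [eps, 1-eps], eps = 1e-7, to stay finite), and
``Dice(A, B) = 1 - (2 * sum(A*B) + s) / (sum A + sum B + s)`` with smooth
``s = 1`` so empty masks are handled without a 0/0.  The total loss is
their sum.  During training the prediction is the sigmoid probability map
(soft intersection); at evaluation time masks are binarized first.

All three functions accept either numpy arrays (returning floats) or
autograd tensors (returning scalar tensors); BCE is computed per pixel and
averaged, Dice per image and then averaged over the batch.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor

EPS = 1e-7


def _check_dims(gt, pred):
    gs = gt.shape if not isinstance(gt, Tensor) else gt.data.shape
    ps = pred.shape if not isinstance(pred, Tensor) else pred.data.shape
    if tuple(gs) != tuple(ps):
        raise ValueError(f"shape mismatch: gt {gs} vs pred {ps}")


def bce_loss(gt, pred):
    """Mean binary cross-entropy between mask ``gt`` and probabilities ``pred``."""
    _check_dims(gt, pred)
    if isinstance(pred, Tensor) or isinstance(gt, Tensor):
        gt = gt if isinstance(gt, Tensor) else Tensor(gt)
        pred = pred if isinstance(pred, Tensor) else Tensor(pred)
        p = pred.clip(EPS, 1.0 - EPS)
        return -(gt * p.log() + (1.0 - gt) * (1.0 - p).log()).mean()
    p = np.clip(np.asarray(pred, dtype=np.float64), EPS, 1.0 - EPS)
    a = np.asarray(gt, dtype=np.float64)
    return float(-(a * np.log(p) + (1.0 - a) * np.log(1.0 - p)).mean())


def dice_loss(gt, pred, smooth: float = 1.0):
    """Soft Dice loss, computed per image and averaged over the batch.

    Inputs may be (H,W), (B,H,W) or (B,1,H,W); the leading axis (if any) is
    the batch.
    """
    _check_dims(gt, pred)
    if isinstance(pred, Tensor) or isinstance(gt, Tensor):
        gt = gt if isinstance(gt, Tensor) else Tensor(gt)
        pred = pred if isinstance(pred, Tensor) else Tensor(pred)
        ndim = pred.ndim
        axes = None if ndim <= 2 else tuple(range(1, ndim))
        inter = (gt * pred).sum(axis=axes)
        sizes = gt.sum(axis=axes) + pred.sum(axis=axes)
        dice = (2.0 * inter + smooth) / (sizes + smooth)
        return (1.0 - dice).mean()
    a = np.asarray(gt, dtype=np.float64)
    b = np.asarray(pred, dtype=np.float64)
    axes = None if a.ndim <= 2 else tuple(range(1, a.ndim))
    inter = (a * b).sum(axis=axes)
    sizes = a.sum(axis=axes) + b.sum(axis=axes)
    return float((1.0 - (2.0 * inter + smooth) / (sizes + smooth)).mean())


def total_loss(gt, pred, smooth: float = 1.0):
    """BCE + Dice."""
    return bce_loss(gt, pred) + dice_loss(gt, pred, smooth)


def total_loss_from_logits(gt, logits: Tensor, smooth: float = 1.0) -> Tensor:
    """BCE + Dice evaluated from raw logits (training path).

    The BCE term uses the logits formulation (equal to BCE(sigmoid) up to
    the probability clamp, but with non-saturating gradients); the Dice
    term uses sigmoid probabilities as the soft intersection.
    """
    from .nn import functional as F
    gt_arr = gt.data if isinstance(gt, Tensor) else np.asarray(gt, np.float32)
    bce = F.bce_with_logits(logits, gt_arr)
    return bce + dice_loss(Tensor(gt_arr), logits.sigmoid(), smooth)
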