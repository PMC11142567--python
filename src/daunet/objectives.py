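"""Differentiable segmentation losses: Dice, BCE, Focal, and their sum.

All losses accept either plain arrays (returning a float) or autodiff
tensors (returning a tensor on the tape, for training). Probabilities are
clipped to [1e-7, 1 - 1e-7] before any logarithm. Reductions are per-pixel
means over everything passed in, so batch and image axes are treated
uniformly.

The Dice loss uses soft confusion counts (tp = sum y*p and so on), smoothed
by ``smooth_eps`` in numerator and denominator so an empty ground truth
matched by an empty prediction scores 0 rather than 0/0.

The focal loss follows the standard two-sided form with
p_t = p where y = 1 and p_t = 1 - p where y = 0, so background pixels
contribute; ``literal_focal=True`` switches to the one-sided form
-mean(alpha * (1 - p)**gamma * log(p)) that ignores the ground truth,
kept only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, log

_CLIP_EPS = 1e-7

__all__ = [
    "LossConfig",
    "ConfusionCounts",
    "soft_counts",
    "dice_loss",
    "bce_loss",
    "focal_loss",
    "combined_loss",
]


@dataclass
class LossConfig:
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    smooth_eps: float = 1e-6
    component_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # dice, bce, focal
    literal_focal: bool = False

    def validate(self) -> None:
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.smooth_eps <= 0:
            raise ValueError("smooth_eps must be > 0")


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies; real-valued when derived from soft probabilities."""

    tp: float
    fp: float
    fn: float
    tn: float

    def validate(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def _pair(y, p) -> tuple[Tensor, Tensor, bool]:
    tensor_mode = isinstance(y, Tensor) or isinstance(p, Tensor)
    yt = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
    pt = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    if yt.shape != pt.shape:
        raise ValueError(f"mask shape {yt.shape} != prediction shape {pt.shape}")
    return yt, pt, tensor_mode


def _ret(value: Tensor, tensor_mode: bool):
    return value if tensor_mode else float(value.data)


def soft_counts(y, p) -> ConfusionCounts:
    """Differentiable confusion tallies; exact when ``p`` is binary."""
    yt, pt, _ = _pair(y, p)
    ya, pa = yt.data, pt.data
    tp = float((ya * pa).sum())
    fp = float(((1.0 - ya) * pa).sum())
    fn = float((ya * (1.0 - pa)).sum())
    tn = float(((1.0 - ya) * (1.0 - pa)).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice_loss(y, p, cfg: LossConfig | None = None):
    """1 - 2TP / (2TP + FP + FN) on soft counts, smoothed."""
    cfg = cfg or LossConfig()
    yt, pt, tensor_mode = _pair(y, p)
    tp = (yt * pt).sum()
    denom = yt.sum() + pt.sum()  # = 2TP + FP + FN
    dice = (2.0 * tp + cfg.smooth_eps) / (denom + cfg.smooth_eps)
    return _ret(1.0 - dice, tensor_mode)


def bce_loss(y, p):
    """Mean binary cross-entropy; probabilities clipped away from {0, 1}."""
    yt, pt, tensor_mode = _pair(y, p)
    pc = pt.clip(_CLIP_EPS, 1.0 - _CLIP_EPS)
    loss = -(yt * log(pc) + (1.0 - yt) * log(1.0 - pc)).mean()
    return _ret(loss, tensor_mode)


def focal_loss(y, p, cfg: LossConfig | None = None):
    """Mean -alpha (1 - p_t)^gamma log(p_t); reduces to alpha*BCE at gamma=0."""
    cfg = cfg or LossConfig()
    cfg.validate()
    yt, pt, tensor_mode = _pair(y, p)
    pc = pt.clip(_CLIP_EPS, 1.0 - _CLIP_EPS)
    if cfg.literal_focal:
        p_t = pc
    else:
        p_t = yt * pc + (1.0 - yt) * (1.0 - pc)
    loss = -(cfg.focal_alpha * (1.0 - p_t) ** cfg.focal_gamma * log(p_t)).mean()
    return _ret(loss, tensor_mode)


def combined_loss(y, p, cfg: LossConfig | None = None):
    """Weighted Dice + BCE + Focal; default weights (1, 1, 1)."""
    cfg = cfg or LossConfig()
    w_dice, w_bce, w_focal = cfg.component_weights
    yt, pt, tensor_mode = _pair(y, p)
    total = (
        w_dice * dice_loss(yt, pt, cfg)
        + w_bce * bce_loss(yt, pt)
        + w_focal * focal_loss(yt, pt, cfg)
    )
    return _ret(total, tensor_mode)
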