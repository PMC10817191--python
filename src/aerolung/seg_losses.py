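"""Segmentation training losses: soft Dice and focal loss.

Standalone, differentiable-in-principle loss functions used when training
voxel classifiers on heavily class-imbalanced airway labelmaps (airway
voxels are ~60x rarer than background).  No network code lives here; the
losses operate on (voxel, class) probability arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("aerolung")

__all__ = ["SoftLabelmapPair", "dice_loss", "focal_loss", "combined_loss"]

_EPS = 1e-7


@dataclass
class SoftLabelmapPair:
    """Predicted class probabilities against a one-hot ground truth.

    ``pred`` and ``truth`` have shape (N, C) for N voxels and C classes.
    Per-voxel probabilities must sum to one (skipped for C == 1, where the
    single channel is a foreground probability); truth is one-hot.
    """

    pred: np.ndarray
    truth: np.ndarray

    def __post_init__(self):
        self.pred = np.atleast_2d(np.asarray(self.pred, dtype=float))
        self.truth = np.atleast_2d(np.asarray(self.truth, dtype=float))
        if self.pred.shape != self.truth.shape:
            raise ValueError("pred and truth must have identical shapes")
        if np.any((self.pred < 0) | (self.pred > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_classes > 1:
            if np.any(np.abs(self.pred.sum(axis=1) - 1.0) > 1e-6):
                raise ValueError("per-voxel probabilities must sum to 1")
            if np.any(np.abs(self.truth.sum(axis=1) - 1.0) > 1e-6):
                raise ValueError("truth must be one-hot")
        if not np.all(np.isin(self.truth, (0.0, 1.0))):
            raise ValueError("truth entries must be 0 or 1")

    @property
    def n_voxels(self) -> int:
        return self.pred.shape[0]

    @property
    def n_classes(self) -> int:
        return self.pred.shape[1]


def dice_loss(pair: SoftLabelmapPair, per_voxel: bool = False,
              eps: float = _EPS) -> float:
    """Soft Dice loss in [0, 1]: 0 for perfect overlap, 1 for disjoint.

    Default form takes voxel sums inside the ratio per class,
    ``1 - sum(p g) / (sum(p g) + sum((1-p) g) + sum(p (1-g)))``,
    averaged over classes; a class empty in both prediction and truth
    contributes 0 via the eps smoothing.  ``per_voxel=True`` instead
    averages the per-voxel ratio (the condensed textbook form, 0/0-guarded
    by eps on true negatives).
    """
    p, g = pair.pred, pair.truth
    if per_voxel:
        inter = p * g
        denom = inter + (1 - p) * g + p * (1 - g)
        return float(np.mean(1.0 - (inter + eps) / (denom + eps)))
    empty = (g.sum(axis=0) == 0)
    if empty.any():
        logger.info("dice_loss: %d truth-empty class(es); eps smoothing "
                    "applies", int(empty.sum()))
    inter = (p * g).sum(axis=0)
    fn = ((1 - p) * g).sum(axis=0)
    fp = (p * (1 - g)).sum(axis=0)
    per_class = 1.0 - (inter + eps) / (inter + fn + fp + eps)
    return float(per_class.mean())


def focal_loss(pair: SoftLabelmapPair, gamma: float = 5.0, alpha: float = 1.0,
               clip: float = _EPS) -> float:
    """Focal loss ``-(1/CN) sum alpha g (1-p)^gamma log p``.

    ``gamma`` (default 5) down-weights voxels the model already predicts
    confidently, concentrating the loss on hard, rare-class voxels;
    ``alpha`` is a flat class weight.  Probabilities are clipped away from
    0/1 to keep the logarithm finite; the perturbation is below any test
    tolerance used here.
    """
    p = np.clip(pair.pred, clip, 1.0 - clip)
    g = pair.truth
    total = -(alpha * g * (1.0 - p) ** gamma * np.log(p)).sum()
    return float(total / (pair.n_classes * pair.n_voxels))


def combined_loss(pair: SoftLabelmapPair, gamma: float = 5.0,
                  alpha: float = 1.0) -> float:
    """Training loss: sum of soft Dice and focal terms."""
    return dice_loss(pair) + focal_loss(pair, gamma=gamma, alpha=alpha)
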