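"""Overlap losses for severely class-imbalanced segmentation.

The Tversky index generalises Dice by weighting false positives and false
negatives separately:

    TI = (sum p0*g0 + eps) / (sum p0*g0 + alpha*sum p0*g1 + beta*sum p1*g0 + eps)

with p0 the predicted foreground probability, g0 the binary foreground
target, p1 = 1 - p0 and g1 = 1 - g0.  The focal Tversky loss is
(1 - TI)^gamma; gamma > 1 focuses training on hard examples.  The default
weights are alpha = beta = 0.8, gamma = 1 (they deliberately do not follow
the alpha + beta = 1 convention).  A small epsilon keeps the empty-mask
case defined (both empty -> index 1, loss 0).

All functions accept either plain numpy arrays or autodiff tensors from
:mod:`aortacine.nn.engine`; in the latter case gradients flow through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.engine import Tensor


@dataclass
class LossConfig:
    alpha: float = 0.8   # false-positive weight
    beta: float = 0.8    # false-negative weight
    gamma: float = 1.0   # focusing exponent
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _check_pair(pred, target):
    p_shape = pred.shape if hasattr(pred, "shape") else np.shape(pred)
    t_shape = target.shape if hasattr(target, "shape") else np.shape(target)
    if int(np.prod(p_shape)) != int(np.prod(t_shape)):
        raise ValueError(f"prediction and target sizes differ: {p_shape} vs {t_shape}")


def tversky_index(pred_fg, target_fg, config: LossConfig | None = None):
    """Tversky overlap index in [0, 1] between probabilities and a binary target."""
    config = config or LossConfig()
    _check_pair(pred_fg, target_fg)
    p0, g0 = pred_fg, target_fg
    tp = (p0 * g0).sum()
    fp = (p0 * (1.0 - g0)).sum()   # predicted foreground on true background
    fn = ((1.0 - p0) * g0).sum()   # missed true foreground
    eps = config.epsilon
    return (tp + eps) / (tp + config.alpha * fp + config.beta * fn + eps)


def focal_tversky_loss(pred_fg, target_fg, config: LossConfig | None = None):
    """(1 - Tversky index)^gamma; zero for a perfect prediction."""
    config = config or LossConfig()
    return (1.0 - tversky_index(pred_fg, target_fg, config)) ** config.gamma


def dice_loss(pred_fg, target_fg, epsilon: float = 1e-6):
    """1 - soft Dice; the loss used by the no-focal-Tversky ablation."""
    _check_pair(pred_fg, target_fg)
    tp = (pred_fg * target_fg).sum()
    denom = pred_fg.sum() + target_fg.sum()
    return 1.0 - (2.0 * tp + epsilon) / (denom + epsilon)


def make_loss(kind: str = "focal_tversky", config: LossConfig | None = None):
    """Return a ``loss(pred, target)`` callable for the training loop."""
    config = config or LossConfig()
    if kind == "focal_tversky":
        return lambda p, g: focal_tversky_loss(p, g, config)
    if kind == "dice":
        return lambda p, g: dice_loss(p, g, config.epsilon)
    raise ValueError(f"unknown loss kind {kind!r}")


__all__ = ["LossConfig", "tversky_index", "focal_tversky_loss", "dice_loss",
           "make_loss", "Tensor"]
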