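"""Composite training objective and cosine-annealing schedule.

The total loss sums per-module binary segmentation losses (Dice +
cross-entropy under deep supervision), lambda-weighted global constraint
terms, and an anatomical size prior that penalizes predicted lesion areas
whose equivalent diameter leaves the clinically plausible 10-40 mm
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = [
    "LossConfig",
    "ScheduleConfig",
    "dice_loss",
    "cross_entropy_loss",
    "size_prior_loss",
    "total_loss",
    "cosine_lr",
]


@dataclass(frozen=True)
class LossConfig:
    epsilon: float = 1e-6
    lambda_global: float = 1.0
    size_prior_mm: tuple = (10.0, 40.0)
    pixel_spacing: float = 0.5
    module_terms: int = 2  # deep-supervision taps (decoder head + aux head)
    global_terms: int = 1

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_global < 0:
            raise ValueError("lambda_global must be >= 0")
        lo, hi = self.size_prior_mm
        if not (0 < lo <= hi):
            raise ValueError("size prior interval must be positive and ordered")


@dataclass(frozen=True)
class ScheduleConfig:
    eta_min: float = 1e-5
    eta_max: float = 1e-3
    t_i: int = 100
    cycles: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.eta_min <= self.eta_max:
            raise ValueError("need 0 <= eta_min <= eta_max")
        if self.t_i < 1:
            raise ValueError("T_i must be >= 1")


def _lift(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def dice_loss(pred, target, epsilon: float = 1e-6):
    """Soft Dice loss 1 - (2|X.Y| + eps) / (|X| + |Y| + eps).

    ``pred`` may be a plain array or an autograd Tensor (for training);
    the return type follows the input.  |X.Y| is the sum of pred*target,
    |X| and |Y| the sums of prediction and target.
    """
    pred_t = _lift(pred)
    target_a = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=float)
    if pred_t.data.shape != target_a.shape:
        raise ValueError("pred and target shapes differ")
    inter = (pred_t * target_a).sum()
    denom = pred_t.sum() + float(target_a.sum())
    loss = 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)
    return loss if isinstance(pred, Tensor) else float(loss.data)


def cross_entropy_loss(pred, target, clip_eps: float = 1e-7):
    """Binary cross-entropy, averaged over pixels, with both class terms.

    Predictions are clipped to [clip_eps, 1-clip_eps] before the logs, so
    confident mistakes are penalized heavily but never produce infinities.
    """
    pred_t = _lift(pred)
    target_a = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=float)
    if pred_t.data.shape != target_a.shape:
        raise ValueError("pred and target shapes differ")
    p = pred_t.clip(clip_eps, 1.0 - clip_eps)
    loss = -(target_a * p.log() + (1.0 - target_a) * (1.0 - p).log()).mean()
    return loss if isinstance(pred, Tensor) else float(loss.data)


def predicted_equivalent_diameter_mm(pred, pixel_spacing: float):
    """Soft equivalent diameter 2*sqrt(area/pi), area = sum(pred)*spacing^2."""
    pred_t = _lift(pred)
    area = pred_t.sum() * (pixel_spacing**2)
    d = (area * (1.0 / math.pi)) ** 0.5 * 2.0
    return d if isinstance(pred, Tensor) else float(d.data)


def size_prior_loss(pred, config: LossConfig):
    """Squared-hinge penalty on the predicted lesion equivalent diameter.

    Zero inside [lo, hi] mm (bounds inclusive); outside, the squared
    distance to the nearest bound normalized by the interval width squared.
    """
    if config.pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    lo, hi = config.size_prior_mm
    width = hi - lo if hi > lo else 1.0
    d = predicted_equivalent_diameter_mm(_lift(pred), config.pixel_spacing)
    dval = float(d.data)
    if lo <= dval <= hi:
        out = Tensor(np.array(0.0))
    elif dval < lo:
        out = ((lo - d) * (1.0 / width)) ** 2.0
    else:
        out = ((d - hi) * (1.0 / width)) ** 2.0
    return out if isinstance(pred, Tensor) else float(out.data)


def total_loss(module_losses, global_losses, size_loss, config: LossConfig):
    """L_total = sum(module) + lambda * sum(global) + size."""
    everything = list(module_losses) + list(global_losses) + [size_loss]
    symbolic = any(isinstance(t, Tensor) for t in everything)
    total = Tensor(np.array(0.0)) if symbolic else 0.0
    for t in module_losses:
        total = total + t
    for g in global_losses:
        total = total + config.lambda_global * g
    total = total + size_loss
    return total if symbolic else float(total)


def cosine_lr(t_cur: float, config: ScheduleConfig) -> float:
    """Cosine-annealed learning rate within one cycle.

    eta_t = eta_min + (eta_max - eta_min)/2 * (1 + cos(pi * T_cur / T_i)),
    monotone non-increasing from eta_max at T_cur=0 to eta_min at T_cur=T_i.
    """
    if not 0 <= t_cur <= config.t_i:
        raise ValueError("T_cur must lie in [0, T_i]")
    return config.eta_min + 0.5 * (config.eta_max - config.eta_min) * (
        1.0 + math.cos(math.pi * t_cur / config.t_i)
    )
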