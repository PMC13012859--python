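"""Training loop for the CRFE network.

Adam at an initial learning rate of 0.001, cosine annealing over a single
cycle spanning all scheduled iterations, batch size 4, up to 100 epochs,
and early stopping when no epoch in a trailing 10-epoch window improves
the validation Dice coefficient by at least 0.001 over the best value seen
before that window.  The checkpoint with the best validation Dice is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Adam, Tensor
from .network import CRFENet, SegmentationModelSpec
from .objective import (
    LossConfig,
    ScheduleConfig,
    cosine_lr,
    cross_entropy_loss,
    dice_loss,
    size_prior_loss,
    total_loss,
)

__all__ = ["TrainConfig", "TrainLog", "train", "early_stop_check", "validation_dice"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 100
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.early_stop_min_delta < 0:
            raise ValueError("min_delta must be >= 0")


@dataclass
class TrainLog:
    train_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0
    best_val_dice: float = 0.0


def early_stop_check(history, patience: int, min_delta: float) -> bool:
    """True iff every entry in the trailing ``patience`` window improves the
    best value seen *before* the window by less than ``min_delta``.

    Pure function of the validation-Dice history; needs at least
    patience + 1 entries to fire.
    """
    history = list(history)
    if not history:
        raise ValueError("history must be non-empty")
    if len(history) <= patience:
        return False
    window = history[-patience:]
    best_before = max(history[:-patience])
    return all(v < best_before + min_delta for v in window)


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Majority-free coarse mask for deep supervision: a coarse cell is
    lesion if any constituent pixel is lesion."""
    h, w = mask.shape[-2:]
    r = mask.reshape(*mask.shape[:-2], h // factor, factor, w // factor, factor)
    return r.max(axis=(-3, -1))


def validation_dice(net: CRFENet, images: np.ndarray, masks: np.ndarray,
                    threshold: float = 0.5, batch_size: int = 8) -> float:
    """Mean hard Dice (prediction binarized at ``threshold``) over a split."""
    dices = []
    for i in range(0, len(images), batch_size):
        prob = net.forward(images[i:i + batch_size]).data[:, 0]
        for p, m in zip(prob, masks[i:i + batch_size]):
            pb = (p >= threshold).astype(float)
            inter = (pb * m).sum()
            denom = pb.sum() + m.sum()
            dices.append(1.0 if denom == 0 else 2.0 * inter / denom)
    return float(np.mean(dices))


def train(
    model_spec: SegmentationModelSpec,
    train_images: np.ndarray,
    train_masks: np.ndarray,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    train_config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
    schedule_config: ScheduleConfig | None = None,
):
    """Train a CRFE network; returns (net with best-Dice parameters, TrainLog)."""
    train_config = train_config or TrainConfig()
    loss_config = loss_config or LossConfig()
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation splits must be non-empty")

    net = CRFENet(model_spec)
    rng = np.random.default_rng(train_config.seed)
    n = len(train_images)
    batches_per_epoch = int(np.ceil(n / train_config.batch_size))
    if schedule_config is None:
        schedule_config = ScheduleConfig(
            eta_max=train_config.learning_rate,
            t_i=train_config.max_epochs * batches_per_epoch,
        )
    opt = Adam(net.params.values(), lr=schedule_config.eta_max)
    log = TrainLog()
    best_state = net.state_dict()
    factor = 2**model_spec.n_pool_stages
    iteration = 0

    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for bi in range(batches_per_epoch):
            idx = order[bi * train_config.batch_size:(bi + 1) * train_config.batch_size]
            imgs = train_images[idx]
            masks = train_masks[idx].astype(float)
            opt.lr = cosine_lr(min(iteration, schedule_config.t_i), schedule_config)

            prob, aux = net.forward(imgs, with_aux=True)
            target = Tensor(masks[:, None])
            coarse = Tensor(_downsample_mask(masks, factor)[:, None])
            module_losses = [
                dice_loss(prob, target, loss_config.epsilon)
                + cross_entropy_loss(prob, target),
                dice_loss(aux, coarse, loss_config.epsilon)
                + cross_entropy_loss(aux, coarse),
            ][: loss_config.module_terms]
            global_losses = (
                [dice_loss(prob.reshape(-1), target.reshape(-1), loss_config.epsilon)]
                if loss_config.global_terms
                else []
            )
            size_losses = [
                size_prior_loss(prob[i:i + 1], loss_config)
                for i in range(prob.data.shape[0])
            ]
            size_term = size_losses[0]
            for s in size_losses[1:]:
                size_term = size_term + s
            size_term = size_term * (1.0 / len(size_losses))
            loss = total_loss(module_losses, global_losses, size_term, loss_config)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")

            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            iteration += 1

        vdice = validation_dice(net, val_images, val_masks)
        log.train_loss.append(float(np.mean(epoch_losses)))
        log.val_dice.append(vdice)
        log.learning_rate.append(opt.lr)
        log.stop_epoch = epoch
        if vdice > log.best_val_dice:
            log.best_val_dice = vdice
            log.best_epoch = epoch
            best_state = net.state_dict()
        if early_stop_check(
            log.val_dice, train_config.early_stop_patience, train_config.early_stop_min_delta
        ):
            break

    net.load_state_dict(best_state)
    return net, log
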