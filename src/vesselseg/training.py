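"""Per-channel training: 4× augmentation, staged-SGD loop, checkpoint selection.

Each enhancement channel trains its own network on that channel's enhanced
images.  The learning rate follows a three-stage schedule — 0.01 for the
first ten epochs, 0.001 through epoch twenty, 0.0001 through epoch thirty —
and the training set is expanded fourfold by horizontal flip, vertical flip
and 180° rotation applied jointly to image and label.
"""

from __future__ import annotations

import copy
import dataclasses
import logging

import numpy as np

from .losses import DEFAULT_LAMBDA, combined_loss, dice_coefficient, dice_loss, weighted_ce
from ._engine import SGD
from .unet import UNet, UNetSpec, build_unet

logger = logging.getLogger(__name__)

#: (last epoch of stage, learning rate) — 1-based epochs.
DEFAULT_LR_STAGES = ((10, 0.01), (20, 0.001), (30, 0.0001))

__all__ = ["TrainConfig", "DEFAULT_LR_STAGES", "augment_4x", "lr_schedule",
           "train_channel", "predict_channel"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 2
    momentum: float = 0.9
    weight_decay: float = 0.0
    lam: float = DEFAULT_LAMBDA
    lr_stages: tuple[tuple[int, float], ...] = DEFAULT_LR_STAGES
    augment: bool = True
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(lr <= 0 for _, lr in self.lr_stages):
            raise ValueError("all learning rates must be positive")
        if self.epochs > self.lr_stages[-1][0]:
            raise ValueError("lr schedule does not cover all epochs")


def augment_4x(pairs: list[tuple[np.ndarray, np.ndarray]]) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Original + horizontal flip + vertical flip + 180° rotation, jointly.

    Returns exactly 4N (image, label, provenance) triples; the label always
    undergoes the same transform as its image.
    """
    out = []
    for img, lab in pairs:
        img = np.asarray(img)
        lab = np.asarray(lab)
        if img.shape[-2:] != lab.shape[-2:]:
            raise ValueError(f"image/label dim mismatch: {img.shape} vs {lab.shape}")
        out.append((img, lab, "original"))
        out.append((img[..., ::-1].copy(), lab[..., ::-1].copy(), "hflip"))
        out.append((img[..., ::-1, :].copy(), lab[..., ::-1, :].copy(), "vflip"))
        out.append((img[..., ::-1, ::-1].copy(), lab[..., ::-1, ::-1].copy(), "rot180"))
    return out


def lr_schedule(epoch: int, stages: tuple[tuple[int, float], ...] = DEFAULT_LR_STAGES) -> float:
    """Learning rate for a 1-based epoch under the staged schedule."""
    if epoch < 1 or epoch > stages[-1][0]:
        raise ValueError(f"epoch {epoch} outside schedule range 1..{stages[-1][0]}")
    for last_epoch, lr in stages:
        if epoch <= last_epoch:
            return lr
    raise AssertionError("unreachable")


def _to_batch(images: list[np.ndarray], dtype) -> np.ndarray:
    return np.stack([np.asarray(im, dtype=dtype)[None, :, :] for im in images])


def train_channel(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    spec: UNetSpec,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[UNet, list[dict]]:
    """Train one channel's network on (enhanced 0–255 image, bool label) pairs.

    Images are scaled to [0, 1] before the first convolution.  When a
    validation fraction is configured, that share of the (unaugmented)
    pairs is held out and the returned model carries the weights of the
    epoch with the best held-out Dice; otherwise the final weights are
    returned.  The training log has one row per epoch with the mean Dice,
    cross-entropy and total loss and the learning rate used.
    """
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    model = build_unet(spec)
    dtype = model.dtype

    n_val = int(round(cfg.val_fraction * len(pairs)))
    n_val = min(n_val, len(pairs) - 1)
    order = rng.permutation(len(pairs))
    val_pairs = [pairs[i] for i in order[:n_val]]
    fit_pairs = [pairs[i] for i in order[n_val:]]
    if cfg.augment:
        fit = [(im, lab) for im, lab, _ in augment_4x(fit_pairs)]
    else:
        fit = list(fit_pairs)

    opt = SGD(model.params(), lr=lr_schedule(1, cfg.lr_stages),
              momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    log: list[dict] = []
    best = (-1.0, None)
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_schedule(epoch, cfg.lr_stages)
        idx = rng.permutation(len(fit))
        sums = {"dice": 0.0, "ce": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(idx), cfg.batch_size):
            chunk = idx[start:start + cfg.batch_size]
            x = _to_batch([fit[i][0] for i in chunk], dtype) / 255.0
            y = _to_batch([fit[i][1] for i in chunk], dtype)
            p = model.forward(x, train=True)
            dv, _ = dice_loss(p, y)
            cv, _ = weighted_ce(p, y)
            total, grad = combined_loss(p, y, cfg.lam)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (dice={dv}, ce={cv}); aborting")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            sums["dice"] += dv
            sums["ce"] += cv
            sums["total"] += total
            n_batches += 1
        row = {"epoch": epoch, "lr": opt.lr,
               "dice": sums["dice"] / n_batches,
               "ce": sums["ce"] / n_batches,
               "total": sums["total"] / n_batches}
        if val_pairs:
            val_dice = float(np.mean([
                dice_coefficient(predict_channel(model, im) > 0.5, lab)
                for im, lab in val_pairs
            ]))
            row["val_dice"] = val_dice
            if val_dice > best[0]:
                best = (val_dice, [a.copy() for a in model.state_arrays()])
        log.append(row)
        logger.info("epoch %d lr=%g dice=%.4f ce=%.4f total=%.4f %s",
                    epoch, row["lr"], row["dice"], row["ce"], row["total"],
                    f"val_dice={row.get('val_dice', float('nan')):.4f}" if val_pairs else "")
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, log


def predict_channel(model: UNet, image: np.ndarray) -> np.ndarray:
    """Probability map in (0, 1) for one enhanced 0–255 image (network frame)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("predict_channel expects a single 2-D image")
    p = model.predict(image[None, None, :, :] / 255.0)
    return p[0, 0].astype(np.float64)
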