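"""Combined cross-entropy + soft-Dice segmentation objective.

The training loss is the arithmetic mean of pixel-averaged cross-entropy
and the soft Dice complement

    L = ( -mean_pix log p_true  +  1 - (2 sum y*p + eps)/(sum y + sum p + eps) ) / 2

with the Dice term accumulated over all pixels of the batch per class
(batch-Dice) and averaged over classes.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, softmax
from .config import LossConfig

#: floor applied inside log() so an exactly-zero probability at a true
#: label yields a large finite penalty instead of infinity
PROB_FLOOR = 1e-12


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(
            f"labels outside [0, {num_classes}): range "
            f"[{labels.min()}, {labels.max()}]")
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[labels], -1, 1)  # (N, C, ...) from (N, ...)


def _check_probs(probs: np.ndarray) -> None:
    total = probs.sum(axis=1)
    if np.abs(total - 1.0).max() > 1e-5:
        raise ValueError("probabilities do not sum to 1 over classes")


def ce_loss_term(probs, labels) -> Tensor:
    """Mean over pixels of -log(probability of the true class)."""
    probs = as_tensor(probs)
    if probs.ndim == 3:
        probs = probs.reshape(1, *probs.shape)
        labels = np.asarray(labels)[None]
    _check_probs(probs.data)
    onehot = _one_hot(labels, probs.shape[1])
    logp = probs.clamp_min(PROB_FLOOR).log()
    picked = (logp * onehot).sum(axis=1)  # (N, H, W)
    return -(picked.mean())


def dice_loss_term(probs, labels, cfg: LossConfig | None = None) -> Tensor:
    """Soft Dice complement, batch-accumulated per class, class-averaged."""
    cfg = cfg or LossConfig()
    probs = as_tensor(probs)
    if probs.ndim == 3:
        probs = probs.reshape(1, *probs.shape)
        labels = np.asarray(labels)[None]
    _check_probs(probs.data)
    num_classes = probs.shape[1]
    onehot = Tensor(_one_hot(labels, num_classes))
    axes = (0, 2, 3)
    inter = (probs * onehot).sum(axis=axes)       # (C,)
    denom = probs.sum(axis=axes) + onehot.sum(axis=axes)
    eps = cfg.epsilon
    dice = ((inter * 2.0) + eps) / (denom + eps)  # (C,) soft Dice per class
    complement = 1.0 - dice
    if not cfg.include_background_in_dice:
        sel = np.zeros(num_classes, np.float32)
        sel[1:] = 1.0 / (num_classes - 1)
        return (complement * Tensor(sel)).sum()
    if cfg.class_weights is not None:
        w = np.asarray(cfg.class_weights, np.float32)
        w = w / w.sum()
        return (complement * Tensor(w)).sum()
    return complement.mean()


def combined_seg_loss(logits, labels, cfg: LossConfig | None = None) -> Tensor:
    """(CE + Dice) / 2 on softmax probabilities of ``logits``."""
    cfg = cfg or LossConfig()
    logits = as_tensor(logits)
    if logits.ndim == 3:
        logits = logits.reshape(1, *logits.shape)
        labels = np.asarray(labels)[None]
    probs = softmax(logits, axis=1)
    ce = ce_loss_term(probs, labels)
    dice = dice_loss_term(probs, labels, cfg)
    return (ce + dice) * 0.5
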