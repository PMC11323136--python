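"""Training loop: SGD with momentum on shuffled slice batches.

The published recipe is SGD(lr 0.01, momentum 0.9, weight decay 1e-4),
batch size 24, constant learning rate, 150 epochs over the axial training
slices.  Checkpoints are flat ``name -> array`` maps saved with
``numpy.savez``; parameter names follow the module tree (for example
``encoder.stages.2.5.mixer.dw.weight``) and are stable across runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import TrainConfig
from .data import (SlicePair, augment_pair, clip_normalize_hu,
                   extract_axial_slices, read_labels, read_manifest,
                   read_volume, resize_image)
from .losses import combined_seg_loss
from .model import SEFUNet


@dataclass
class EpochRecord:
    epoch: int
    mean_loss: float
    lr: float
    seconds: float


@dataclass
class TrainResult:
    model: SEFUNet
    history: list[EpochRecord] = field(default_factory=list)
    iteration_losses: list[float] = field(default_factory=list)
    checkpoint_path: Path | None = None
    best_checkpoint_path: Path | None = None


def load_training_slices(manifest_path: str | Path, input_size: int,
                         num_classes: int = 9) -> list[SlicePair]:
    """Preprocessed, resized training slices for every train-split case."""
    entries = [e for e in read_manifest(manifest_path) if e.split == "train"]
    if not entries:
        raise ValueError(f"manifest {manifest_path} has an empty training split")
    slices = []
    for e in entries:
        vol = clip_normalize_hu(read_volume(e.image_path))
        lab = read_labels(e.label_path, num_classes=num_classes)
        for pair in extract_axial_slices(vol, lab):
            img = np.clip(resize_image(pair.image, input_size), 0.0, 1.0)
            msk = resize_image(pair.label, input_size, mode="label")
            slices.append(SlicePair(img, msk, pair.case_id, pair.slice_index))
    return slices


def save_checkpoint(model: SEFUNet, path: str | Path) -> None:
    np.savez(str(path), **model.state_dict())


def load_checkpoint(model: SEFUNet, path: str | Path) -> SEFUNet:
    with np.load(str(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def train(cfg: TrainConfig, out_dir: str | Path | None = None,
          slices: list[SlicePair] | None = None,
          log_fn=print) -> TrainResult:
    """Run the optimization loop; returns the model and per-epoch log.

    ``cfg.max_iterations``, when set, caps the total number of SGD steps
    (useful for smoke runs and overfitting studies); epochs still delimit
    the logging records.
    """
    if slices is None:
        if not cfg.manifest:
            raise ValueError("either a manifest or explicit slices are required")
        slices = load_training_slices(cfg.manifest, cfg.model.input_size,
                                      cfg.model.num_classes)
    if not slices:
        raise ValueError("no training slices")

    rng = np.random.default_rng(cfg.seed)
    model = SEFUNet(cfg.model)
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate,
                 momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    result = TrainResult(model=model)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    images = np.stack([s.image for s in slices]).astype(np.float32)
    labels = np.stack([s.label for s in slices]).astype(np.int64)
    n = len(slices)
    steps_per_epoch = -(-n // cfg.batch_size)
    total_steps = cfg.max_iterations or cfg.epochs * steps_per_epoch
    best_loss = np.inf
    iters_done = 0
    model.train()
    for epoch in range(1, cfg.epochs + 1):
        t0 = time.time()
        order = rng.permutation(n)
        losses = []
        for step in range(steps_per_epoch):
            if cfg.lr_schedule == "poly":
                opt.lr = cfg.learning_rate * \
                    (1.0 - iters_done / total_steps) ** cfg.poly_power
            idx = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            xb = images[idx][:, None]
            yb = labels[idx]
            if cfg.augment:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    pair = augment_pair(SlicePair(xb[j, 0], yb[j]), rng)
                    xb[j, 0], yb[j] = pair.image, pair.label
            logits = model(xb)
            loss = combined_seg_loss(logits, yb, cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            result.iteration_losses.append(loss.item())
            iters_done += 1
            if cfg.max_iterations and iters_done >= cfg.max_iterations:
                break
        rec = EpochRecord(epoch, float(np.mean(losses)), opt.lr,
                          time.time() - t0)
        result.history.append(rec)
        if log_fn:
            log_fn(f"epoch {rec.epoch:4d}  loss {rec.mean_loss:.4f}  "
                   f"lr {rec.lr:g}  {rec.seconds:.1f}s")
        if out_dir is not None:
            if rec.mean_loss < best_loss:
                best_loss = rec.mean_loss
                result.best_checkpoint_path = out_dir / "best.npz"
                save_checkpoint(model, result.best_checkpoint_path)
            result.checkpoint_path = out_dir / "last.npz"
            save_checkpoint(model, result.checkpoint_path)
            log_path = out_dir / "train_log.txt"
            with open(log_path, "a") as fh:
                fh.write(f"{rec.epoch}\t{rec.mean_loss:.6f}\t{rec.lr:g}\t"
                         f"{rec.seconds:.2f}\n")
        if cfg.max_iterations and iters_done >= cfg.max_iterations:
            break
    return result
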