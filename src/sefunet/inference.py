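"""Slice-by-slice 2-D inference over 3-D cases.

A raw HU volume is windowed/normalized, each axial slice is resized to the
model resolution and classified independently, the argmax label map is
resized back to the native slice size with nearest-neighbour interpolation
(no class mixing), and the slices are stacked in order into a 3-D label
volume with the geometry of the input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import (CTVolume, LabelVolume, clip_normalize_hu, resize_image,
                   write_labels)
from .model import SEFUNet


def predict_slice(model: SEFUNet, image: np.ndarray) -> np.ndarray:
    """Argmax class map at model resolution for one normalized slice."""
    image = np.asarray(image, np.float32)
    if image.ndim != 2:
        raise ValueError("predict_slice expects a single H x W image")
    if image.min() < -1e-6 or image.max() > 1 + 1e-6:
        raise ValueError("slice is not normalized to [0, 1]")
    size = model.cfg.input_size
    if image.shape != (size, size):
        image = resize_image(image, size, mode="continuous")
        image = np.clip(image, 0.0, 1.0)
    logits = model.predict_logits(image[None, None])
    return np.argmax(logits[0], axis=0).astype(np.int16)


def predict_volume(model: SEFUNet, volume: CTVolume,
                   batch_size: int = 8) -> LabelVolume:
    """Clip/normalize, predict every axial slice, restore native size,
    and stack in the original order."""
    norm = clip_normalize_hu(volume)
    size = model.cfg.input_size
    d, h, w = norm.voxels.shape
    batch = np.empty((d, 1, size, size), np.float32)
    for k in range(d):
        img = norm.voxels[k]
        if img.shape != (size, size):
            img = np.clip(resize_image(img, size, mode="continuous"), 0.0, 1.0)
        batch[k, 0] = img
    out = np.empty((d, h, w), np.int16)
    for start in range(0, d, batch_size):
        logits = model.predict_logits(batch[start:start + batch_size])
        labels = np.argmax(logits, axis=1).astype(np.int16)
        for j, lab in enumerate(labels):
            if lab.shape != (h, w):
                lab = resize_image(lab, h, mode="label") if h == w else \
                    np.rint(_resize_rect(lab, (h, w))).astype(np.int16)
            out[start + j] = lab
    return LabelVolume(out, volume.spacing, num_classes=model.cfg.num_classes)


def _resize_rect(label_map: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize as _sk_resize
    return _sk_resize(label_map, target, order=0, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def write_prediction(pred: LabelVolume, path: str | Path) -> None:
    """NIfTI label volume mirroring the input spacing."""
    write_labels(pred, path)
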