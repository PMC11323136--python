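"""Configuration dataclasses for the model, loss and training loop.

The architectural defaults follow the published SEF-UNet configuration:
encoder stage depths [3, 3, 9, 3] with channel dims [64, 128, 320, 512],
decoder output channels [256, 128, 64, 16], 9 classes (8 abdominal organs
+ background) at 224x224 input.  The three ratios the architecture leaves
open (SE bottleneck reduction, token-mixer expansion, MLP ratio) default
to the calibrated triple (4, 1.75, 3.125) with a 5x5 encoder depthwise
kernel, which reproduces the published 24.65 M parameter budget; see
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

#: Foreground organ labels 1..8 in the fixed reporting order.
ORGAN_NAMES = (
    "spleen", "right_kidney", "left_kidney", "gallbladder",
    "liver", "stomach", "aorta", "pancreas",
)
ORGAN_ABBREV = ("Sp", "RK", "LK", "Ga", "Li", "St", "Ao", "Pa")

DECODER_VARIANTS = ("dcup", "cup", "none")


@dataclass
class ModelConfig:
    depths: tuple[int, int, int, int] = (3, 3, 9, 3)
    dims: tuple[int, int, int, int] = (64, 128, 320, 512)
    decoder_channels: tuple[int, int, int, int] = (256, 128, 64, 16)
    num_classes: int = 9
    in_channels: int = 1
    input_size: int = 224
    se_reduction: int = 4
    mixer_expansion: float = 1.75
    mlp_ratio: float = 3.125
    dw_kernel_encoder: int = 5
    dw_kernel_decoder: int = 3
    decoder_variant: str = "dcup"
    n_stages: int = 4
    activation: str = "relu"
    seed: int = 1234

    def __post_init__(self):
        self.depths = tuple(int(d) for d in self.depths)
        self.dims = tuple(int(d) for d in self.dims)
        self.decoder_channels = tuple(int(d) for d in self.decoder_channels)
        for name in ("depths", "dims", "decoder_channels"):
            vals = getattr(self, name)
            if len(vals) != 4 or any(v < 1 for v in vals):
                raise ValueError(f"{name} must be 4 positive integers, got {vals}")
        if self.num_classes < 1 or self.in_channels < 1:
            raise ValueError("num_classes and in_channels must be positive")
        if self.input_size < 32 or self.input_size % 32:
            raise ValueError(
                f"input_size must be a positive multiple of 32, got {self.input_size}")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be positive")
        if self.mixer_expansion <= 0 or self.mlp_ratio <= 0:
            raise ValueError("mixer_expansion and mlp_ratio must be positive")
        for k in (self.dw_kernel_encoder, self.dw_kernel_decoder):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"depthwise kernels must be odd, got {k}")
        if self.decoder_variant not in DECODER_VARIANTS:
            raise ValueError(
                f"decoder_variant must be one of {DECODER_VARIANTS}")
        if self.n_stages not in (2, 3, 4):
            raise ValueError("n_stages must be 2, 3 or 4")
        for c in self.dims[: self.n_stages]:
            if math.floor(c * self.mixer_expansion) < self.se_reduction:
                raise ValueError(
                    "SE bottleneck would collapse: floor(dim * mixer_expansion) "
                    f"= {math.floor(c * self.mixer_expansion)} < se_reduction")
        if self.activation not in ("relu", "gelu"):
            raise ValueError("activation must be 'relu' or 'gelu'")

    # stage i (0-based) spatial reduction vs the input
    def stage_stride(self, i: int) -> int:
        return 4 * 2 ** i

    def expanded_dim(self, i: int) -> int:
        return math.floor(self.dims[i] * self.mixer_expansion)

    def mlp_hidden(self, i: int) -> int:
        return math.floor(self.dims[i] * self.mlp_ratio)

    def se_hidden(self, i: int) -> int:
        return math.floor(self.expanded_dim(i) / self.se_reduction)

    def decoder_plan(self) -> list[int]:
        """Output channels of the decoder blocks actually used."""
        return list(self.decoder_channels[4 - self.n_stages:])


@dataclass
class LossConfig:
    epsilon: float = 1e-5
    class_weights: tuple[float, ...] | None = None
    include_background_in_dice: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.class_weights is not None:
            self.class_weights = tuple(float(w) for w in self.class_weights)
            if any(w <= 0 for w in self.class_weights):
                raise ValueError("class_weights must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 24
    epochs: int = 150
    max_iterations: int | None = None
    lr_schedule: str = "constant"   # or "poly": lr * (1 - t/T)^poly_power
    poly_power: float = 0.9
    seed: int = 1234
    manifest: str | None = None
    augment: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive (momentum/decay non-negative)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.lr_schedule not in ("constant", "poly"):
            raise ValueError("lr_schedule must be 'constant' or 'poly'")
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        if isinstance(self.loss, dict):
            self.loss = LossConfig(**self.loss)


def load_train_config(path: str | Path, **overrides) -> TrainConfig:
    """Read a YAML key-value configuration file; keyword overrides win.

    Nested ``model.*`` / ``loss.*`` keys may be given either as nested
    mappings or flat dotted keys.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested: dict = {}
    for key, val in raw.items():
        if "." in key:
            head, tail = key.split(".", 1)
            nested.setdefault(head, {})[tail] = val
        else:
            nested[key] = val
    nested.update(overrides)
    return TrainConfig(**nested)


def save_train_config(cfg: TrainConfig, path: str | Path) -> None:
    data = asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


__all__ = [
    "ModelConfig", "LossConfig", "TrainConfig", "ORGAN_NAMES", "ORGAN_ABBREV",
    "DECODER_VARIANTS", "load_train_config", "save_train_config", "replace",
]
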