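"""SEF-UNet: SEFormer encoder, dCUP decoder, segmentation head.

The encoder is four stages of MetaFormer-style residual blocks whose token
mixer is a squeeze-and-excitation-gated depthwise-separable convolution:

    X' = SESepConv(LayerNorm(X)) + X
    Y  = X' + MLP(LayerNorm(X'))
    SESepConv(X) = pw2( SE( dw( act( pw1(X) ) ) ) )

Each stage starts with a strided downsampling convolution (x4 stem, then
x2), giving feature maps at 1/4, 1/8, 1/16 and 1/32 of the input.  The
decoder stacks depthwise cascaded upsampling (dCUP) blocks:

    Y = dw( ReLU( BatchNorm( conv3x3( cat(skip, up2(X)) ) ) ) )

the first three fusing the encoder skips, the last running without a skip;
a 1x1 classifier plus a final bilinear x2 restores input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concat, conv2d, interpolate_bilinear, no_grad
from .config import ModelConfig


# ---------------------------------------------------------------------
# array-level primitive operations (the auditable building blocks)
# ---------------------------------------------------------------------

def depthwise_conv2d(x, kernel, stride: int = 1, padding: int = 0):
    """Per-channel 2-D convolution.

    Parameters
    ----------
    x : (N, C, H, W) array or Tensor
    kernel : (C, k, k) array — one kernel per channel
    """
    xt = as_tensor(x)
    kern = np.asarray(kernel.data if isinstance(kernel, Tensor) else kernel,
                      dtype=np.float32)
    c = xt.shape[1]
    if kern.shape[0] != c:
        raise ValueError(f"kernel has {kern.shape[0]} channels, input has {c}")
    w = as_tensor(kern[:, None, :, :])
    out = conv2d(xt, w, None, stride=stride, padding=padding, groups=c)
    return out if isinstance(x, Tensor) else out.data


def pointwise_conv2d(x, weights, bias=None):
    """1x1 convolution mixing channels: ``weights`` is (C_in, C_out)."""
    xt = as_tensor(x)
    wmat = np.asarray(weights.data if isinstance(weights, Tensor) else weights,
                      dtype=np.float32)
    if wmat.shape[0] != xt.shape[1]:
        raise ValueError(
            f"weights expect {wmat.shape[0]} channels, input has {xt.shape[1]}")
    w = as_tensor(wmat.T[:, :, None, None])  # (C_out, C_in, 1, 1)
    b = None if bias is None else as_tensor(bias)
    out = conv2d(xt, w, b, stride=1, padding=0, groups=1)
    return out if isinstance(x, Tensor) else out.data


def se_gate(x, fc1_w, fc2_w, fc1_b=None, fc2_b=None):
    """Squeeze-and-excitation channel gating.

    Global average pool -> fc1 -> ReLU -> fc2 -> sigmoid, broadcast onto x.
    ``fc1_w`` is (C, C_r), ``fc2_w`` is (C_r, C).
    """
    xt = as_tensor(x)
    n, c = xt.shape[0], xt.shape[1]
    w1 = as_tensor(fc1_w)
    w2 = as_tensor(fc2_w)
    if w1.shape[0] != c:
        raise ValueError(f"fc1 expects {w1.shape[0]} channels, input has {c}")
    z = xt.mean(axis=(2, 3))                      # squeeze: (N, C)
    s = z @ w1
    if fc1_b is not None:
        s = s + as_tensor(fc1_b)
    s = s.relu()
    f = s @ w2
    if fc2_b is not None:
        f = f + as_tensor(fc2_b)
    f = f.sigmoid()                               # excitation: (N, C) in (0,1)
    out = xt * f.reshape(n, c, 1, 1)
    return out if isinstance(x, Tensor) else out.data


# ---------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------

class SEGate(nn.Module):
    """SE block on ``channels`` with bottleneck ``channels // reduction``.

    The two fully connected layers are bias-free.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError("SE bottleneck collapsed to zero units")
        self.fc1 = nn.Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return se_gate(x, self.fc1.weight, self.fc2.weight)


class SESeparableConv(nn.Module):
    """Token mixer: pw1 -> act -> depthwise -> SE gate -> pw2.

    Expands C to floor(expansion * C), mixes spatially per channel, gates
    channels, and projects back; resolution and channel count are preserved.
    """

    def __init__(self, channels: int, expansion: float, reduction: int,
                 kernel: int, activation: str, rng: np.random.Generator):
        super().__init__()
        expanded = int(np.floor(channels * expansion))
        self.pw1 = nn.Conv2d(channels, expanded, 1, rng=rng)
        self.act = nn.make_activation(activation)
        self.dw = nn.Conv2d(expanded, expanded, kernel, padding=kernel // 2,
                            groups=expanded, rng=rng)
        self.se = SEGate(expanded, reduction, rng)
        self.pw2 = nn.Conv2d(expanded, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pw2(self.se(self.dw(self.act(self.pw1(x)))))


class Mlp(nn.Module):
    """Position-wise two-layer MLP applied over the channel axis."""

    def __init__(self, channels: int, hidden: int, activation: str,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.act = nn.make_activation(activation)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        flat = x.transpose((0, 2, 3, 1)).reshape(n * h * w, c)
        out = self.fc2(self.act(self.fc1(flat)))
        return out.reshape(n, h, w, c).transpose((0, 3, 1, 2))


class SEFormerBlock(nn.Module):
    """MetaFormer residual pair with the SE separable-conv token mixer."""

    def __init__(self, channels: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(channels)
        self.mixer = SESeparableConv(channels, cfg.mixer_expansion,
                                     cfg.se_reduction, cfg.dw_kernel_encoder,
                                     cfg.activation, rng)
        self.norm2 = nn.LayerNorm(channels)
        hidden = int(np.floor(channels * cfg.mlp_ratio))
        self.mlp = Mlp(channels, hidden, cfg.activation, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.mixer(self.norm1(x)) + x
        return self.mlp(self.norm2(x)) + x


class DownsampleStage(nn.Module):
    """Strided convolution: x4 stem (7x7/4, pad 2) or x2 (3x3/2, pad 1)."""

    def __init__(self, in_channels: int, out_channels: int, is_stem: bool,
                 rng: np.random.Generator):
        super().__init__()
        if is_stem:
            self.conv = nn.Conv2d(in_channels, out_channels, 7, stride=4,
                                  padding=2, rng=rng)
        else:
            self.conv = nn.Conv2d(in_channels, out_channels, 3, stride=2,
                                  padding=1, rng=rng)
        self.stride = 4 if is_stem else 2

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % self.stride or x.shape[3] % self.stride:
            raise ValueError(
                f"resolution {x.shape[2:]} not divisible by stride {self.stride}")
        return self.conv(x)


@dataclass
class EncoderOutput:
    """Skip feature maps (stages 1..n-1) plus the bottleneck (last stage)."""
    skips: list[Tensor]
    bottleneck: Tensor


class Encoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.downsamples = nn.ModuleList()
        self.stages = nn.ModuleList()
        prev = cfg.in_channels
        for i in range(cfg.n_stages):
            self.downsamples.append(
                DownsampleStage(prev, cfg.dims[i], is_stem=(i == 0), rng=rng))
            stage = nn.ModuleList(
                SEFormerBlock(cfg.dims[i], cfg, rng) for _ in range(cfg.depths[i]))
            self.stages.append(stage)
            prev = cfg.dims[i]

    def forward(self, x: Tensor) -> EncoderOutput:
        feats = []
        for down, stage in zip(self.downsamples, self.stages):
            x = down(x)
            for block in stage:
                x = block(x)
            feats.append(x)
        return EncoderOutput(skips=feats[:-1], bottleneck=feats[-1])


class DCUPBlock(nn.Module):
    """Bilinear x2 upsample, optional skip concat, conv-BN-ReLU, and (in the
    dcup variant) a trailing depthwise convolution."""

    def __init__(self, in_channels: int, skip_channels: int, out_channels: int,
                 variant: str, dw_kernel: int, rng: np.random.Generator):
        super().__init__()
        if variant not in ("dcup", "cup"):
            raise ValueError(f"unknown decoder block variant {variant!r}")
        self.skip_channels = skip_channels
        self.conv = nn.Conv2d(in_channels + skip_channels, out_channels, 3,
                              padding=1, bias=False, rng=rng)
        self.norm = nn.BatchNorm2d(out_channels)
        self.act = nn.ReLU()
        self.dw = (nn.Conv2d(out_channels, out_channels, dw_kernel,
                             padding=dw_kernel // 2, groups=out_channels, rng=rng)
                   if variant == "dcup" else None)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        up = interpolate_bilinear(x, 2 * x.shape[2], 2 * x.shape[3])
        if skip is not None:
            if skip.shape[2] != up.shape[2] or skip.shape[3] != up.shape[3]:
                raise ValueError(
                    f"skip resolution {skip.shape[2:]} does not match "
                    f"upsampled {up.shape[2:]}")
            up = concat([skip, up], axis=1)
        elif self.skip_channels:
            raise ValueError("block was built with a skip but none was given")
        y = self.act(self.norm(self.conv(up)))
        if self.dw is not None:
            y = self.dw(y)
        return y


class Decoder(nn.Module):
    """Stack of dCUP/CUP blocks consuming the encoder skips deepest-first."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.decoder_variant == "none":
            raise ValueError("no decoder is built for variant 'none'")
        plan = cfg.decoder_plan()
        skip_dims = list(cfg.dims[: cfg.n_stages - 1])[::-1]  # deepest first
        self.blocks = nn.ModuleList()
        prev = cfg.dims[cfg.n_stages - 1]
        for j, out_ch in enumerate(plan):
            skip_ch = skip_dims[j] if j < len(skip_dims) else 0
            self.blocks.append(DCUPBlock(prev, skip_ch, out_ch,
                                         cfg.decoder_variant,
                                         cfg.dw_kernel_decoder, rng))
            prev = out_ch

    def forward(self, enc: EncoderOutput) -> Tensor:
        x = enc.bottleneck
        skips = enc.skips[::-1]
        for j, block in enumerate(self.blocks):
            x = block(x, skips[j] if j < len(skips) else None)
        return x


class SegmentationHead(nn.Module):
    """1x1 classifier followed by bilinear upsampling to input resolution."""

    def __init__(self, in_channels: int, num_classes: int, input_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, num_classes, 1, rng=rng)
        self.input_size = input_size

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if y.shape[2] != self.input_size or y.shape[3] != self.input_size:
            y = interpolate_bilinear(y, self.input_size, self.input_size)
        return y


class SEFUNet(nn.Module):
    """The full encoder-decoder segmentation network."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg, rng)
        if cfg.decoder_variant == "none":
            self.decoder = None
            head_in = cfg.dims[cfg.n_stages - 1]
        else:
            self.decoder = Decoder(cfg, rng)
            head_in = cfg.decoder_plan()[-1]
        self.head = SegmentationHead(head_in, cfg.num_classes, cfg.input_size, rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}")
        enc = self.encoder(x)
        feat = enc.bottleneck if self.decoder is None else self.decoder(enc)
        return self.head(feat)

    def predict_logits(self, x) -> np.ndarray:
        """Inference-mode forward pass returning a numpy array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(x).data
        finally:
            if was_training:
                self.train()
        return out


# ---------------------------------------------------------------------
# parameter / MAC accounting
# ---------------------------------------------------------------------

def count_parameters(cfg: ModelConfig | None = None) -> int:
    """Total learnable scalar count (weights, biases, norm parameters)."""
    return SEFUNet(cfg or ModelConfig()).num_parameters()


def _conv_macs(cin: int, cout: int, k: int, hw: int, groups: int = 1) -> int:
    return (cin // groups) * cout * k * k * hw


def count_macs(cfg: ModelConfig | None = None, input_size: int | None = None) -> float:
    """Multiply-accumulate count of one forward pass, in units of 1e9.

    Counts convolution and fully connected layers only, one MAC per
    FLOP-unit, for a single image.
    """
    cfg = cfg or ModelConfig()
    size = input_size or cfg.input_size
    if size % 32:
        raise ValueError("input size must be a multiple of 32")
    total = 0
    prev = cfg.in_channels
    res = size
    for i in range(cfg.n_stages):
        stride, k = (4, 7) if i == 0 else (2, 3)
        res //= stride
        hw = res * res
        c = cfg.dims[i]
        total += _conv_macs(prev, c, k, hw)
        ce, cr, mh = cfg.expanded_dim(i), cfg.se_hidden(i), cfg.mlp_hidden(i)
        per_block = (_conv_macs(c, ce, 1, hw)                       # pw1
                     + _conv_macs(ce, ce, cfg.dw_kernel_encoder, hw, groups=ce)
                     + ce * cr + cr * ce                            # SE fc pair
                     + _conv_macs(ce, c, 1, hw)                     # pw2
                     + c * mh * hw + mh * c * hw)                   # MLP
        total += cfg.depths[i] * per_block
        prev = c
    if cfg.decoder_variant == "none":
        total += prev * cfg.num_classes * res * res
        return total / 1e9
    plan = cfg.decoder_plan()
    skip_dims = list(cfg.dims[: cfg.n_stages - 1])[::-1]
    for j, out_ch in enumerate(plan):
        res *= 2
        hw = res * res
        skip_ch = skip_dims[j] if j < len(skip_dims) else 0
        total += _conv_macs(prev + skip_ch, out_ch, 3, hw)
        if cfg.decoder_variant == "dcup":
            total += _conv_macs(out_ch, out_ch, cfg.dw_kernel_decoder, hw,
                                groups=out_ch)
        prev = out_ch
    total += prev * cfg.num_classes * res * res  # 1x1 head at decoder output
    return total / 1e9


def summarize(cfg: ModelConfig | None = None) -> dict:
    """Per-component parameter counts and total MACs for reporting."""
    cfg = cfg or ModelConfig()
    model = SEFUNet(cfg)
    groups: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        groups[top] = groups.get(top, 0) + p.data.size
    total = model.num_parameters()
    return {
        "config": cfg,
        "per_component_parameters": groups,
        "total_parameters": total,
        "parameters_millions": round(total / 1e6, 2),
        "gmacs": round(count_macs(cfg, cfg.input_size), 2),
        "input_size": cfg.input_size,
    }


def format_summary(report: dict) -> str:
    lines = ["SEF-UNet architecture summary", "-" * 32]
    for comp, count in report["per_component_parameters"].items():
        lines.append(f"{comp:<12s} {count / 1e6:8.3f} M params")
    lines.append("-" * 32)
    lines.append(f"total        {report['parameters_millions']:.2f} M params")
    lines.append(f"MACs @ {report['input_size']}    {report['gmacs']:.2f} G")
    return "\n".join(lines)
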