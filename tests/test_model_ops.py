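"""Operator-level checks of the encoder/decoder building blocks:
loop oracles for the primitives, composition oracles for the blocks,
shape conservation, residual identities and architecture shapes."""

import numpy as np
import pytest

from oracles import loop_depthwise_conv2d, loop_pointwise_conv2d, loop_se_gate
from sefunet import nn
from sefunet.autodiff import Tensor
from sefunet.config import ModelConfig
from sefunet.model import (DCUPBlock, Decoder, Encoder, SEFUNet, SEFormerBlock,
                           SESeparableConv, SegmentationHead, count_macs,
                           count_parameters, depthwise_conv2d, pointwise_conv2d,
                           se_gate)


# ------------------------------------------------------------------ primitives

def test_depthwise_delta_kernel_is_identity(rng):
    x = rng.normal(size=(1, 3, 5, 5)).astype(np.float32)
    k = np.zeros((3, 3, 3), np.float32)
    k[:, 1, 1] = 1.0
    assert np.allclose(depthwise_conv2d(x, k, stride=1, padding=1), x, atol=1e-6)


def test_depthwise_all_ones_sums_window(rng):
    x = rng.normal(size=(1, 1, 3, 3)).astype(np.float32)
    out = depthwise_conv2d(x, np.ones((1, 3, 3), np.float32))
    assert out.shape == (1, 1, 1, 1)
    assert np.isclose(out[0, 0, 0, 0], x.sum(), atol=1e-5)


@pytest.mark.parametrize("stride,padding", [(1, 0), (1, 1), (2, 0), (2, 1)])
def test_depthwise_matches_loop_oracle(rng, stride, padding):
    x = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
    k = rng.normal(size=(4, 3, 3)).astype(np.float32)
    got = depthwise_conv2d(x, k, stride=stride, padding=padding)
    want = loop_depthwise_conv2d(x, k, stride=stride, padding=padding)
    assert np.abs(got - want).max() < 1e-5


def test_depthwise_rejects_bad_stride_and_channels(rng):
    x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
    with pytest.raises(ValueError):
        depthwise_conv2d(x, np.ones((3, 3, 3), np.float32))
    with pytest.raises(ValueError):
        depthwise_conv2d(x, np.ones((2, 3, 3), np.float32), stride=0)


def test_pointwise_identity_zero_and_loop(rng):
    x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
    assert np.allclose(pointwise_conv2d(x, np.eye(3, dtype=np.float32)), x, atol=1e-6)
    assert np.allclose(pointwise_conv2d(x, np.zeros((3, 3), np.float32)), 0.0)
    w = rng.normal(size=(3, 2)).astype(np.float32)
    got = pointwise_conv2d(x, w)
    assert np.abs(got - loop_pointwise_conv2d(x, w)).max() < 1e-5
    with pytest.raises(ValueError):
        pointwise_conv2d(x, np.ones((4, 2), np.float32))


def test_se_gate_zero_weights_halves_input(rng):
    x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
    out = se_gate(x, np.zeros((4, 2), np.float32), np.zeros((2, 4), np.float32))
    assert np.allclose(out, 0.5 * x, atol=1e-6)


def test_se_gate_squeeze_uses_channel_mean(rng):
    # a constant channel of value v must produce the same gate as any other
    # field with mean v on that channel
    v = 0.7
    const = np.full((1, 1, 4, 4), v, np.float32)
    varied = (v + rng.normal(size=(1, 1, 4, 4)).astype(np.float32))
    varied += v - varied.mean()
    w1 = rng.normal(size=(1, 2)).astype(np.float32)
    w2 = rng.normal(size=(2, 1)).astype(np.float32)
    g_const = se_gate(const, w1, w2) / const
    g_var = se_gate(varied, w1, w2) / varied
    assert np.allclose(g_const, g_var[0, 0, 0, 0], atol=1e-5)


def test_se_gate_matches_loop_oracle_and_range(rng):
    x = rng.normal(size=(2, 2, 3, 3)).astype(np.float32)
    w1 = (0.5 * rng.normal(size=(2, 2))).astype(np.float32)
    w2 = (0.5 * rng.normal(size=(2, 2))).astype(np.float32)
    got = se_gate(x, w1, w2)
    want = loop_se_gate(x, w1, w2)
    assert np.abs(got - want).max() < 1e-5
    gate = got[np.abs(x) > 1e-3] / x[np.abs(x) > 1e-3]
    assert (gate > 0).all() and (gate < 1).all()


# ------------------------------------------------------------------ mixers/blocks

def _manual_mixer(mixer: SESeparableConv, x: np.ndarray) -> np.ndarray:
    """Chain the audited primitives by hand: pw1 -> act -> dw -> SE -> pw2."""
    h = pointwise_conv2d(x, mixer.pw1.weight.data[:, :, 0, 0].T,
                         mixer.pw1.bias.data)
    h = np.maximum(h, 0.0)
    k = mixer.dw.kernel_size
    h = depthwise_conv2d(h, mixer.dw.weight.data[:, 0], padding=k // 2)
    h = h + mixer.dw.bias.data[None, :, None, None]
    h = loop_se_gate(h, mixer.se.fc1.weight.data, mixer.se.fc2.weight.data)
    return pointwise_conv2d(h, mixer.pw2.weight.data[:, :, 0, 0].T,
                            mixer.pw2.bias.data)


def test_se_separable_conv_matches_composition_and_preserves_shape(rng):
    mixer = SESeparableConv(6, expansion=2.0, reduction=4, kernel=3,
                            activation="relu", rng=rng)
    x = rng.normal(size=(2, 6, 5, 5)).astype(np.float32)
    got = mixer(Tensor(x)).data
    assert got.shape == x.shape
    assert np.abs(got - _manual_mixer(mixer, x)).max() < 1e-4


def test_se_separable_conv_zero_projection_annihilates(rng):
    mixer = SESeparableConv(4, 2.0, 2, 3, "relu", rng)
    mixer.pw2.weight.data[:] = 0.0
    x = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
    assert np.allclose(mixer(Tensor(x)).data, 0.0, atol=1e-7)


def _layernorm_ref(x, weight, bias):
    mu = x.mean(axis=1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
    xhat = (x - mu) / np.sqrt(var + 1e-6)
    return xhat * weight[None, :, None, None] + bias[None, :, None, None]


def test_seformer_block_matches_stepwise_evaluation(rng):
    cfg = ModelConfig(dims=(6, 8, 8, 8), depths=(1, 1, 1, 1),
                      mixer_expansion=2.0, mlp_ratio=2.0, se_reduction=2,
                      dw_kernel_encoder=3, input_size=32,
                      decoder_channels=(8, 8, 8, 8))
    block = SEFormerBlock(6, cfg, rng)
    x = rng.normal(size=(2, 6, 4, 4)).astype(np.float32)
    got = block(Tensor(x)).data

    n1 = _layernorm_ref(x, block.norm1.weight.data, block.norm1.bias.data)
    xp = _manual_mixer(block.mixer, n1) + x
    n2 = _layernorm_ref(xp, block.norm2.weight.data, block.norm2.bias.data)
    n, c, h, w = n2.shape
    flat = n2.transpose(0, 2, 3, 1).reshape(-1, c)
    hdn = np.maximum(flat @ block.mlp.fc1.weight.data + block.mlp.fc1.bias.data, 0)
    mlp = (hdn @ block.mlp.fc2.weight.data + block.mlp.fc2.bias.data)
    want = mlp.reshape(n, h, w, c).transpose(0, 3, 1, 2) + xp
    assert np.abs(got - want).max() < 1e-4


@pytest.mark.parametrize("channels,hw", [(4, 6), (10, 5), (16, 7)])
def test_seformer_block_shape_conservation(rng, channels, hw):
    cfg = ModelConfig(dims=(channels,) * 4, depths=(1, 1, 1, 1),
                      mixer_expansion=1.5, mlp_ratio=2.0, se_reduction=2,
                      input_size=32, decoder_channels=(8, 8, 8, 8),
                      dw_kernel_encoder=3)
    block = SEFormerBlock(channels, cfg, rng)
    x = rng.normal(size=(3, channels, hw, hw)).astype(np.float32)
    assert block(Tensor(x)).data.shape == x.shape


def test_residual_identity_when_projections_zeroed(rng):
    cfg = ModelConfig(dims=(6, 6, 6, 6), depths=(1, 1, 1, 1), input_size=32,
                      mixer_expansion=2.0, mlp_ratio=2.0, se_reduction=2,
                      decoder_channels=(8, 8, 8, 8), dw_kernel_encoder=3)
    block = SEFormerBlock(6, cfg, rng)
    x = rng.normal(size=(2, 6, 5, 5)).astype(np.float32)
    # zero token-mixer output projection: first residual becomes identity
    block.mixer.pw2.weight.data[:] = 0.0
    block.mixer.pw2.bias.data[:] = 0.0
    n2 = _layernorm_ref(x, block.norm2.weight.data, block.norm2.bias.data)
    mid = block.norm1(Tensor(x))
    xprime = block.mixer(mid).data + x
    assert np.allclose(xprime, x, atol=1e-6)
    # additionally zero the MLP projection: the whole block is the identity
    block.mlp.fc2.weight.data[:] = 0.0
    block.mlp.fc2.bias.data[:] = 0.0
    assert np.allclose(block(Tensor(x)).data, x, atol=1e-6)


# ------------------------------------------------------------------ stages/shapes

def test_default_encoder_stage_shapes_at_224():
    cfg = ModelConfig(depths=(1, 1, 1, 1))  # default dims, one block per stage
    enc = Encoder(cfg, np.random.default_rng(0))
    x = np.random.default_rng(1).random((1, 1, 224, 224), dtype=np.float32)
    from sefunet.autodiff import no_grad
    with no_grad():
        out = enc(Tensor(x))
    assert [s.shape[1:] for s in out.skips] == [
        (64, 56, 56), (128, 28, 28), (320, 14, 14)]
    assert out.bottleneck.shape[1:] == (512, 7, 7)


def test_encoder_resolution_scaling_and_stage_count(rng, tiny_model_config):
    from dataclasses import replace
    from sefunet.autodiff import no_grad
    cfg = replace(tiny_model_config, input_size=96)
    enc = Encoder(cfg, np.random.default_rng(0))
    with no_grad():
        out = enc(Tensor(rng.random((1, 1, 96, 96)).astype(np.float32)))
    assert out.bottleneck.shape[1:] == (cfg.dims[3], 3, 3)

    cfg2 = replace(tiny_model_config, n_stages=2)
    enc2 = Encoder(cfg2, np.random.default_rng(0))
    with no_grad():
        out2 = enc2(Tensor(rng.random((1, 1, 64, 64)).astype(np.float32)))
    assert len(out2.skips) == 1
    assert out2.bottleneck.shape[1:] == (cfg2.dims[1], 8, 8)


def test_downsample_rejects_indivisible_resolution(rng, tiny_model_config):
    enc = Encoder(tiny_model_config, np.random.default_rng(0))
    with pytest.raises(ValueError):
        enc(Tensor(rng.random((1, 1, 30, 30)).astype(np.float32)))


# ------------------------------------------------------------------ decoder

def test_dcup_block_shapes_with_published_channels(rng):
    block = DCUPBlock(512, 320, 256, "dcup", 3, rng)
    x = Tensor(rng.normal(size=(1, 512, 7, 7)).astype(np.float32))
    skip = Tensor(rng.normal(size=(1, 320, 14, 14)).astype(np.float32))
    block.eval()
    assert block(x, skip).shape == (1, 256, 14, 14)
    with pytest.raises(ValueError):
        block(x, Tensor(rng.normal(size=(1, 320, 15, 15)).astype(np.float32)))


def test_dcup_upsample_of_constant_is_constant(rng):
    block = DCUPBlock(3, 0, 4, "cup", 3, rng)
    x = Tensor(np.full((1, 3, 4, 4), 2.5, np.float32))
    from sefunet.autodiff import interpolate_bilinear
    up = interpolate_bilinear(x, 8, 8)
    assert np.allclose(up.data, 2.5, atol=1e-6)


def test_dcup_matches_manual_chain(rng):
    from sefunet.autodiff import interpolate_bilinear, concat
    block = DCUPBlock(5, 3, 4, "dcup", 3, rng)
    block.eval()
    x = Tensor(rng.normal(size=(2, 5, 3, 3)).astype(np.float32))
    skip = Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
    got = block(x, skip).data
    up = concat([skip, interpolate_bilinear(x, 6, 6)], axis=1)
    y = block.norm(block.conv(up)).data
    y = np.maximum(y, 0)
    k = block.dw.kernel_size
    y = depthwise_conv2d(y, block.dw.weight.data[:, 0], padding=k // 2)
    y = y + block.dw.bias.data[None, :, None, None]
    assert np.abs(got - y).max() < 1e-5


def test_decoder_variant_parameter_ordering(tiny_model_config):
    from dataclasses import replace
    counts = {v: count_parameters(replace(tiny_model_config, decoder_variant=v))
              for v in ("none", "cup", "dcup")}
    assert counts["none"] < counts["cup"] < counts["dcup"]


def test_decoder_output_resolution(tiny_model_config, rng):
    from sefunet.autodiff import no_grad
    model = SEFUNet(tiny_model_config)
    model.eval()
    with no_grad():
        enc = model.encoder(Tensor(rng.random((1, 1, 64, 64)).astype(np.float32)))
        dec = model.decoder(enc)
    assert dec.shape == (1, tiny_model_config.decoder_channels[3], 32, 32)


# ------------------------------------------------------------------ full model

def test_full_forward_shapes_and_variant_none(tiny_model_config, rng):
    from dataclasses import replace
    x = rng.random((2, 1, 64, 64)).astype(np.float32)
    model = SEFUNet(tiny_model_config)
    out = model.predict_logits(x)
    assert out.shape == (2, 9, 64, 64)
    assert np.isfinite(out).all()
    none_model = SEFUNet(replace(tiny_model_config, decoder_variant="none"))
    assert none_model.predict_logits(x).shape == (2, 9, 64, 64)


def test_forward_is_deterministic_and_batch_independent(tiny_model_config, rng):
    model = SEFUNet(tiny_model_config)
    x = rng.random((3, 1, 64, 64)).astype(np.float32)
    a = model.predict_logits(x)
    b = model.predict_logits(x)
    assert np.array_equal(a, b)
    solo = model.predict_logits(x[1:2])
    assert np.allclose(a[1], solo[0], atol=1e-5)


def test_gradient_reaches_every_parameter(tiny_model_config, rng):
    model = SEFUNet(tiny_model_config)
    x = rng.random((1, 1, 64, 64)).astype(np.float32)
    out = model(x)
    out.sum().backward()
    dead = [name for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []


# ------------------------------------------------------------------ accounting

def test_parameter_count_monotone_in_width():
    small = ModelConfig(dims=(8, 16, 32, 64), depths=(1, 1, 1, 1), input_size=64,
                        decoder_channels=(32, 16, 16, 8), mixer_expansion=2.0,
                        mlp_ratio=2.0, dw_kernel_encoder=3)
    big = ModelConfig(dims=(16, 32, 64, 128), depths=(1, 1, 1, 1), input_size=64,
                      decoder_channels=(32, 16, 16, 8), mixer_expansion=2.0,
                      mlp_ratio=2.0, dw_kernel_encoder=3)
    assert count_parameters(big) > count_parameters(small)


def test_macs_scale_with_input_area(tiny_model_config):
    base = count_macs(tiny_model_config, 224)
    quad = count_macs(tiny_model_config, 448)
    assert quad / base == pytest.approx(4.0, rel=1e-3)
    mid = count_macs(tiny_model_config, 384)
    assert mid / base == pytest.approx((384 / 224) ** 2, rel=1e-3)


def test_macs_counter_agrees_with_layer_enumeration(tiny_model_config):
    """Cross-check the analytic MAC counter against a direct enumeration of
    the instantiated model's conv/fc layers."""
    from sefunet import nn as snn
    cfg = tiny_model_config
    model = SEFUNet(cfg)
    size = cfg.input_size

    total = 0
    # walk modules, tracking resolutions the same way the forward pass does
    res = size
    for i, (down, stage) in enumerate(zip(model.encoder.downsamples,
                                          model.encoder.stages)):
        res //= down.stride
        hw = res * res
        c = down.conv
        total += (c.in_channels // c.groups) * c.out_channels * c.kernel_size ** 2 * hw
        for block in stage:
            for conv in (block.mixer.pw1, block.mixer.dw, block.mixer.pw2):
                total += (conv.in_channels // conv.groups) * conv.out_channels \
                    * conv.kernel_size ** 2 * hw
            for fc in (block.mixer.se.fc1, block.mixer.se.fc2):
                total += fc.in_features * fc.out_features
            for fc in (block.mlp.fc1, block.mlp.fc2):
                total += fc.in_features * fc.out_features * hw
    for blk in model.decoder.blocks:
        res *= 2
        hw = res * res
        conv = blk.conv
        total += conv.in_channels * conv.out_channels * 9 * hw
        if blk.dw is not None:
            total += blk.dw.out_channels * blk.dw.kernel_size ** 2 * hw
    total += model.head.conv.in_channels * model.head.conv.out_channels * res * res
    assert count_macs(cfg, size) == pytest.approx(total / 1e9, rel=1e-12)
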