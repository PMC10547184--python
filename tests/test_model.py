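"""Architecture contracts: encoder shapes, fusion, WCU, decoders, gradients."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from cunet import nn
from cunet.model import (CSFI, CSFIConfig, CUNet, Encoder, EncoderConfig,
                         WcuConfig, WideContextUnit, fuse_weighted,
                         images_to_batch, normalized_fusion_weights)
from cunet.nn import Tensor


def test_default_channel_schedule():
    cfg = EncoderConfig()
    assert [cfg.channels(l) for l in range(1, 8)] == [64, 128, 256, 512, 512,
                                                     512, 512]


def test_encoder_pyramid_sides_halve():
    cfg = EncoderConfig(levels=7, base_channels=8, channel_cap=16)
    enc = Encoder(cfg, bn_momentum=0.99, rng=np.random.default_rng(0)).eval()
    x = np.random.default_rng(1).random((1, 3, 128, 128))
    pyramid = enc(Tensor(x))
    sides = [p.shape[-1] for p in pyramid]
    assert sides == [128, 64, 32, 16, 8, 4, 2]
    channels = [p.shape[1] for p in pyramid]
    assert channels == [8, 16, 16, 16, 16, 16, 16]


def test_encoder_rejects_non_divisible_input():
    cfg = EncoderConfig(levels=7, base_channels=8)
    enc = Encoder(cfg, bn_momentum=0.99, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="divisible"):
        enc(Tensor(np.zeros((1, 3, 100, 100))))


def test_gating_unit_zeroed_conv_halves_feature():
    from cunet.nn import GatingUnit

    gate = GatingUnit(4, rng=np.random.default_rng(0)).eval()
    gate.conv.weight.data[...] = 0.0
    gate.conv.bias.data[...] = 0.0
    x = np.random.default_rng(1).normal(size=(1, 4, 6, 6))
    out = gate(Tensor(x)).data
    np.testing.assert_allclose(out, 0.5 * x, atol=1e-12)


def test_fuse_weighted_closed_forms_and_oracle():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=(2, 1, 2, 4, 4))
    e = 1e-4
    sym = fuse_weighted([Tensor(a), Tensor(b)], Tensor(np.array([1.0, 1.0])))
    np.testing.assert_allclose(sym.data, (a + b) / (2.0 + e), atol=1e-12)
    dom = fuse_weighted([Tensor(a), Tensor(b)], Tensor(np.array([0.0, 5.0])))
    np.testing.assert_allclose(dom.data, 5.0 * b / (5.0 + e), atol=1e-12)
    # three-input brute force, scalar arithmetic per element
    xs = rng.normal(size=(3, 1, 1, 3, 3))
    v = np.array([0.3, 1.7, 0.9])
    out = fuse_weighted([Tensor(x) for x in xs], Tensor(v)).data
    r = [max(vi, 0.0) for vi in v]
    den = sum(r) + e
    for i in range(3):
        for j in range(3):
            expect = sum(r[k] * xs[k, 0, 0, i, j] for k in range(3)) / den
            assert out[0, 0, i, j] == pytest.approx(expect, abs=1e-12)


def test_fuse_weighted_scale_equivariance_and_weight_bounds():
    rng = np.random.default_rng(3)
    xs = rng.normal(size=(3, 1, 2, 4, 4))
    v = np.array([1.2, -0.5, 0.4])  # negative weight is ReLU-ed away
    base = fuse_weighted([Tensor(x) for x in xs], Tensor(v)).data
    scaled = fuse_weighted([Tensor(3.5 * x) for x in xs], Tensor(v)).data
    np.testing.assert_allclose(scaled, 3.5 * base, atol=1e-10)
    w = normalized_fusion_weights(v)
    assert np.all(w >= 0.0)
    assert 0.0 <= w.sum() < 1.0


def test_fuse_weighted_shape_mismatch_names_index():
    a = Tensor(np.zeros((1, 1, 4, 4)))
    b = Tensor(np.zeros((1, 1, 5, 4)))
    with pytest.raises(ValueError, match="input 1"):
        fuse_weighted([a, b], Tensor(np.ones(2)))


def test_wcu_impulse_kernels_double_input():
    cfg = WcuConfig(kernel_extent=5)
    wcu = WideContextUnit(1, cfg, rng=np.random.default_rng(0))
    for conv in (wcu.conv_v1, wcu.conv_h1, wcu.conv_h2, wcu.conv_v2):
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
        center = tuple(s // 2 for s in conv.weight.data.shape[2:])
        conv.weight.data[(0, 0) + center] = 1.0
    x = np.random.default_rng(1).normal(size=(1, 1, 8, 8))
    np.testing.assert_allclose(wcu(Tensor(x)).data, 2.0 * x, atol=1e-12)


def test_wcu_matches_dense_separable_convolution_oracle():
    cfg = WcuConfig(kernel_extent=5)
    wcu = WideContextUnit(1, cfg, rng=np.random.default_rng(4))
    for conv in (wcu.conv_v1, wcu.conv_h1, wcu.conv_h2, wcu.conv_v2):
        conv.bias.data[...] = 0.0
    x = np.random.default_rng(5).normal(size=(5, 5))
    out = wcu(Tensor(x[None, None]))
    # dense oracle: each branch's NxN kernel is the outer product of its
    # orthogonal 1-D kernels (axes independent, so no flip subtleties)
    kv1 = wcu.conv_v1.weight.data[0, 0, :, 0]
    kh1 = wcu.conv_h1.weight.data[0, 0, 0, :]
    kh2 = wcu.conv_h2.weight.data[0, 0, 0, :]
    kv2 = wcu.conv_v2.weight.data[0, 0, :, 0]
    dense1 = np.outer(kv1, kh1)
    dense2 = np.outer(kv2, kh2)
    expect = correlate2d(x, dense1, mode="same") + correlate2d(x, dense2,
                                                              mode="same")
    np.testing.assert_allclose(out.data[0, 0], expect, atol=1e-5)


def test_wcu_rejects_even_extent():
    with pytest.raises(ValueError, match="odd"):
        WcuConfig(kernel_extent=4).validate()


def test_wcu_constant_input_gives_constant_interior():
    cfg = WcuConfig(kernel_extent=5)
    wcu = WideContextUnit(1, cfg, rng=np.random.default_rng(6))
    out = wcu(Tensor(np.full((1, 1, 16, 16), 0.7))).data[0, 0]
    interior = out[4:-4, 4:-4]
    np.testing.assert_allclose(interior, interior[0, 0], atol=1e-10)


def test_csfi_single_layer_matches_unrolled_composition():
    enc_cfg = EncoderConfig(levels=3, base_channels=8, channel_cap=16)
    cfg = CSFIConfig(n_layers=1, fpn_channels=8, levels_used=(1, 2, 3))
    csfi = CSFI(enc_cfg, cfg, bn_momentum=0.99,
                rng=np.random.default_rng(7)).eval()
    rng = np.random.default_rng(8)
    pyramid = [Tensor(rng.normal(size=(1, enc_cfg.channels(l), 16 // 2 ** (l - 1),
                                       16 // 2 ** (l - 1)))) for l in (1, 2, 3)]
    out = csfi(pyramid)
    # hand-unrolled: laterals+gates, top-down fuse/conv, bottom-up fuse/conv
    layer = csfi.layers[0]
    maps = [g(lat(p)) for p, lat, g in zip(pyramid, csfi.laterals, csfi.gates)]
    td2 = maps[2]
    td1 = layer.td_convs[1](layer.td_nodes[1](
        [maps[1], nn.resize_bilinear(td2, 8, 8)]))
    td0 = layer.td_convs[0](layer.td_nodes[0](
        [maps[0], nn.resize_bilinear(td1, 16, 16)]))
    out0 = td0
    out1 = layer.bu_convs[0](layer.bu_nodes[0](
        [maps[1], td1, nn.resize_bilinear(out0, 8, 8)]))
    out2 = layer.bu_convs[1](layer.bu_nodes[1](
        [maps[2], nn.resize_bilinear(out1, 4, 4)]))
    for got, expect in zip(out, (out0, out1, out2)):
        np.testing.assert_allclose(got.data, expect.data, atol=1e-10)


def test_csfi_requires_contiguous_levels():
    with pytest.raises(ValueError, match="contiguous"):
        CSFIConfig(levels_used=(3, 5, 7)).validate(7)


def test_forward_shapes_and_range(tiny_model):
    tiny_model.eval()
    x = np.random.default_rng(9).random((2, 3, 64, 64))
    seg, bou = tiny_model(x)
    assert seg.shape == (2, 1, 64, 64)
    assert bou.shape == (2, 1, 64, 64)
    for m in (seg.data, bou.data):
        assert m.min() >= 0.0 and m.max() <= 1.0


def test_eval_forward_deterministic_and_batch_consistent(tiny_model):
    tiny_model.eval()
    rng = np.random.default_rng(10)
    img = rng.random((1, 3, 64, 64))
    pair = np.concatenate([img, img])
    seg, bou = tiny_model(pair)
    np.testing.assert_array_equal(seg.data[0], seg.data[1])
    seg2, _ = tiny_model(pair)
    np.testing.assert_array_equal(seg.data, seg2.data)


def test_boundary_head_ablation_leaves_segmentation_unchanged(tiny_model_cfg):
    model = CUNet(tiny_model_cfg).eval()
    x = np.random.default_rng(11).random((1, 3, 64, 64))
    seg_before, bou_before = model(x)
    for name, p in model.decoder.named_parameters():
        if name.startswith("bou_"):
            p.data[...] = 0.0
    seg_after, bou_after = model(x)
    np.testing.assert_array_equal(seg_before.data, seg_after.data)
    assert not np.array_equal(bou_before.data, bou_after.data)


def test_every_parameter_receives_gradient(tiny_model_cfg):
    from cunet.losses import total_loss

    model = CUNet(tiny_model_cfg)
    model.eval()  # dropout off: gradient coverage is a connectivity property
    rng = np.random.default_rng(12)
    x = rng.random((2, 3, 64, 64))
    seg, bou = model(x)
    seg_t = (rng.random((2, 1, 64, 64)) > 0.5).astype(float)
    bou_t = (rng.random((2, 1, 64, 64)) > 0.5).astype(float)
    loss, _ = total_loss(seg, seg_t, bou, bou_t)
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, name
        assert np.any(p.grad != 0.0), name


def test_images_to_batch_layout():
    img = np.zeros((8, 6, 3))
    img[2, 3, 1] = 0.7
    batch = images_to_batch([img])
    assert batch.shape == (1, 3, 8, 6)
    assert batch[0, 1, 2, 3] == 0.7
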