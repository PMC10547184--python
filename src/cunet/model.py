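"""C-UNet: boundary-aware nucleus segmentation with cross-scale weighted fusion.

The network is a 7-level convolutional encoder feeding a stack of three
bidirectional weighted feature-pyramid layers (the cross-scale feature
integration module, CSFI), a wide-context unit (WCU) built from orthogonal
1-D convolutions, and two coupled top-down decoders that emit a segmentation
probability map and a boundary probability map at input resolution.

Every fusion node combines its inputs by fast normalized fusion,

    out = sum_i ReLU(v_i) x_i / (sum_j ReLU(v_j) + e),   e = 1e-4,

with one learnable scalar v_i per input edge, so each node learns the relative
importance of its resolutions.  Gating units (1x1 conv -> batch norm ->
sigmoid -> dropout, multiplied into the feature) suppress responses from
irrelevant regions before fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor, Module


FUSION_EPS = 1e-4


@dataclass
class EncoderConfig:
    levels: int = 7
    base_channels: int = 64
    channel_cap: int = 512
    dropout_rate: float = 0.5

    def validate(self):
        if self.levels < 3:
            raise ValueError("encoder needs at least 3 levels")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def channels(self, level: int) -> int:
        return min(self.base_channels * 2 ** (level - 1), self.channel_cap)


@dataclass
class CSFIConfig:
    n_layers: int = 3
    fpn_channels: int = 64
    levels_used: tuple[int, ...] = (3, 4, 5, 6, 7)

    def validate(self, encoder_levels: int):
        if self.n_layers < 1:
            raise ValueError("CSFI needs at least one layer")
        lv = sorted(self.levels_used)
        if lv != list(range(lv[0], lv[-1] + 1)):
            raise ValueError("levels_used must be contiguous")
        if lv[-1] > encoder_levels:
            raise ValueError("levels_used exceeds encoder depth")


@dataclass
class WcuConfig:
    kernel_extent: int = 7

    def validate(self):
        if self.kernel_extent % 2 == 0 or self.kernel_extent < 3:
            raise ValueError("WCU kernel extent must be odd and >= 3")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    csfi: CSFIConfig = field(default_factory=CSFIConfig)
    wcu: WcuConfig = field(default_factory=WcuConfig)
    wcu_level: int = 6  # pyramid level routed through the WCU into the decoder seed
    bn_momentum: float = 0.99
    seed: int = 0

    def validate(self):
        self.encoder.validate()
        self.csfi.validate(self.encoder.levels)
        self.wcu.validate()
        if self.wcu_level not in self.csfi.levels_used:
            raise ValueError("wcu_level must be one of csfi.levels_used")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["csfi"]["levels_used"] = list(self.csfi.levels_used)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        enc = EncoderConfig(**d["encoder"])
        cs = CSFIConfig(**{**d["csfi"], "levels_used": tuple(d["csfi"]["levels_used"])})
        wcu = WcuConfig(**d["wcu"])
        return cls(encoder=enc, csfi=cs, wcu=wcu, wcu_level=d["wcu_level"],
                   bn_momentum=d["bn_momentum"], seed=d["seed"])

    def reduced(self) -> "ModelConfig":
        """A narrow configuration for CPU-scale smoke training."""
        return ModelConfig(
            encoder=EncoderConfig(levels=self.encoder.levels, base_channels=8,
                                  channel_cap=64,
                                  dropout_rate=self.encoder.dropout_rate),
            csfi=CSFIConfig(n_layers=self.csfi.n_layers, fpn_channels=16,
                            levels_used=self.csfi.levels_used),
            wcu=self.wcu, wcu_level=self.wcu_level,
            bn_momentum=self.bn_momentum, seed=self.seed,
        )


def fuse_weighted(inputs: list, v: Tensor, e: float = FUSION_EPS) -> Tensor:
    """Fast normalized fusion of equal-shape features with ReLU-ed weights."""
    if len(inputs) != v.data.shape[0]:
        raise ValueError(f"{len(inputs)} inputs but {v.data.shape[0]} weights")
    shape = inputs[0].shape if isinstance(inputs[0], Tensor) else np.shape(inputs[0])
    for i, x in enumerate(inputs[1:], start=1):
        xs = x.shape if isinstance(x, Tensor) else np.shape(x)
        if xs != shape:
            raise ValueError(f"fusion input {i} has shape {xs}, expected {shape}")
    r = nn.relu(v)
    den = nn.tsum(r) + e
    num = None
    for i, x in enumerate(inputs):
        term = nn.mul(nn.astensor(x), r[i])
        num = term if num is None else num + term
    return num / den


def normalized_fusion_weights(v: np.ndarray, e: float = FUSION_EPS) -> np.ndarray:
    """Effective per-edge weights ReLU(v_i) / (sum ReLU(v) + e); sum < 1."""
    r = np.maximum(np.asarray(v, dtype=float), 0.0)
    return r / (r.sum() + e)


class FusionNode(Module):
    def __init__(self, n_inputs: int):
        super().__init__()
        self.v = Tensor(np.ones(n_inputs), requires_grad=True)

    def forward(self, inputs):
        return fuse_weighted(inputs, self.v)


class Encoder(Module):
    """Classic contracting path: per level two 3x3 conv+BN+ReLU, then 2x2
    max-pool; channels double per level up to the cap; dropout at the deepest
    level only."""

    def __init__(self, cfg: EncoderConfig, *, bn_momentum: float,
                 rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        blocks = []
        c_in = 3
        for level in range(1, cfg.levels + 1):
            c_out = cfg.channels(level)
            blocks.append(nn.ConvBnRelu(c_in, c_out, bn_momentum=bn_momentum, rng=rng))
            blocks.append(nn.ConvBnRelu(c_out, c_out, bn_momentum=bn_momentum, rng=rng))
            c_in = c_out
        self.blocks = blocks
        self.drop = nn.Dropout(cfg.dropout_rate, rng=rng)

    def forward(self, x) -> list[Tensor]:
        levels = self.cfg.levels
        side = x.shape[-1]
        need = 2 ** (levels - 1)
        if x.shape[-1] % need or x.shape[-2] % need:
            raise ValueError(
                f"input sides {x.shape[-2]}x{x.shape[-1]} must be divisible by "
                f"2^(levels-1) = {need}"
            )
        pyramid = []
        h = nn.astensor(x)
        for level in range(1, levels + 1):
            h = self.blocks[2 * (level - 1)](h)
            h = self.blocks[2 * level - 1](h)
            if level == levels:
                h = self.drop(h)
            pyramid.append(h)
            if level < levels:
                h = nn.maxpool2(h)
        return pyramid


class WideContextUnit(Module):
    """Two parallel compositions of orthogonal 1-D convolutions, summed.

    branch1 = Conv_1xN(Conv_Nx1(x)); branch2 = Conv_Nx1(Conv_1xN(x)).
    Each branch has an NxN effective receptive field at the cost of 1-D
    kernels.
    """

    def __init__(self, channels: int, cfg: WcuConfig, *, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        n = cfg.kernel_extent
        self.conv_v1 = nn.Conv2d(channels, channels, (n, 1), rng=rng)
        self.conv_h1 = nn.Conv2d(channels, channels, (1, n), rng=rng)
        self.conv_h2 = nn.Conv2d(channels, channels, (1, n), rng=rng)
        self.conv_v2 = nn.Conv2d(channels, channels, (n, 1), rng=rng)

    def forward(self, x):
        branch1 = self.conv_h1(self.conv_v1(x))
        branch2 = self.conv_v2(self.conv_h2(x))
        return branch1 + branch2


class CSFILayer(Module):
    """One bidirectional pass over the used pyramid levels.

    Top-down (coarse to fine): td_l = Conv(fuse(in_l, resize(td_{l+1}))).
    Bottom-up (fine to coarse): out_l = Conv(fuse(in_l, td_l, resize(out_{l-1})));
    the coarsest node fuses (in_L, resize(out_{L-1})) and the finest output is
    its top-down node.  All resizes are bilinear.
    """

    def __init__(self, n_levels: int, channels: int, *, bn_momentum: float,
                 rng: np.random.Generator):
        super().__init__()
        self.n_levels = n_levels
        self.td_nodes = [FusionNode(2) for _ in range(n_levels - 1)]
        self.td_convs = [
            nn.ConvBnRelu(channels, channels, bn_momentum=bn_momentum, rng=rng)
            for _ in range(n_levels - 1)
        ]
        self.bu_nodes = [
            FusionNode(3 if i < n_levels - 1 else 2) for i in range(1, n_levels)
        ]
        self.bu_convs = [
            nn.ConvBnRelu(channels, channels, bn_momentum=bn_momentum, rng=rng)
            for _ in range(1, n_levels)
        ]

    def forward(self, maps: list[Tensor]) -> list[Tensor]:
        n = self.n_levels
        td: list[Tensor | None] = [None] * n
        td[n - 1] = maps[n - 1]
        for idx in range(n - 2, -1, -1):
            up = nn.resize_bilinear(td[idx + 1], maps[idx].shape[2], maps[idx].shape[3])
            fused = self.td_nodes[idx]([maps[idx], up])
            td[idx] = self.td_convs[idx](fused)
        out: list[Tensor | None] = [None] * n
        out[0] = td[0]
        for idx in range(1, n):
            down = nn.resize_bilinear(out[idx - 1], maps[idx].shape[2],
                                      maps[idx].shape[3])
            if idx < n - 1:
                fused = self.bu_nodes[idx - 1]([maps[idx], td[idx], down])
            else:
                fused = self.bu_nodes[idx - 1]([maps[idx], down])
            out[idx] = self.bu_convs[idx - 1](fused)
        return out  # type: ignore[return-value]


class CSFI(Module):
    """Lateral 1x1 projections + gating, then stacked bidirectional layers."""

    def __init__(self, enc_cfg: EncoderConfig, cfg: CSFIConfig, *,
                 bn_momentum: float, rng: np.random.Generator):
        super().__init__()
        cfg.validate(enc_cfg.levels)
        self.cfg = cfg
        self.levels = tuple(sorted(cfg.levels_used))
        self.laterals = [
            nn.Conv2d(enc_cfg.channels(lv), cfg.fpn_channels, 1, rng=rng)
            for lv in self.levels
        ]
        self.gates = [
            nn.GatingUnit(cfg.fpn_channels, bn_momentum=bn_momentum, rng=rng)
            for _ in self.levels
        ]
        self.layers = [
            CSFILayer(len(self.levels), cfg.fpn_channels, bn_momentum=bn_momentum,
                      rng=rng)
            for _ in range(cfg.n_layers)
        ]

    def forward(self, pyramid: list[Tensor]) -> list[Tensor]:
        if len(pyramid) < self.levels[-1]:
            raise ValueError("encoder pyramid is shallower than levels_used")
        maps = [
            gate(lat(pyramid[lv - 1]))
            for lv, lat, gate in zip(self.levels, self.laterals, self.gates)
        ]
        for layer in self.layers:
            maps = layer(maps)
        return maps


class DecoderHead(Module):
    """Refinement unit (3x3 conv then 1x1 conv), bilinear upsampling to input
    resolution, 1x1 projection, sigmoid."""

    def __init__(self, channels: int, *, bn_momentum: float,
                 rng: np.random.Generator):
        super().__init__()
        self.refine3 = nn.ConvBnRelu(channels, channels, 3, bn_momentum=bn_momentum,
                                     rng=rng)
        self.refine1 = nn.ConvBnRelu(channels, channels, 1, bn_momentum=bn_momentum,
                                     rng=rng)
        self.project = nn.Conv2d(channels, 1, 1, rng=rng)

    def forward(self, x, out_h: int, out_w: int):
        h = self.refine1(self.refine3(x))
        h = nn.resize_bilinear(h, out_h, out_w)
        return nn.sigmoid(self.project(h))


class DualDecoder(Module):
    """Coupled top-down decoders.

    The segmentation branch at level l fuses (csfi_l, resize(seg_{l+1}),
    resize(csfi_{l+1})); the boundary branch fuses (seg_l, resize(bou_{l+1}),
    resize(csfi_{l+1})) — boundary features consume segmentation features but
    never the reverse.  The deepest level of each branch is seeded from the
    wide-context feature.
    """

    def __init__(self, n_levels: int, channels: int, *, bn_momentum: float,
                 rng: np.random.Generator):
        super().__init__()
        self.n_levels = n_levels
        self.seg_seed_node = FusionNode(2)
        self.seg_seed_conv = nn.ConvBnRelu(channels, channels,
                                           bn_momentum=bn_momentum, rng=rng)
        self.bou_seed_node = FusionNode(2)
        self.bou_seed_conv = nn.ConvBnRelu(channels, channels,
                                           bn_momentum=bn_momentum, rng=rng)
        self.seg_nodes = [FusionNode(3) for _ in range(n_levels - 1)]
        self.seg_convs = [
            nn.ConvBnRelu(channels, channels, bn_momentum=bn_momentum, rng=rng)
            for _ in range(n_levels - 1)
        ]
        self.bou_nodes = [FusionNode(3) for _ in range(n_levels - 1)]
        self.bou_convs = [
            nn.ConvBnRelu(channels, channels, bn_momentum=bn_momentum, rng=rng)
            for _ in range(n_levels - 1)
        ]
        self.seg_head = DecoderHead(channels, bn_momentum=bn_momentum, rng=rng)
        self.bou_head = DecoderHead(channels, bn_momentum=bn_momentum, rng=rng)

    def forward(self, csfi_maps: list[Tensor], wcu_feature: Tensor,
                out_h: int, out_w: int):
        n = self.n_levels
        deepest = csfi_maps[n - 1]
        wcu_at = nn.resize_bilinear(wcu_feature, deepest.shape[2], deepest.shape[3])
        seg = [None] * n
        seg[n - 1] = self.seg_seed_conv(self.seg_seed_node([deepest, wcu_at]))
        for idx in range(n - 2, -1, -1):
            hh, ww = csfi_maps[idx].shape[2], csfi_maps[idx].shape[3]
            seg_up = nn.resize_bilinear(seg[idx + 1], hh, ww)
            csfi_up = nn.resize_bilinear(csfi_maps[idx + 1], hh, ww)
            seg[idx] = self.seg_convs[idx](
                self.seg_nodes[idx]([csfi_maps[idx], seg_up, csfi_up])
            )
        bou = [None] * n
        bou[n - 1] = self.bou_seed_conv(self.bou_seed_node([seg[n - 1], wcu_at]))
        for idx in range(n - 2, -1, -1):
            hh, ww = csfi_maps[idx].shape[2], csfi_maps[idx].shape[3]
            bou_up = nn.resize_bilinear(bou[idx + 1], hh, ww)
            csfi_up = nn.resize_bilinear(csfi_maps[idx + 1], hh, ww)
            bou[idx] = self.bou_convs[idx](
                self.bou_nodes[idx]([seg[idx], bou_up, csfi_up])
            )
        seg_prob = self.seg_head(seg[0], out_h, out_w)
        bou_prob = self.bou_head(bou[0], out_h, out_w)
        return seg_prob, bou_prob


class CUNet(Module):
    """Full network: encoder -> gated CSFI (+WCU on one level) -> dual decoder."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg.encoder, bn_momentum=cfg.bn_momentum, rng=rng)
        self.csfi = CSFI(cfg.encoder, cfg.csfi, bn_momentum=cfg.bn_momentum, rng=rng)
        self.wcu = WideContextUnit(cfg.csfi.fpn_channels, cfg.wcu, rng=rng)
        self.decoder = DualDecoder(len(cfg.csfi.levels_used), cfg.csfi.fpn_channels,
                                   bn_momentum=cfg.bn_momentum, rng=rng)

    def forward(self, image) -> tuple[Tensor, Tensor]:
        x = nn.astensor(image)
        if x.ndim == 3:
            x = nn.reshape(x, (1,) + x.shape)
        out_h, out_w = x.shape[2], x.shape[3]
        pyramid = self.encoder(x)
        csfi_maps = self.csfi(pyramid)
        wcu_idx = self.cfg.wcu_level - min(self.cfg.csfi.levels_used)
        wcu_feature = self.wcu(csfi_maps[wcu_idx])
        return self.decoder(csfi_maps, wcu_feature, out_h, out_w)


def images_to_batch(images: list[np.ndarray]) -> np.ndarray:
    """Stack H x W x 3 float images into an (N, 3, H, W) batch."""
    return np.stack([np.moveaxis(im, -1, 0) for im in images]).astype(float)
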