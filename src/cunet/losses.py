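"""Composite training objectives for the dual-decoder network.

The segmentation head is trained with focal Tversky + w_seg * (Dice + BCE)
and the boundary head with focal Tversky + w_bou * Combo, both with
w_seg = w_bou = 0.4 — the combination found to give the best segmentation
quality.  Pixel terms are summed within an image and averaged over the batch,
which keeps the weights scale-free across crop sizes.

All losses accept autodiff tensors (for training) or plain arrays and accept
maps shaped (H, W), (N, H, W) or (N, 1, H, W).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import Tensor, astensor


@dataclass
class LossConfig:
    """Hyper-parameters of the composite objective.

    alpha_ft / beta_ft trade off false positives vs false negatives in the
    Tversky index; gamma_ft is the focal exponent (loss = (1 - TI)^(1/gamma)).
    alpha_combo balances weighted cross-entropy against the Dice score inside
    the combo loss, beta_combo weights the positive class in that CE.
    """

    w_seg: float = 0.4
    w_bou: float = 0.4
    E: float = 1e-3  # smoothness constant
    alpha_ft: float = 0.3
    beta_ft: float = 0.7
    gamma_ft: float = 4.0 / 3.0
    alpha_combo: float = 0.5
    beta_combo: float = 0.5
    head_balance: float = 1.0

    def validate(self):
        if min(self.w_seg, self.w_bou, self.head_balance) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.E <= 0 or self.gamma_ft <= 0:
            raise ValueError("E and gamma_ft must be > 0")
        if not 0.0 <= self.alpha_combo <= 1.0:
            raise ValueError("alpha_combo must be in [0, 1]")


_CLIP_EPS = 1e-7


def _as_batch(pred, target) -> tuple[Tensor, Tensor, int]:
    pred, target = astensor(pred), astensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if pred.ndim <= 2:
        shape = (1, pred.data.size)
    else:
        shape = (pred.shape[0], int(pred.data[0].size))
    return nn.reshape(pred, shape), nn.reshape(target, shape), shape[0]


def dice_loss(pred, target, E: float = 1e-3) -> Tensor:
    """1 - (2 sum(p t) + E) / (sum(p) + sum(t) + E), batch-averaged."""
    p, t, _ = _as_batch(pred, target)
    inter = nn.tsum(p * t, axis=1)
    denom = nn.tsum(p, axis=1) + nn.tsum(t, axis=1)
    return nn.tmean(1.0 - (2.0 * inter + E) / (denom + E))


def bce_loss(pred, target) -> Tensor:
    """Binary cross-entropy, pixel-averaged; predictions clipped to [1e-7, 1-1e-7]."""
    p, t, _ = _as_batch(pred, target)
    pc = nn.clip(p, _CLIP_EPS, 1.0 - _CLIP_EPS)
    terms = t * nn.log(pc) + (1.0 - t) * nn.log(1.0 - pc)
    return nn.tmean(-nn.tmean(terms, axis=1))


def focal_tversky_loss(pred, target, alpha: float = 0.3, beta: float = 0.7,
                       gamma: float = 4.0 / 3.0, E: float = 1e-3) -> Tensor:
    """(1 - TI)^(1/gamma) for the foreground class, batch-averaged.

    TI = (sum(p t) + E) / (sum(p t) + alpha sum((1-t) p) + beta sum(t (1-p)) + E);
    alpha penalizes false positives, beta false negatives.
    """
    p, t, _ = _as_batch(pred, target)
    tp = nn.tsum(p * t, axis=1)
    fp = nn.tsum((1.0 - t) * p, axis=1)
    fn = nn.tsum(t * (1.0 - p), axis=1)
    ti = (tp + E) / (tp + alpha * fp + beta * fn + E)
    return nn.tmean(nn.power(nn.clip(1.0 - ti, 0.0, 1.0), 1.0 / gamma))


def combo_loss(pred, target, alpha: float = 0.5, beta: float = 0.5,
               E: float = 1e-3) -> Tensor:
    """alpha * weighted-CE - (1 - alpha) * Dice score.

    The weighted CE weights the positive class by ``beta``.  Bounded below by
    -(1 - alpha) (perfect Dice with zero CE contribution).
    """
    p, t, _ = _as_batch(pred, target)
    pc = nn.clip(p, _CLIP_EPS, 1.0 - _CLIP_EPS)
    terms = beta * (t * nn.log(pc)) + (1.0 - beta) * ((1.0 - t) * nn.log(1.0 - pc))
    ce_w = nn.tmean(-nn.tmean(terms, axis=1))
    dice_score = 1.0 - dice_loss(pred, target, E)
    return alpha * ce_w - (1.0 - alpha) * dice_score


def seg_head_loss(pred, target, cfg: LossConfig | None = None) -> Tensor:
    """Focal Tversky + w_seg * (Dice + BCE)."""
    cfg = cfg or LossConfig()
    ft = focal_tversky_loss(pred, target, cfg.alpha_ft, cfg.beta_ft,
                            cfg.gamma_ft, cfg.E)
    return ft + cfg.w_seg * (dice_loss(pred, target, cfg.E) + bce_loss(pred, target))


def boundary_head_loss(pred, target, cfg: LossConfig | None = None) -> Tensor:
    """Focal Tversky + w_bou * Combo."""
    cfg = cfg or LossConfig()
    ft = focal_tversky_loss(pred, target, cfg.alpha_ft, cfg.beta_ft,
                            cfg.gamma_ft, cfg.E)
    return ft + cfg.w_bou * combo_loss(pred, target, cfg.alpha_combo,
                                       cfg.beta_combo, cfg.E)


def total_loss(seg_pred, seg_target, bou_pred, bou_target,
               cfg: LossConfig | None = None) -> tuple[Tensor, dict[str, float]]:
    """seg head + head_balance * boundary head, with a component breakdown."""
    cfg = cfg or LossConfig()
    cfg.validate()
    seg = seg_head_loss(seg_pred, seg_target, cfg)
    bou = boundary_head_loss(bou_pred, bou_target, cfg)
    total = seg + cfg.head_balance * bou
    breakdown = {
        "seg_head": seg.item(),
        "boundary_head": bou.item(),
        "head_balance": cfg.head_balance,
        "total": total.item(),
    }
    return total, breakdown
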