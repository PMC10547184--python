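"""Pixel- and object-level segmentation evaluation.

Pixel metrics (accuracy, recall/TPRp, precision, FPRp, Dice, F1) come from
the binary confusion counts.  Object metrics treat 8-connected components as
instances and match predicted to ground-truth instances one-to-one, greedily
by descending pairwise Dice among pairs exceeding a Dice threshold (0.7):
recall_o = matched / n_gt, FNRo = 1 - recall_o, and object accuracy is the
matched count over the union of objects (Jaccard-style).  Undefined ratios
(empty denominators) are reported as NaN, never silently as zero.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)

UNDEFINED = float("nan")


@dataclass
class PixelConfusion:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ObjectMatching:
    pairs: list[tuple[int, int, float]]
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    dsc_threshold: float = 0.7

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class MetricsReport:
    acc_o: float
    recall_o: float
    fnr_o: float
    acc_p: float
    recall_p: float
    tpr_p: float
    fpr_p: float
    dice: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    return prob_map > threshold


def pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> PixelConfusion:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return PixelConfusion(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: PixelConfusion) -> float:
    if c.total == 0:
        return UNDEFINED
    return (c.tp + c.tn) / c.total


def recall(c: PixelConfusion) -> float:
    if c.tp + c.fn == 0:
        return UNDEFINED
    return c.tp / (c.tp + c.fn)


def precision(c: PixelConfusion) -> float:
    if c.tp + c.fp == 0:
        return UNDEFINED
    return c.tp / (c.tp + c.fp)


def tpr_p(c: PixelConfusion) -> float:
    return recall(c)


def fpr_p(c: PixelConfusion) -> float:
    if c.fp + c.tn == 0:
        return UNDEFINED
    return c.fp / (c.fp + c.tn)


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """2 |pred ∩ gt| / (|pred| + |gt|); both empty counts as perfect (1)."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    denom = int(pred.sum()) + int(gt.sum())
    if denom == 0:
        logger.info("dice of two empty masks: defined as 1 (perfect agreement)")
        return 1.0
    return 2.0 * int(np.count_nonzero(pred & gt)) / denom


def f1_score(precision_value: float, recall_value: float) -> float:
    if math.isnan(precision_value) or math.isnan(recall_value):
        return UNDEFINED
    if precision_value + recall_value == 0:
        logger.info("F1 with precision = recall = 0: defined as 0")
        return 0.0
    return 2.0 * precision_value * recall_value / (precision_value + recall_value)


def label_instances(mask: np.ndarray) -> np.ndarray:
    """8-connected components of a binary mask as an instance map."""
    return ndimage.label(np.asarray(mask).astype(bool), structure=_STRUCT8)[0]


def _pairwise_dsc(gt: np.ndarray, pred: np.ndarray):
    """Dice for every overlapping (gt_id, pred_id) label pair."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    gt_sizes = np.bincount(gt.ravel())
    pred_sizes = np.bincount(pred.ravel())
    both = (gt > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True
    )
    out = {}
    for (g, p), inter in zip(pairs.T, counts):
        out[(int(g), int(p))] = 2.0 * inter / (gt_sizes[g] + pred_sizes[p])
    return out


def match_objects(pred_instances: np.ndarray, gt_instances: np.ndarray,
                  dsc_threshold: float = 0.7) -> ObjectMatching:
    """Greedy one-to-one matching by descending pairwise Dice (> threshold).

    Ties are broken by ascending (gt_id, pred_id) for determinism.
    """
    if np.shape(pred_instances) != np.shape(gt_instances):
        raise ValueError("instance maps must share shape")
    dsc = _pairwise_dsc(gt_instances, pred_instances)
    candidates = sorted(
        ((-d, g, p) for (g, p), d in dsc.items() if d > dsc_threshold)
    )
    gt_ids = set(np.unique(gt_instances)) - {0}
    pred_ids = set(np.unique(pred_instances)) - {0}
    pairs = []
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    for negd, g, p in candidates:
        if g in used_gt or p in used_pred:
            continue
        pairs.append((g, p, -negd))
        used_gt.add(g)
        used_pred.add(p)
    return ObjectMatching(
        pairs=pairs,
        unmatched_gt=sorted(gt_ids - used_gt),
        unmatched_pred=sorted(pred_ids - used_pred),
        dsc_threshold=dsc_threshold,
    )


def object_metrics(m: ObjectMatching, n_gt: int, n_pred: int,
                   union_normalized: bool = True):
    """(acc_o, recall_o, fnr_o) from a matching.

    acc_o = matched / (n_gt + n_pred - matched) by default (union
    normalization); set ``union_normalized=False`` for matched / n_pred.
    """
    if m.n_matched > min(n_gt, n_pred):
        raise ValueError("matched pairs exceed instance counts")
    if n_gt == 0:
        return UNDEFINED, UNDEFINED, UNDEFINED
    recall_o = m.n_matched / n_gt
    fnr_o = 1.0 - recall_o
    denom = (n_gt + n_pred - m.n_matched) if union_normalized else n_pred
    acc_o = m.n_matched / denom if denom > 0 else UNDEFINED
    return acc_o, recall_o, fnr_o


def evaluate_pair(pred_mask: np.ndarray, gt_mask: np.ndarray,
                  gt_instances: np.ndarray | None = None,
                  dsc_threshold: float = 0.7,
                  union_normalized: bool = True) -> MetricsReport:
    """All nine metrics for one predicted/ground-truth mask pair."""
    c = pixel_confusion(pred_mask, gt_mask)
    prec = precision(c)
    rec = recall(c)
    pred_inst = label_instances(pred_mask)
    if gt_instances is None:
        gt_instances = label_instances(gt_mask)
    n_gt = int(len(np.unique(gt_instances)) - (1 if 0 in gt_instances else 0))
    n_pred = int(pred_inst.max())
    matching = match_objects(pred_inst, gt_instances, dsc_threshold)
    acc_o, recall_o, fnr_o = object_metrics(matching, n_gt, n_pred,
                                            union_normalized)
    return MetricsReport(
        acc_o=acc_o,
        recall_o=recall_o,
        fnr_o=fnr_o,
        acc_p=accuracy(c),
        recall_p=rec,
        tpr_p=tpr_p(c),
        fpr_p=fpr_p(c),
        dice=dice_coefficient(pred_mask, gt_mask),
        f1=f1_score(prec, rec),
    )


FIELDS = ("acc_o", "recall_o", "fnr_o", "acc_p", "recall_p", "tpr_p",
          "fpr_p", "dice", "f1")


def evaluate_dataset(pred_dir, gt_dir, dsc_threshold: float = 0.7,
                     union_normalized: bool = True,
                     csv_path=None, summary_path=None):
    """Evaluate matching mask files from two directories.

    Prediction masks are PNGs; the ground truth for ``name.png`` is
    ``gt_dir/name.png`` (binary mask), with instances taken from
    ``gt_dir/<name with mask_ -> instance_>.tiff`` when present.  Returns
    (per-image rows, summary dict with mean and std per metric).
    """
    from PIL import Image
    import tifffile

    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    rows = []
    pred_files = sorted(pred_dir.glob("*.png"))
    if not pred_files:
        raise FileNotFoundError(f"no PNG masks found in {pred_dir}")
    for pf in pred_files:
        gf = gt_dir / pf.name
        if not gf.exists():
            raise FileNotFoundError(f"missing ground truth for {pf.name}: {gf}")
        pred = np.asarray(Image.open(pf).convert("L")) > 127
        gt = np.asarray(Image.open(gf).convert("L")) > 127
        inst_file = gt_dir / (pf.stem.replace("mask_", "instance_") + ".tiff")
        gt_inst = tifffile.imread(inst_file).astype(np.int32) if inst_file.exists() else None
        report = evaluate_pair(pred, gt, gt_inst, dsc_threshold, union_normalized)
        rows.append({"filename": pf.name, **report.as_dict()})
    summary = {}
    for key in FIELDS:
        vals = np.array([r[key] for r in rows], dtype=float)
        vals = vals[~np.isnan(vals)]
        summary[key] = {
            "mean": float(vals.mean()) if vals.size else UNDEFINED,
            "std": float(vals.std()) if vals.size else UNDEFINED,
        }
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=("filename",) + FIELDS)
            writer.writeheader()
            writer.writerows(rows)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return rows, summary
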