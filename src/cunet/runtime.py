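"""Training and prediction orchestration.

Optimization follows the reference recipe: SGD (lr 1e-3, momentum 0.9,
weight decay 5e-4), batch-norm running-statistics decay 0.99, random square
crops for training, full-resolution evaluation, early stopping on validation
Dice with the best-validation checkpoint retained.  Every source of
randomness (split shuffling, crop positions, augmentation, weight
initialization, dropout) is seeded, so a run is reproducible bit-for-bit on
one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .losses import LossConfig, total_loss
from .metrics import dice_coefficient
from .model import CUNet, ModelConfig, images_to_batch
from .nn import SGD
from .preprocessing import AugmentationPolicy, augment


@dataclass
class Sample:
    image: np.ndarray  # H x W x 3 in [0, 1]
    mask: np.ndarray  # H x W bool
    boundary: np.ndarray  # H x W bool
    name: str = ""


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 10
    bn_momentum_decay: float = 0.99
    train_crop: int = 256
    eval_size: int = 512
    max_epochs: int = 100
    max_steps: int | None = None
    early_stop_patience: int = 15
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def validate(self, model_cfg: ModelConfig):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        need = 2 ** (model_cfg.encoder.levels - 1)
        if self.train_crop % need:
            raise ValueError(
                f"train_crop must be divisible by 2^(levels-1) = {need}"
            )


def load_samples(dataset_dir) -> list[Sample]:
    """Read all scenes listed in a dataset manifest."""
    from PIL import Image

    dataset_dir = Path(dataset_dir)
    with open(dataset_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    samples = []
    for entry in manifest["scenes"]:
        image = np.asarray(Image.open(dataset_dir / entry["image"])).astype(float) / 255.0
        mask = np.asarray(Image.open(dataset_dir / entry["mask"]).convert("L")) > 127
        boundary = np.asarray(
            Image.open(dataset_dir / entry["boundary"]).convert("L")) > 127
        samples.append(Sample(image=image, mask=mask, boundary=boundary,
                              name=entry["image"]))
    return samples


def split_dataset(items: list, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Deterministic shuffled split into train/val/test lists."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(items) < 3:
        raise ValueError("dataset must have at least 3 items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n = len(items)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(max(n_train, 1), n - 2)
    n_val = min(max(n_val, 1), n - n_train - 1)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train : n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val :]]
    return train, val, test


def _random_crop(sample: Sample, size: int, rng: np.random.Generator) -> Sample:
    h, w = sample.mask.shape
    if h < size or w < size:
        raise ValueError(f"sample {sample.name} smaller than crop size {size}")
    y0 = int(rng.integers(0, h - size + 1))
    x0 = int(rng.integers(0, w - size + 1))
    return Sample(
        image=sample.image[y0 : y0 + size, x0 : x0 + size],
        mask=sample.mask[y0 : y0 + size, x0 : x0 + size],
        boundary=sample.boundary[y0 : y0 + size, x0 : x0 + size],
        name=sample.name,
    )


def _pad_to_divisible(image: np.ndarray, divisor: int):
    h, w = image.shape[:2]
    ph = (-h) % divisor
    pw = (-w) % divisor
    if ph == 0 and pw == 0:
        return image, (0, 0)
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="reflect"), (ph, pw)


def _masks_to_batch(masks: list[np.ndarray]) -> np.ndarray:
    return np.stack([m[None].astype(float) for m in masks])


def refresh_batchnorm_stats(model: CUNet, batch: np.ndarray):
    """Re-estimate batch-norm running statistics from one calibration batch.

    With a slow decay (0.99) the running estimates lag the weights after short
    training runs; a single momentum-0 pass pins them to the statistics of the
    final weights.  Weights are untouched.
    """
    from .nn.layers import BatchNorm2d

    bns = []
    stack = [model]
    while stack:
        mod = stack.pop()
        for _, child in mod._children():
            stack.append(child)
        if isinstance(mod, BatchNorm2d):
            bns.append((mod, mod.momentum))
            mod.momentum = 0.0
    was_training = model.training
    model.train()
    model(batch)
    model.train(was_training)
    for bn, momentum in bns:
        bn.momentum = momentum


def validation_dice(model: CUNet, samples: list[Sample],
                    threshold: float = 0.5) -> float:
    """Mean Dice of thresholded eval-mode predictions over ``samples``."""
    was_training = model.training
    model.eval()
    divisor = 2 ** (model.cfg.encoder.levels - 1)
    dices = []
    for s in samples:
        img, (ph, pw) = _pad_to_divisible(s.image, divisor)
        seg, _ = model(images_to_batch([img]))
        prob = seg.data[0, 0]
        if ph or pw:
            prob = prob[: prob.shape[0] - ph or None, : prob.shape[1] - pw or None]
        dices.append(dice_coefficient(prob > threshold, s.mask))
    model.train(was_training)
    return float(np.mean(dices))


@dataclass
class TrainResult:
    checkpoint_path: Path
    log_path: Path
    best_val_dice: float
    epochs_run: int
    steps_run: int
    history: list[dict] = field(default_factory=list)


def save_checkpoint(path, model: CUNet, train_cfg: TrainConfig,
                    loss_cfg: LossConfig, extra: dict | None = None):
    """Self-describing checkpoint: weights + full config + seed."""
    meta = {
        "model": model.cfg.to_dict(),
        "train": {**asdict(train_cfg),
                  "split": list(train_cfg.split)},
        "loss": asdict(loss_cfg),
        **(extra or {}),
    }
    state = model.state_dict()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[CUNet, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = CUNet(ModelConfig.from_dict(meta["model"]))
    model.load_state_dict(state)
    return model, meta


def train(train_samples: list[Sample], val_samples: list[Sample],
          model_cfg: ModelConfig | None = None,
          loss_cfg: LossConfig | None = None,
          train_cfg: TrainConfig | None = None,
          policy: AugmentationPolicy | None = None,
          out_dir=".", init_from=None) -> TrainResult:
    """Train a C-UNet; returns the best-validation checkpoint and a JSONL log.

    ``init_from`` warm-starts the weights from an existing checkpoint file
    (pretraining hook; no download logic).
    """
    model_cfg = model_cfg or ModelConfig()
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    model_cfg.bn_momentum = train_cfg.bn_momentum_decay
    train_cfg.validate(model_cfg)
    if not train_samples or not val_samples:
        raise ValueError("train and validation manifests must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "training_log.jsonl"
    ckpt_path = out_dir / "checkpoint.npz"

    model = CUNet(model_cfg)
    if init_from is not None:
        with np.load(init_from, allow_pickle=False) as data:
            state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state_dict(state)
    model.train()
    opt = SGD(model.parameters(), lr=train_cfg.learning_rate,
              momentum=train_cfg.momentum, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)

    best_dice = -np.inf
    best_state = None
    epochs_without_improvement = 0
    step = 0
    history = []
    stop = False
    with open(log_path, "w") as log:
        for epoch in range(train_cfg.max_epochs):
            order = rng.permutation(len(train_samples))
            for start in range(0, len(order), train_cfg.batch_size):
                batch_idx = order[start : start + train_cfg.batch_size]
                imgs, masks, bounds = [], [], []
                for i in batch_idx:
                    s = train_samples[i]
                    if min(s.mask.shape) > train_cfg.train_crop:
                        s = _random_crop(s, train_cfg.train_crop, rng)
                    if policy is not None:
                        img, (m, b) = augment(s.image, (s.mask, s.boundary),
                                              policy, rng=rng)
                        s = Sample(img, m, b, s.name)
                    imgs.append(s.image)
                    masks.append(s.mask)
                    bounds.append(s.boundary)
                seg, bou = model(images_to_batch(imgs))
                loss, parts = total_loss(seg, _masks_to_batch(masks),
                                         bou, _masks_to_batch(bounds), loss_cfg)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at step {step}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                step += 1
                log.write(json.dumps({"step": step, "epoch": epoch, **parts}) + "\n")
                if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                    stop = True
                    break
            val_dice = validation_dice(model, val_samples)
            history.append({"epoch": epoch, "val_dice": val_dice, "step": step})
            log.write(json.dumps(history[-1]) + "\n")
            if val_dice > best_dice:
                best_dice = val_dice
                best_state = model.state_dict()
                epochs_without_improvement = 0
            else:
                epochs_without_improvement += 1
            if stop or epochs_without_improvement >= train_cfg.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    save_checkpoint(ckpt_path, model, train_cfg, loss_cfg,
                    extra={"best_val_dice": best_dice})
    return TrainResult(
        checkpoint_path=ckpt_path,
        log_path=log_path,
        best_val_dice=best_dice,
        epochs_run=history[-1]["epoch"] + 1 if history else 0,
        steps_run=step,
        history=history,
    )


def predict(checkpoint_path, image_dir, out_dir, threshold: float = 0.5,
            save_probabilities: bool = False) -> list[Path]:
    """Write thresholded prediction masks for every PNG image in a directory.

    Inputs whose sides are not divisible by the network's pooling factor are
    reflect-padded (offsets recorded in a sidecar JSON), never cropped.
    """
    from PIL import Image
    import tifffile

    model, _meta = load_checkpoint(checkpoint_path)
    model.eval()
    divisor = 2 ** (model.cfg.encoder.levels - 1)
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    metadata = {}
    for pf in sorted(image_dir.glob("image_*.png")) or sorted(image_dir.glob("*.png")):
        image = np.asarray(Image.open(pf).convert("RGB")).astype(float) / 255.0
        padded, (ph, pw) = _pad_to_divisible(image, divisor)
        seg, bou = model(images_to_batch([padded]))
        prob = seg.data[0, 0]
        bprob = bou.data[0, 0]
        if ph or pw:
            prob = prob[: prob.shape[0] - ph or None, : prob.shape[1] - pw or None]
            bprob = bprob[: bprob.shape[0] - ph or None, : bprob.shape[1] - pw or None]
        mask = prob > threshold
        out_name = pf.stem.replace("image_", "mask_") + ".png"
        out_path = out_dir / out_name
        Image.fromarray(mask.astype(np.uint8) * 255).save(out_path)
        if save_probabilities:
            tifffile.imwrite(out_dir / (pf.stem + "_prob.tiff"),
                             prob.astype(np.float32))
        metadata[pf.name] = {"pad": [ph, pw], "threshold": threshold}
        written.append(out_path)
    with open(out_dir / "predict_meta.json", "w") as fh:
        json.dump(metadata, fh, indent=2)
    return written
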