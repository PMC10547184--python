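"""Paired image/target augmentation.

Geometric transforms (flips, resize-rescale, integer translation, elastic
deformation) are applied identically to the image and both supervision
targets, with nearest-neighbor interpolation for the binary targets and
bilinear for the image.  Photometric transforms (blur, noise, hue/saturation/
contrast shifts) touch the image only.  Every call is deterministic given the
inputs and the policy seed (or an explicit generator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

logger = logging.getLogger(__name__)

GEOMETRIC_ORDER = (
    "horizontal_flip",
    "vertical_flip",
    "resize_rescale",
    "translation",
    "elastic_deformation",
)
PHOTOMETRIC_ORDER = (
    "gaussian_blur",
    "gaussian_noise",
    "additive_gaussian_noise",
    "hue_shift",
    "saturation_shift",
    "contrast_shift",
)


@dataclass
class TransformSpec:
    prob: float = 0.5
    magnitude: tuple[float, float] | None = None

    def validate(self, name: str):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"{name}: probability must be in [0, 1]")


@dataclass
class AugmentationPolicy:
    """Which transforms to apply, with what probability and magnitude range."""

    geometric: dict[str, TransformSpec] = field(default_factory=dict)
    photometric: dict[str, TransformSpec] = field(default_factory=dict)
    seed: int = 0

    def validate(self):
        for name, spec in {**self.geometric, **self.photometric}.items():
            if name not in GEOMETRIC_ORDER + PHOTOMETRIC_ORDER:
                raise ValueError(f"unknown transform {name!r}")
            spec.validate(name)

    @classmethod
    def default(cls, seed: int = 0) -> "AugmentationPolicy":
        """The augmentation family used for cytology training images."""
        return cls(
            geometric={
                "horizontal_flip": TransformSpec(0.5),
                "vertical_flip": TransformSpec(0.5),
                "resize_rescale": TransformSpec(0.3, (0.9, 1.1)),
                "translation": TransformSpec(0.3, (-20, 20)),
                "elastic_deformation": TransformSpec(0.2, (4.0, 8.0)),
            },
            photometric={
                "gaussian_blur": TransformSpec(0.3, (0.3, 1.2)),
                "gaussian_noise": TransformSpec(0.2, (0.01, 0.04)),
                "additive_gaussian_noise": TransformSpec(0.2, (0.01, 0.05)),
                "hue_shift": TransformSpec(0.3, (-0.04, 0.04)),
                "saturation_shift": TransformSpec(0.3, (-0.15, 0.15)),
                "contrast_shift": TransformSpec(0.3, (0.8, 1.2)),
            },
            seed=seed,
        )


def _translate(arr: np.ndarray, dy: int, dx: int, order: int) -> np.ndarray:
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def _resize_rescale(arr: np.ndarray, scale: float, order: int) -> np.ndarray:
    h, w = arr.shape[:2]
    zoom = [scale, scale] + [1] * (arr.ndim - 2)
    z = ndimage.zoom(arr.astype(float), zoom, order=order)
    zh, zw = z.shape[:2]
    out = np.zeros_like(arr, dtype=z.dtype)
    if zh >= h:  # center crop
        y0, x0 = (zh - h) // 2, (zw - w) // 2
        out = z[y0 : y0 + h, x0 : x0 + w]
    else:  # center pad
        y0, x0 = (h - zh) // 2, (w - zw) // 2
        out = np.zeros(arr.shape, dtype=z.dtype)
        out[y0 : y0 + zh, x0 : x0 + zw] = z
    return out


def _elastic_fields(shape, alpha: float, rng: np.random.Generator,
                    smooth: float = 8.0):
    """Smooth displacement fields, rescaled if they would fold the grid."""
    dy = ndimage.gaussian_filter(rng.normal(size=shape), smooth) * alpha
    dx = ndimage.gaussian_filter(rng.normal(size=shape), smooth) * alpha
    # folding check: 1 + d(dy)/dy must stay positive (same for x)
    jy = 1.0 + np.gradient(dy, axis=0)
    jx = 1.0 + np.gradient(dx, axis=1)
    worst = min(jy.min(), jx.min())
    if worst <= 0.05:
        factor = 0.9 * 0.95 / max(1e-9, 1.0 - worst)
        logger.warning(
            "elastic deformation would fold the grid (min Jacobian %.3f); "
            "displacement rescaled by %.3f", worst, factor,
        )
        dy *= factor
        dx *= factor
    return dy, dx


def _warp(arr: np.ndarray, dy: np.ndarray, dx: np.ndarray, order: int):
    h, w = arr.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    coords = [yy + dy, xx + dx]
    if arr.ndim == 2:
        return ndimage.map_coordinates(arr.astype(float), coords, order=order,
                                       mode="reflect")
    chans = [
        ndimage.map_coordinates(arr[..., c].astype(float), coords, order=order,
                                mode="reflect")
        for c in range(arr.shape[2])
    ]
    return np.stack(chans, axis=-1)


def augment(image: np.ndarray, targets: tuple[np.ndarray, np.ndarray],
            policy: AugmentationPolicy,
            rng: np.random.Generator | None = None):
    """Apply the policy to one (image, (mask, boundary)) sample.

    Returns new arrays; inputs are never modified.  Masks keep their dtype.
    """
    policy.validate()
    mask, boundary = targets
    if image.shape[:2] != mask.shape or mask.shape != boundary.shape:
        raise ValueError("image and targets must share height and width")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    img = image.astype(float).copy()
    msk = mask.copy()
    bnd = boundary.copy()

    for name in GEOMETRIC_ORDER:
        spec = policy.geometric.get(name)
        if spec is None or rng.random() >= spec.prob:
            continue
        if name == "horizontal_flip":
            img, msk, bnd = img[:, ::-1].copy(), msk[:, ::-1].copy(), bnd[:, ::-1].copy()
        elif name == "vertical_flip":
            img, msk, bnd = img[::-1].copy(), msk[::-1].copy(), bnd[::-1].copy()
        elif name == "resize_rescale":
            scale = rng.uniform(*spec.magnitude)
            img = _resize_rescale(img, scale, order=1)
            msk = _resize_rescale(msk.astype(float), scale, order=0).astype(mask.dtype)
            bnd = _resize_rescale(bnd.astype(float), scale, order=0).astype(boundary.dtype)
        elif name == "translation":
            lo, hi = spec.magnitude
            dy = int(rng.integers(int(lo), int(hi) + 1))
            dx = int(rng.integers(int(lo), int(hi) + 1))
            img = _translate(img, dy, dx, order=1)
            msk = _translate(msk, dy, dx, order=0)
            bnd = _translate(bnd, dy, dx, order=0)
        elif name == "elastic_deformation":
            alpha = rng.uniform(*spec.magnitude)
            dy_f, dx_f = _elastic_fields(msk.shape, alpha, rng)
            img = _warp(img, dy_f, dx_f, order=1)
            msk = (_warp(msk.astype(float), dy_f, dx_f, order=0) > 0.5).astype(mask.dtype)
            bnd = (_warp(bnd.astype(float), dy_f, dx_f, order=0) > 0.5).astype(boundary.dtype)

    for name in PHOTOMETRIC_ORDER:
        spec = policy.photometric.get(name)
        if spec is None or rng.random() >= spec.prob:
            continue
        if name == "gaussian_blur":
            sigma = rng.uniform(*spec.magnitude)
            for c in range(img.shape[2]):
                img[..., c] = ndimage.gaussian_filter(img[..., c], sigma)
        elif name == "gaussian_noise":
            # multiplicative speckle: I * (1 + n)
            sigma = rng.uniform(*spec.magnitude)
            img = img * (1.0 + rng.normal(0.0, sigma, img.shape))
        elif name == "additive_gaussian_noise":
            sigma = rng.uniform(*spec.magnitude)
            img = img + rng.normal(0.0, sigma, img.shape)
        elif name == "hue_shift":
            shift = rng.uniform(*spec.magnitude)
            hsv = rgb2hsv(np.clip(img, 0, 1))
            hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
            img = hsv2rgb(hsv)
        elif name == "saturation_shift":
            shift = rng.uniform(*spec.magnitude)
            hsv = rgb2hsv(np.clip(img, 0, 1))
            hsv[..., 1] = np.clip(hsv[..., 1] + shift, 0.0, 1.0)
            img = hsv2rgb(hsv)
        elif name == "contrast_shift":
            factor = rng.uniform(*spec.magnitude)
            mean = img.mean()
            img = (img - mean) * factor + mean

    return np.clip(img, 0.0, 1.0), (msk, bnd)
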