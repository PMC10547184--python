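"""Synthetic cytology scene generator with exact instance-level ground truth.

Emulates the statistical structure of liquid-based cytology fields: elliptical,
partially overlapping, hematoxylin-dark nuclei sitting in eosin-tinted
cytoplasm halos, with defocus blur, sensor noise and unlabeled impurity blobs.
Rendering follows the Beer-Lambert law — per-pixel stain densities are mapped
to RGB transmittance through a 2x3 optical-density basis — so the scenes also
serve as ground-truthed fixtures for stain separation.

Photorealism is a non-goal; the generator's purpose is exact, reproducible
ground truth (instance map, semantic mask, boundary map) for every image.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

# Unit-normalized H&E optical-density color vectors (rows: hematoxylin, eosin).
DEFAULT_STAIN_BASIS = np.array(
    [
        [0.644, 0.717, 0.267],
        [0.093, 0.954, 0.283],
    ]
)
DEFAULT_STAIN_BASIS /= np.linalg.norm(DEFAULT_STAIN_BASIS, axis=1, keepdims=True)


@dataclass
class SceneParams:
    """Parameters of one synthetic cytology field.

    Ranges are inclusive (lo, hi) pairs sampled uniformly per scene.
    ``overlap_fraction`` is the probability that a newly placed nucleus is
    allowed to intersect an existing one; disallowed placements are
    rejection-sampled to stay disjoint.
    """

    image_height: int = 768
    image_width: int = 1024
    n_nuclei_range: tuple[int, int] = (5, 60)
    nucleus_radius_range: tuple[float, float] = (8.0, 28.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.85)
    overlap_fraction: float = 0.25
    border_truncation_prob: float = 0.15
    impurity_count_range: tuple[int, int] = (0, 6)
    blur_sigma_range: tuple[float, float] = (0.0, 1.2)
    noise_sigma_range: tuple[float, float] = (0.0, 0.03)
    stain_basis: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAIN_BASIS.copy()
    )
    seed: int = 0

    def validate(self):
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be at least 64 pixels")
        for name in ("n_nuclei_range", "nucleus_radius_range", "eccentricity_range",
                     "impurity_count_range", "blur_sigma_range", "noise_sigma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has lower > upper: {(lo, hi)}")
        if self.nucleus_radius_range[0] < 1:
            raise ValueError("nucleus radii must be >= 1 pixel")
        if self.nucleus_radius_range[1] > min(self.image_height, self.image_width) / 2:
            raise ValueError("nucleus radius range exceeds min(H, W)/2")
        if not (0.0 <= self.eccentricity_range[0] and self.eccentricity_range[1] < 1.0):
            raise ValueError("eccentricity range must lie in [0, 1)")
        basis = np.asarray(self.stain_basis, dtype=float)
        if basis.shape != (2, 3):
            raise ValueError("stain_basis must be a 2x3 matrix")
        if np.any(np.linalg.norm(basis, axis=1) <= 0):
            raise ValueError("stain_basis rows must have strictly positive norm")


@dataclass
class Ellipse:
    """One nucleus: center (row, col), semi-axes (a >= b), rotation in radians."""

    center: tuple[float, float]
    axes: tuple[float, float]
    theta: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        cy, cx = self.center
        a, b = self.axes
        dy, dx = rows - cy, cols - cx
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass
class LabeledScene:
    image: np.ndarray  # H x W x 3 float in [0, 1]
    instance_map: np.ndarray  # H x W int32, 0 = background
    semantic_mask: np.ndarray  # H x W bool
    boundary_map: np.ndarray  # H x W bool
    nuclei: list[Ellipse]
    hema_density: np.ndarray  # H x W float, rendering ground truth
    eosin_density: np.ndarray  # H x W float


def _rasterize(shape, ell: Ellipse) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel indices inside the ellipse, restricted to a bounding box."""
    h, w = shape
    cy, cx = ell.center
    r = ell.axes[0] + 1
    r0, r1 = max(int(cy - r), 0), min(int(cy + r) + 2, h)
    c0, c1 = max(int(cx - r), 0), min(int(cx + r) + 2, w)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    inside = ell.contains(rows, cols)
    return rows[inside], cols[inside], inside


def _place_nuclei(params: SceneParams, rng: np.random.Generator) -> list[Ellipse]:
    h, w = params.image_height, params.image_width
    n = int(rng.integers(params.n_nuclei_range[0], params.n_nuclei_range[1] + 1))
    nuclei: list[Ellipse] = []
    for _ in range(n):
        a = rng.uniform(*params.nucleus_radius_range)
        ecc = rng.uniform(*params.eccentricity_range)
        b = a * np.sqrt(1.0 - ecc**2)
        theta = rng.uniform(0, np.pi)
        truncate = rng.random() < params.border_truncation_prob
        may_overlap = rng.random() < params.overlap_fraction
        for _try in range(200):
            if truncate:
                cy = rng.uniform(-0.3 * a, h - 1 + 0.3 * a)
                cx = rng.uniform(-0.3 * a, w - 1 + 0.3 * a)
                # force contact with a border for a fraction of draws
                edge = rng.integers(0, 4)
                if edge == 0:
                    cy = rng.uniform(-0.3 * a, 0.5 * a)
                elif edge == 1:
                    cy = rng.uniform(h - 1 - 0.5 * a, h - 1 + 0.3 * a)
                elif edge == 2:
                    cx = rng.uniform(-0.3 * a, 0.5 * a)
                else:
                    cx = rng.uniform(w - 1 - 0.5 * a, w - 1 + 0.3 * a)
            else:
                cy = rng.uniform(a, h - 1 - a)
                cx = rng.uniform(a, w - 1 - a)
            ok = True
            for other in nuclei:
                d = np.hypot(cy - other.center[0], cx - other.center[1])
                if may_overlap:
                    # cap occlusion: centers at least 0.7 of the larger radius
                    # apart so earlier instances keep visible pixels
                    if d < 0.7 * max(a, other.axes[0]):
                        ok = False
                        break
                else:
                    if d < a + other.axes[0]:
                        ok = False
                        break
            if ok:
                nuclei.append(Ellipse((cy, cx), (a, b), theta))
                break
    return nuclei


def generate_scene(params: SceneParams) -> LabeledScene:
    """Render one scene; a pure function of ``params`` (including its seed)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    nuclei = _place_nuclei(params, rng)

    instance_map = np.zeros((h, w), dtype=np.int32)
    hema = np.zeros((h, w))
    eosin = np.zeros((h, w))
    for k, ell in enumerate(nuclei, start=1):
        # cytoplasm halo: scaled-up copy of the nucleus ellipse
        halo = Ellipse(ell.center, (ell.axes[0] * 2.2, ell.axes[1] * 2.2), ell.theta)
        hr, hc, _ = _rasterize((h, w), halo)
        eosin[hr, hc] = np.maximum(eosin[hr, hc], 0.35)
        hema[hr, hc] = np.maximum(hema[hr, hc], 0.03)
        rr, cc, _ = _rasterize((h, w), ell)
        instance_map[rr, cc] = k  # later-placed nuclei occlude earlier ones
        # hematoxylin dominates chromatin; eosin uptake under the nucleus is weak
        hema[rr, cc] = 1.0 + rng.normal(0.0, 0.1)
        eosin[rr, cc] = 0.05

    # impurity blobs: rendered, never labeled
    n_imp = int(rng.integers(params.impurity_count_range[0],
                             params.impurity_count_range[1] + 1))
    for _ in range(n_imp):
        r = rng.uniform(2.0, 10.0)
        cy, cx = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
        blob = Ellipse((cy, cx), (r, r * rng.uniform(0.6, 1.0)), rng.uniform(0, np.pi))
        rr, cc, _ = _rasterize((h, w), blob)
        hema[rr, cc] = np.maximum(hema[rr, cc], rng.uniform(0.3, 0.6))
        eosin[rr, cc] = np.maximum(eosin[rr, cc], rng.uniform(0.2, 0.5))

    basis = np.asarray(params.stain_basis, dtype=float)
    od = hema[..., None] * basis[0] + eosin[..., None] * basis[1]
    image = np.exp(-od)

    blur_sigma = rng.uniform(*params.blur_sigma_range)
    if blur_sigma > 0:
        for ch in range(3):
            image[..., ch] = gaussian_filter(image[..., ch], blur_sigma)
    noise_sigma = rng.uniform(*params.noise_sigma_range)
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    # drop labels occluded down to zero pixels, keeping ids dense
    labels = np.unique(instance_map)
    labels = labels[labels > 0]
    remap = np.zeros(int(instance_map.max()) + 1, dtype=np.int32)
    kept: list[Ellipse] = []
    for new_id, old_id in enumerate(labels, start=1):
        remap[old_id] = new_id
        kept.append(nuclei[old_id - 1])
    instance_map = remap[instance_map]

    from .preprocessing import make_boundary_map

    semantic = instance_map > 0
    boundary = make_boundary_map(instance_map, thickness=2)
    return LabeledScene(
        image=image,
        instance_map=instance_map,
        semantic_mask=semantic,
        boundary_map=boundary,
        nuclei=kept,
        hema_density=hema,
        eosin_density=eosin,
    )


def scene_seed(base_seed: int, index: int) -> int:
    """Deterministic per-scene seed derived from a dataset seed."""
    return (base_seed * 1_000_003 + index) % (2**31 - 1)


def generate_dataset(n_scenes: int, params: SceneParams, out_dir) -> dict:
    """Write ``n_scenes`` scenes and a JSON manifest; returns the manifest.

    Files per scene k: image_k.png (8-bit RGB), instance_k.tiff (16-bit
    labels), mask_k.png and boundary_k.png (8-bit binary).
    """
    from PIL import Image
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k in range(n_scenes):
        sp = SceneParams(**{**asdict(params), "stain_basis": params.stain_basis,
                            "seed": scene_seed(params.seed, k)})
        scene = generate_scene(sp)
        paths = {
            "image": out_dir / f"image_{k}.png",
            "instance": out_dir / f"instance_{k}.tiff",
            "mask": out_dir / f"mask_{k}.png",
            "boundary": out_dir / f"boundary_{k}.png",
        }
        try:
            Image.fromarray(
                (scene.image * 255).round().astype(np.uint8)
            ).save(paths["image"])
            tifffile.imwrite(paths["instance"],
                             scene.instance_map.astype(np.uint16))
            Image.fromarray(scene.semantic_mask.astype(np.uint8) * 255).save(
                paths["mask"])
            Image.fromarray(scene.boundary_map.astype(np.uint8) * 255).save(
                paths["boundary"])
        except OSError as exc:
            raise OSError(f"failed writing scene files under {out_dir}: {exc}") from exc
        entries.append({
            "index": k,
            "seed": sp.seed,
            **{key: str(p.name) for key, p in paths.items()},
        })
    manifest = {"n_scenes": n_scenes, "base_seed": params.seed, "scenes": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def dataset_checksum(out_dir) -> str:
    """SHA-256 over all files of a generated dataset (reproducibility probe)."""
    digest = hashlib.sha256()
    for p in sorted(Path(out_dir).iterdir()):
        if p.is_file():
            digest.update(p.name.encode())
            digest.update(p.read_bytes())
    return digest.hexdigest()
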