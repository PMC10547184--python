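"""Structure-preserving H&E stain separation and normalization.

An RGB image is mapped to optical density OD = -log((I + eps) / I0) and
factorized as OD ~ D @ B where B is a 2x3 non-negative stain color basis
(rows: hematoxylin, eosin) and D >= 0 are per-pixel stain densities.  The
factorization is a sparse non-negative matrix factorization: background
pixels (OD norm below a floor) are excluded and an L1 penalty on the density
maps pushes each pixel toward a single stain.  Normalization re-expresses the
source densities in a target image's basis after matching robust density
maxima, which recolors the image while leaving its structure untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import DictionaryLearning


@dataclass
class StainModel:
    """Fitted 2-stain model: unit-row color basis + robust density maxima."""

    basis: np.ndarray  # 2x3, rows unit-norm, hematoxylin first
    max_densities: np.ndarray  # per-stain 99th-percentile density

    def validate(self):
        if self.basis.shape != (2, 3) or np.any(self.basis < -1e-9):
            raise ValueError("basis must be a non-negative 2x3 matrix")
        norms = np.linalg.norm(self.basis, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("basis rows must be unit-normalized")
        if np.any(self.max_densities <= 0):
            raise ValueError("max_densities must be positive")


_OD_EPS = 1.0 / 255.0


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Optical density of an image in [0, 1] (I0 = 1, eps = 1/255)."""
    return -np.log((np.clip(image, 0.0, 1.0) + _OD_EPS) / (1.0 + _OD_EPS))


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(np.exp(-od) * (1.0 + _OD_EPS) - _OD_EPS, 0.0, 1.0)


def _order_hematoxylin_first(basis: np.ndarray, densities: np.ndarray):
    """Hematoxylin appears blue: its OD vector absorbs red most strongly."""
    if basis[0, 0] < basis[1, 0]:
        basis = basis[::-1].copy()
        densities = densities[:, ::-1].copy()
    return basis, densities


def fit_stain_model(image: np.ndarray, sparsity: float = 0.1,
                    od_floor: float = 0.15, max_pixels: int = 5000) -> StainModel:
    """Estimate the 2-stain basis of an H&E image by sparse NMF on OD pixels.

    The factorization is solved as non-negative dictionary learning (dictionary
    atoms constrained to the unit ball, L1-penalized non-negative codes), the
    usual formulation of sparse stain separation.  Deterministic: tissue pixels
    are subsampled on a fixed stride and the solver is seeded.
    """
    od = rgb_to_od(image).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) >= od_floor]
    if tissue.shape[0] < 0.01 * od.shape[0] or tissue.shape[0] < 2:
        raise ValueError("no stained tissue: image is (almost) entirely white")
    if tissue.shape[0] > max_pixels:
        step = tissue.shape[0] // max_pixels + 1
        tissue = tissue[::step]
    learner = DictionaryLearning(
        n_components=2,
        positive_code=True,
        positive_dict=True,
        fit_algorithm="cd",
        transform_algorithm="lasso_cd",
        alpha=sparsity,
        max_iter=100,
        tol=1e-8,
        random_state=0,
    )
    learner.fit(np.maximum(tissue, 0.0))
    basis = learner.components_
    norms = np.linalg.norm(basis, axis=1)
    if np.any(norms == 0):
        # one-stain image: replace the empty atom with a direction orthogonal
        # to the found stain inside the non-negative octant
        live = basis[norms > 0][0] / norms[norms > 0][0]
        spare = np.clip(np.array([1.0, 1.0, 1.0]) / np.sqrt(3) - live, 1e-3, None)
        basis = np.stack([live, spare / np.linalg.norm(spare)])
        norms = np.linalg.norm(basis, axis=1)
    basis = basis / norms[:, None]
    basis, _ = _order_hematoxylin_first(basis, np.zeros((1, 2)))
    # robust density maxima from the same least-squares transform used later
    densities = np.maximum(tissue @ np.linalg.pinv(basis), 0.0)
    max_d = np.percentile(densities, 99, axis=0)
    max_d = np.maximum(max_d, 1e-6)
    model = StainModel(basis=basis, max_densities=max_d)
    model.validate()
    return model


def stain_densities(image: np.ndarray, model: StainModel) -> np.ndarray:
    """Per-pixel density maps (H, W, 2) w.r.t. a fitted basis.

    Solved by unconstrained least squares against the 2x3 basis with negative
    densities clipped to zero — exact whenever the image lies in the basis cone.
    """
    od = rgb_to_od(image)
    pinv = np.linalg.pinv(model.basis)  # 3x2
    d = od @ pinv
    return np.maximum(d, 0.0)


def reconstruct(densities: np.ndarray, model: StainModel) -> np.ndarray:
    return od_to_rgb(densities @ model.basis)


def normalize_stains(source: np.ndarray, source_model: StainModel,
                     target_model: StainModel) -> np.ndarray:
    """Recolor ``source`` into the target stain appearance.

    Densities are rescaled so the source's robust maxima match the target's,
    then recombined with the target basis.
    """
    source_model.validate()
    target_model.validate()
    d = stain_densities(source, source_model)
    scale = target_model.max_densities / source_model.max_densities
    return reconstruct(d * scale, target_model)
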