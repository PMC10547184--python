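import warnings

import numpy as np
import pytest

from cunet.model import CUNet, EncoderConfig, CSFIConfig, ModelConfig, WcuConfig
from cunet.synthetic import SceneParams, generate_scene, scene_seed

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ModelConfig:
    """Narrow 7-level configuration small enough for CPU unit tests."""
    return ModelConfig(
        encoder=EncoderConfig(levels=7, base_channels=8, channel_cap=32),
        csfi=CSFIConfig(n_layers=3, fpn_channels=16),
        wcu=WcuConfig(kernel_extent=7),
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_model_cfg) -> CUNet:
    return CUNet(tiny_model_cfg)


@pytest.fixture(scope="session")
def small_scenes():
    """Four 64x64 labeled scenes used for overfitting and e2e checks."""
    scenes = []
    for k in range(4):
        params = SceneParams(
            image_height=64, image_width=64, n_nuclei_range=(3, 6),
            nucleus_radius_range=(5.0, 10.0), seed=scene_seed(7, k),
        )
        scenes.append(generate_scene(params))
    return scenes


@pytest.fixture(scope="session")
def clean_scene():
    """One noiseless, blur-free scene with known rendering ground truth."""
    params = SceneParams(
        image_height=256, image_width=256, n_nuclei_range=(12, 12),
        blur_sigma_range=(0.0, 0.0), noise_sigma_range=(0.0, 0.0),
        impurity_count_range=(0, 0), seed=3,
    )
    return generate_scene(params)


def angular_error_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosine = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))
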