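import numpy as np
import pytest

from fadefit import HyperCube, SceneConfig, SkewNormalParams, SpectralAxis


@pytest.fixture
def axis5():
    return SpectralAxis([500.0, 550.0, 600.0, 650.0, 700.0])


@pytest.fixture
def small_cube(axis5):
    rng = np.random.default_rng(0)
    data = rng.uniform(0.1, 0.9, size=(4, 4, 5))
    return HyperCube(data, axis5, "reflectance")


@pytest.fixture
def wool_shape():
    # undyed-wool emission: 580 nm centre, 95 nm width, erf asymmetry 550/10 nm
    return SkewNormalParams(A=1.0, lambda_max=580.0, sigma=95.0, p=550.0, s=10.0)


@pytest.fixture
def emission_grid():
    return np.arange(500.0, 801.0, 4.0)


@pytest.fixture
def noiseless_scene_config():
    return SceneConfig(shape=(32, 32), noise_sd=0.0, n_specular=5, seed=3)
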