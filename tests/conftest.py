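import logging

import numpy as np
import pytest

from cfidetect.synth import SceneParams, generate_sample

# silence the routine extrema-exhaustion notices in bulk runs
logging.getLogger("cfidetect.bemd").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_params() -> SceneParams:
    """Default scene scaled to 128 px for fast unit tests."""
    return SceneParams(seed=11).scaled(128)


@pytest.fixture(scope="session")
def clean_params() -> SceneParams:
    """Noise-free, vignetting-free scene at 128 px."""
    import dataclasses

    return dataclasses.replace(
        SceneParams(seed=23).scaled(128), noise_sd=0.0, vignetting_strength=0.0
    )


@pytest.fixture(scope="session")
def sample_label2(small_params):
    return generate_sample(small_params, 2, seed=321)


@pytest.fixture(scope="session")
def blob_features():
    """Two well-separated Gaussian classes in 8 dimensions (4 informative)."""
    rng = np.random.default_rng(42)
    n = 60
    X0 = rng.normal(0.0, 1.0, (n, 8))
    X1 = rng.normal(0.0, 1.0, (n, 8))
    X1[:, :4] += 4.0
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    return X, y
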