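import warnings

import numpy as np
import pytest

from lipidstack import SyntheticSpec, generate_stack


@pytest.fixture(scope="session")
def clean_sphere_stack():
    """Noiseless, bleed-free stack of 20 well-separated spheres with ground truth."""
    spec = SyntheticSpec(
        n_droplets=20,
        noise="none",
        z_bleed_sigma=0.0,
        aspect_range=(1.0, 1.0),
        min_separation=15.0,
        radius_median=18.0,
        radius_sigma_log=0.35,
        radius_clip=(10.0, 40.0),
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # placement must succeed completely
        stack, truth = generate_stack(spec)
    assert truth.n_droplets == 20
    return stack, truth


@pytest.fixture(scope="session")
def noisy_stack():
    """Default-condition stack: Gaussian noise sigma 5 (8-bit), axial bleed 8 um."""
    spec = SyntheticSpec(n_droplets=25, noise="gaussian", noise_sigma=5.0, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = generate_stack(spec)
    return stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
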