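import numpy as np
import pytest

from msanet import NetworkConfig, PhantomParams, generate_cohort, validate_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest legal architecture: 32-pixel inputs, 2-pixel deepest map."""
    return validate_config(NetworkConfig(
        input_size=32,
        stage_channels=[4, 4, 8, 8, 8],
        num_heads=2,
        patch_grid=2,
        pool_kernel=2,
        mlp_hidden=8,
        batch_size=4,
        max_epochs=3,
    ))


@pytest.fixture(scope="session")
def tiny_params():
    """Phantom settings matched to the tiny architecture."""
    return PhantomParams(image_size=32, lesion_radius=(3, 6),
                         slices_per_patient=(2, 4), lesions_per_slice=(1, 2),
                         seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return generate_cohort(10, tiny_params)
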