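import numpy as np
import pytest

from petmip import PhantomConfig, SplitSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_config():
    """Small, fast phantom: 16x12x12 voxels, 2 manufacturers."""
    from petmip.phantom import ManufacturerEffect

    return PhantomConfig(
        grid_shape=(16, 12, 12),
        voxel_mm=(12.0, 12.0, 12.0),
        manufacturer_effects=(
            ManufacturerEffect(gain=1.0, blur_sigma_mm=0.0, noise_cv=0.0),
            ManufacturerEffect(gain=1.2, blur_sigma_mm=6.0, noise_cv=0.1),
        ),
        minority_fraction=0.3,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """40 cases on a small grid; shared across read-only tests."""
    from petmip.phantom import ManufacturerEffect

    config = PhantomConfig(
        grid_shape=(16, 12, 12),
        voxel_mm=(12.0, 12.0, 12.0),
        manufacturer_effects=(
            ManufacturerEffect(1.0, 0.0, 0.0),
            ManufacturerEffect(1.1, 6.0, 0.05),
            ManufacturerEffect(1.2, 9.0, 0.1),
        ),
        minority_fraction=0.3,
    )
    spec = SplitSpec(dev_manufacturers=(0, 1), external_manufacturers=(2,))
    return generate_cohort(config, 40, spec, seed=7)
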