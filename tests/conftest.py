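import numpy as np
import pytest

from eitmap import SyntheticConfig, VoxelGrid


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid((16, 16, 8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_config(small_grid) -> SyntheticConfig:
    """A fast-to-generate group configuration for unit tests."""
    return SyntheticConfig(
        n_recordings=6,
        grid=small_grid,
        noise_fwhm_um=75.0,
        n_time_bins=3,
        seed=7,
    )
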