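import numpy as np
import pytest

import vegattrib as va


@pytest.fixture(scope="session")
def small_scene() -> va.SyntheticScene:
    """A 12x12 default-condition scene shared by read-only tests."""
    return va.generate_scene(va.SyntheticConfig(n_rows=12, n_cols=12, seed=3))


@pytest.fixture(scope="session")
def quiet_climate_config() -> va.SyntheticConfig:
    """Climate with no interannual noise: pure seasonal cycle + trend."""
    return va.SyntheticConfig(
        n_rows=6, n_cols=6, seed=0,
        pre_noise_sd=0.0, tem_noise_sd=0.0, pet_noise_sd=0.0, noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_ndvi_config() -> va.SyntheticConfig:
    """Noise-free NDVI (and no human trend) over a variable climate, so the
    greenness field is an exact linear function of PRE and PET."""
    return va.SyntheticConfig(
        n_rows=6, n_cols=6, seed=0, noise_sd=0.0, human_trend_map={},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
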