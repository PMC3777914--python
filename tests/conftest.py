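import numpy as np
import pytest

from tumorresp.synth import SyntheticConfig


@pytest.fixture
def noise_free_config() -> SyntheticConfig:
    """Generating conditions with every noise source switched off."""
    from tumorresp.synth import InVivoConfig

    return SyntheticConfig(
        seed=7,
        viability_noise_cv=0.0,
        mvd_noise_cv=0.0,
        in_vivo=InVivoConfig(signal_noise_cv=0.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
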