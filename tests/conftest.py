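import numpy as np
import pytest

from citrusann.dataset import RESPONSE_COLUMNS, encode_features, load_citrus_table
from citrusann.synthetic import SurfaceConfig


@pytest.fixture(scope="session")
def citrus():
    return load_citrus_table()


@pytest.fixture(scope="session")
def encoded(citrus):
    return encode_features(citrus)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def noiseless_config(**kwargs) -> SurfaceConfig:
    """SurfaceConfig with all noise switched off (shared test helper)."""
    kwargs.setdefault("noise_sd", {k: 0.0 for k in RESPONSE_COLUMNS})
    return SurfaceConfig(**kwargs)
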