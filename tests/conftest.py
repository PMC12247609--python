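import numpy as np
import pytest

import reidsim as rs


@pytest.fixture(scope="session")
def small_gallery() -> rs.FeatureMatrix:
    """A 157 x 1000 reference-scale gallery used by several tests."""
    return rs.generate_gallery(rs.PopulationConfig(157, 1000, seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
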