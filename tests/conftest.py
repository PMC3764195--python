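import numpy as np
import pytest

from cdgcycle import PopulationModelParams


@pytest.fixture
def default_params() -> PopulationModelParams:
    """Study-condition parameters with a smaller cell count for unit tests."""
    return PopulationModelParams(n_cells=5_000, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
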