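import numpy as np
import pytest

from exmtool.volume import LabelVolume, generate_ground_truth


@pytest.fixture(scope="session")
def small_gt() -> LabelVolume:
    """A 64^3 dense synthetic neuropil volume shared across tests."""
    return generate_ground_truth(
        (64, 64, 64), 6.0, dict(count=5, radius_range=(40.0, 150.0)), seed=7
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
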