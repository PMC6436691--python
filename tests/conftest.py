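import numpy as np
import pytest

from lamglm.benchmark import Scenario, simulate_ground_truth


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced fold that keeps every pipeline stage fast in unit tests."""
    return Scenario(
        n_columns=128,
        amplitude=2.0,
        wavelength=12.0,
        margin=1.0,
        grid_shape=(48, 48, 8),
        subsamples=4,
    )


@pytest.fixture(scope="session")
def small_gt(small_scenario):
    return simulate_ground_truth(small_scenario)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on
    # which other tests ran before
    return np.random.default_rng(2026)
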