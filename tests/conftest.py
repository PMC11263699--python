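import numpy as np
import pytest

from quasisync import ModelParams, SingleSpeciesParams


@pytest.fixture(scope="session")
def s05() -> ModelParams:
    """Fast-damping designed preset (b = 1)."""
    return ModelParams.preset("S0.5")


@pytest.fixture(scope="session")
def s02() -> ModelParams:
    return ModelParams.preset("S0.2")


@pytest.fixture(scope="session")
def s01() -> ModelParams:
    return ModelParams.preset("S0.1")


@pytest.fixture(scope="session")
def oscillatory_sets() -> list[tuple[float, float, float, float]]:
    """A pool of random parameter sets in the oscillatory coexistence
    regime, produced by the Monte-Carlo screen with a fixed seed."""
    from quasisync import sample_oscillatory_params

    sets = sample_oscillatory_params(1_000_000, rng_seed=2024)
    assert len(sets) >= 100, "screen acceptance collapsed"
    return sets[:100]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
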