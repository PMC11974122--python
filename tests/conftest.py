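import numpy as np
import pytest

from layersim.engine import load_scenario, make_base, run_scenario
from layersim.genome import build_genetic_map, sample_founders
from layersim.traits import TraitParams


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def params():
    return TraitParams()


@pytest.fixture(scope="session")
def small_map():
    return build_genetic_map(2, 60, 1.0, np.random.default_rng(7))


@pytest.fixture
def founder_pool(small_map, rng):
    return sample_founders(small_map, 5, 10, rng)


@pytest.fixture(scope="session")
def tiny_base():
    """Scaled-down base population shared by engine-level tests."""
    return make_base(seed=11, scale=0.05)


@pytest.fixture(scope="session")
def tiny_run(tiny_base):
    """Five cycles of the reference program (pedigree males, phenotypic
    females) at desk scale, with the scheduler state retained."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scenario(load_scenario(1), base=tiny_base, seed=11,
                            horizon_weeks=315.0, keep_state=True)
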