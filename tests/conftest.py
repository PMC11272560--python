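import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tdabreak.breaktest import hfd_break_test
from tdabreak.persistence import FiltrationParams, tv_total_persistence
from tdabreak.signals import build_scenario

# master seed for the suite's deterministic replicate streams
SUITE_SEED = 7


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def example1():
    """The five-epoch Gaussian/circle/Gaussian/sphere/Gaussian scenario."""
    signal, preset = build_scenario("example1", rng=np.random.default_rng(SUITE_SEED))
    return signal, preset


@pytest.fixture(scope="session")
def example1_curves(example1):
    """Total-persistence curves of the example1 scenario (300 windows)."""
    signal, preset = example1
    return tv_total_persistence(
        signal, preset.window_config, FiltrationParams(max_homology_dim=2)
    )


@pytest.fixture(scope="session")
def example1_tests(example1_curves):
    """Break tests per homology dimension on the example1 TP curves."""
    streams = np.random.default_rng(SUITE_SEED).spawn(3)
    return {
        k: hfd_break_test(example1_curves[k], n_permutations=999, rng=streams[k])
        for k in (0, 1, 2)
    }
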