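import numpy as np
import pytest

from tonepred.sequences import BlockDesign
from tonepred.simulate import (
    SimulationParams,
    make_kernel,
    make_topographies,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_design():
    # 160 events, 16 omissions (4 per class): smallest design used in tests
    return BlockDesign(n_stimuli=160, omission_rate=0.10)


@pytest.fixture(scope="session")
def small_cohort(tiny_design):
    """Three subjects at miniature scale with all effects on."""
    return simulate_cohort(n_subjects=3, n_sensors=16, design=tiny_design,
                           seed=11)


@pytest.fixture(scope="session")
def noiseless_params():
    return SimulationParams(anticipation_gain=0.0, omission_gain=0.0,
                            entropy_signature_gain=0.0, noise_sd=0.0,
                            amplitude_jitter_sd=0.0)


@pytest.fixture(scope="session")
def topo16():
    return make_topographies(16, 0.3, seed=2)


@pytest.fixture(scope="session")
def kernel():
    return make_kernel()


@pytest.fixture
def rng():
    return np.random.default_rng(123)
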