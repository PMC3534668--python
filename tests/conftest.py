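import numpy as np
import pytest

from stemnet import synth
from stemnet.simulate import EnsembleConfig, SimulationConfig, simulate_ensemble

#: one fixed seed for all deterministic test randomness
SEED = 20130


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def synth_tables():
    """Default synthetic corpus: 2,000 studies, policy-independent null."""
    return synth.generate_usage_table(synth.SynthConfig(seed=SEED))


@pytest.fixture(scope="session")
def small_ensemble():
    """20 replicates at the reference parameters, for cheap unit checks."""
    return simulate_ensemble(
        EnsembleConfig(n_replicates=20, base=SimulationConfig(), seed=SEED)
    )
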