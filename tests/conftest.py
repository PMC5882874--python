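import numpy as np
import pytest

from riboreg.aptamer_search import build_profile
from riboreg.synthetic_data import SimConfig, make_seed_alignment, simulate


@pytest.fixture(scope="session")
def sim_small():
    """Small ground-truth simulation shared across tests (4 per type + 4 decoys)."""
    return simulate(SimConfig(seed=7, n_per_type=4, n_decoys=4))


@pytest.fixture(scope="session")
def profile(sim_small):
    return build_profile([s for _, s in sim_small.seed_alignment])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna_str(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
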