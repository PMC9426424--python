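import numpy as np
import pytest

from aquiferpop.synthetic_community import SimConfig, TruthSpec, generate_community
from aquiferpop.tables_io import RunConfig


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def two_strain_bundle():
    """Small deterministic two-strain community reused across tests."""
    sim = SimConfig(genome_length=6000, n_genes=6, coverage=100.0, seed=7)
    spec = TruthSpec(
        n_strains=2,
        fractions=[[0.7, 0.3], [0.4, 0.6]],
        snv_density=10.0,
        recomb_rate=0.0,
    )
    return generate_community(sim, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
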