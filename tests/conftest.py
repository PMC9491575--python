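import numpy as np
import pytest

from tpll_subtyper.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The package's reference synthetic cohort (2,000 genes, 10/18/11/39)."""
    return generate_cohort(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for expensive stages (network, pipeline)."""
    cfg = SimulationConfig(n_genes=400, shared_fraction=0.05,
                           close_fraction=0.1, specific_fraction=0.03)
    return generate_cohort(cfg, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
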