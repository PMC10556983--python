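import numpy as np
import pytest

import qpt
from qpt.genio import PRESETS


@pytest.fixture(scope="session")
def sim_config():
    return qpt.SimConfig(n_loci=2000, seed=11)


@pytest.fixture(scope="session")
def genotypes(sim_config):
    return qpt.simulate_genotypes(sim_config)


@pytest.fixture(scope="session")
def eigen(genotypes):
    panel, _ = qpt.filter_sites(genotypes, **PRESETS["neutral-panel"])
    K = qpt.standardized_kinship(panel)
    eig = qpt.conditional_eigen(K, samples=genotypes.samples,
                                provenance=panel.provenance)
    qpt.pc_sets(eig)
    return eig


@pytest.fixture(scope="session")
def neutral_traits(eigen):
    """1,000 neutral traits with va_true = 1."""
    return qpt.simulate_traits(eigen, qpt.TraitTruth(va_true=1.0), 1000,
                               seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
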