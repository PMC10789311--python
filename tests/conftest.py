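import numpy as np
import pytest

import mlgscan as m
from mlgscan.ehh import ExtensionPolicy
from mlgscan.statistics import ScanConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def example_genotypes():
    """Two-site, six-individual matrix used throughout the worked examples."""
    return m.GenotypeMatrix(np.array([[2, 2, 2, 0, 0, 1], [2, 2, 0, 0, 0, 1]]))


def random_genotype_matrix(rng, n_sites=None, n_ind=None):
    n_sites = n_sites or int(rng.integers(3, 51))
    n_ind = n_ind or int(rng.integers(2, 21))
    return m.GenotypeMatrix(rng.integers(0, 3, size=(n_sites, n_ind)))


@pytest.fixture(scope="session")
def small_fixture():
    """One small diploid sample with sites: (haps, genotypes, site table)."""
    params = m.SimulationParameters(L=50_000, n_hap=40, theta_like=47, rho_like=24, seed=7)
    haps, sites = m.simulate_neutral(params)
    return haps, m.collapse_to_genotypes(haps), sites


@pytest.fixture
def nsl_config():
    return ScanConfig(statistic="nsl", unphased=True, policy=ExtensionPolicy(trunc_ok=True))
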