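import numpy as np
import pytest

from strainsfs.demography import DemographicModel
from strainsfs.dfe import DFEModel, SpectraCache
from strainsfs.synthetic import SimScenario, random_coalescent_tree


@pytest.fixture(scope="session")
def one_epoch():
    return DemographicModel([1.0], [])


@pytest.fixture(scope="session")
def bottleneck():
    return DemographicModel([1.0, 0.1], [0.05])


@pytest.fixture(scope="session")
def eq_cache_n14(one_epoch):
    """Selected-spectra cache for the equilibrium demography, shared
    across tests (read-only)."""
    return SpectraCache(one_epoch, 14)


@pytest.fixture(scope="session")
def tree30():
    return random_coalescent_tree(30, seed=42)


def make_scenario(**kw):
    defaults = dict(
        n_hosts=16,
        n_haplotypes_target=14,
        genome_length=5000,
        frac_synonymous=0.3,
        demography=DemographicModel([1.0], []),
        dfe=None,
        theta_s=50.0,
        depth_mean=50.0,
        depth_sd=0.0,
        strain_major_fraction=1.0,
        seed=0,
    )
    defaults.update(kw)
    return SimScenario(**defaults)


@pytest.fixture
def scenario_factory():
    return make_scenario
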