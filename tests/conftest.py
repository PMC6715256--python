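import numpy as np
import pytest

from mshtc import (EstimationParams, GeneticMap, HaplotypeMatrix,
                   records_from_matrix, simulate_sample)


@pytest.fixture(scope="session")
def small_sim():
    """Constant-N sample small enough for exhaustive checks."""
    return simulate_sample(demography="constant", n=40, L_bp=500_000,
                           mu=1e-8, rho=1e-8, seed=11)


@pytest.fixture(scope="session")
def norec_sim():
    """Recombination-free sample with many singletons (x_AS checks)."""
    return simulate_sample(demography="constant", n=100, L_bp=3_000_000,
                           mu=1e-8, rho=0.0, seed=7)


@pytest.fixture()
def uniform_params():
    return EstimationParams(mu=1e-8, gmap=GeneticMap.uniform(1e-8),
                            n=40, N0=1e4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_matrix(alleles, positions=None, **kw):
    alleles = np.asarray(alleles, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1) * 10
    return HaplotypeMatrix(alleles=alleles, positions=positions, **kw)


@pytest.fixture()
def matrix_factory():
    return make_matrix


@pytest.fixture()
def records_factory():
    return records_from_matrix
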