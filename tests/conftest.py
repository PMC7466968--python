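import numpy as np
import pytest

from erpower import (
    ArchitectureConfig,
    BurninParams,
    HaplotypePopulation,
    assign_qtl,
    run_burnin,
)
from erpower.config import FullConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_pop():
    """4 haplotypes (2 diploids), 3 sites, L=100."""
    haps = np.array(
        [
            [1, 0, 1],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 0],
        ],
        dtype=np.uint8,
    )
    return HaplotypePopulation(L=100, positions=[10, 40, 70], haplotypes=haps)


@pytest.fixture(scope="session")
def small_burnin():
    """Reduced-scale equilibrium population shared across tests."""
    return run_burnin(BurninParams(N=200, L=2_000_000, mu=2e-7, r=1.0, seed=11))


@pytest.fixture(scope="session")
def small_arch(small_burnin):
    return assign_qtl(
        small_burnin, ArchitectureConfig(n_qtl=20, seed=5)
    )


def reduced_config(**kw):
    """Scaled-down standard model for fast multi-replicate tests."""
    defaults = dict(
        N=200, L=2_000_000, mu=2e-7, r=1.0,
        n_qtl=20, N_per_line=200, sample_size=50, seed=33,
    )
    defaults.update(kw)
    return FullConfig(**defaults)
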