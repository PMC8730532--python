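import numpy as np
import pytest

from herimap.grm import compute_grm, make_covariates
from herimap.synthetic import SimulationDesign, simulate_genotypes


@pytest.fixture(scope="session")
def family_design():
    """Small family-block design: 10 blocks of 8, 500 variants."""
    return SimulationDesign(n_samples=80, n_variants=500, n_family_blocks=10,
                            family_block_size=8, seed=42)


@pytest.fixture(scope="session")
def family_genotypes(family_design):
    from herimap.genotypes import qc_filter

    return qc_filter(simulate_genotypes(family_design))[0]


@pytest.fixture(scope="session")
def family_grm(family_genotypes):
    return compute_grm(family_genotypes)


@pytest.fixture(scope="session")
def family_sqrt(family_grm):
    """Matrix square root of the family GRM for drawing genetic values."""
    evals, evecs = np.linalg.eigh(family_grm.values)
    return evecs * np.sqrt(np.clip(evals, 0, None))


@pytest.fixture()
def intercept_only(family_grm):
    return make_covariates(None, None, n_samples=family_grm.n_samples)
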