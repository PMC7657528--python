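import numpy as np
import pytest

from fcmsku import CovariateMatrix, GenotypeMatrix, simulate_covariates, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genotypes():
    """Hand-written 6 x 4 genotype matrix."""
    values = np.array(
        [
            [0, 1, 2, 0],
            [1, 0, 1, 1],
            [2, 1, 0, 0],
            [0, 2, 1, 1],
            [1, 1, 0, 2],
            [2, 0, 2, 0],
        ]
    )
    return GenotypeMatrix(
        values=values,
        snp_ids=[f"rs{j}" for j in range(1, 5)],
        sample_ids=[f"id{i}" for i in range(1, 7)],
    )


@pytest.fixture
def medium_dataset():
    """n = 120 simulated genotypes with matching covariates."""
    geno = simulate_genotypes(120, 30, seed=7)
    covar = simulate_covariates(120, seed=8)
    return geno, covar
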