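import numpy as np
import pytest

from sparselmm.geno_io import (
    GenotypeMatrix,
    PhenotypeVector,
    compute_kinship,
    impute_and_center,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geno(rng):
    """Centered 40 x 30 genotype matrix with non-trivial allele frequencies."""
    raw = rng.integers(0, 3, size=(40, 30)).astype(float)
    g = GenotypeMatrix(raw, [f"m{j}" for j in range(30)])
    return impute_and_center(g)


@pytest.fixture
def small_kinship(small_geno):
    return compute_kinship(small_geno)


@pytest.fixture
def small_pheno(rng, small_geno):
    beta = np.zeros(small_geno.p)
    beta[[1, 5]] = [1.0, -0.8]
    y = small_geno.dosages @ beta + rng.standard_normal(small_geno.n)
    return PhenotypeVector(values=y)
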