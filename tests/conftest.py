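import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msatpop as mp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_matrix(
    rng: np.random.Generator,
    n_pops: int = 3,
    n_per_pop: int = 5,
    n_loci: int = 3,
    n_alleles: int = 4,
    missing_rate: float = 0.0,
) -> mp.GenotypeMatrix:
    """A random genotype matrix with allele sizes in a small integer range."""
    n = n_pops * n_per_pop
    calls = rng.integers(1, n_alleles + 1, size=(n, n_loci, 2)).astype(np.int32)
    if missing_rate > 0:
        miss = rng.random((n, n_loci)) < missing_rate
        calls[miss] = mp.MISSING
    return mp.GenotypeMatrix(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        pop_labels=[f"Pop{i // n_per_pop + 1}" for i in range(n)],
        loci=[f"L{l+1}" for l in range(n_loci)],
        calls=calls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_bundle():
    """One study-shaped synthetic bundle shared across tests."""
    from msatpop.synthetic import make_study_like

    return make_study_like(seed=7, scale=0.25)
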