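import numpy as np
import pytest

import crossbred as cb


@pytest.fixture(scope="session")
def breeds4():
    return cb.BreedSet(("D", "H", "L", "W"))


@pytest.fixture(scope="session")
def breeds5():
    return cb.BreedSet(("D", "H", "L", "P", "W"))


@pytest.fixture(scope="session")
def rmap_small():
    """Six pig-like autosomes, uniform 1 cM/Mb."""
    return cb.default_pig_like_map(6)


@pytest.fixture(scope="session")
def small_pool(breeds4, rmap_small):
    """Well-differentiated founder pool at unit-test scale (p=400), with the
    unbalanced design (one breed at n=14)."""
    freqs = cb.sample_breed_freqs(400, breeds4, fst=0.2, seed=101)
    return cb.sample_founders(freqs, [60, 14, 60, 60], rmap_small, seed=102)


@pytest.fixture(scope="session")
def fitted_small(small_pool, breeds4):
    geno = small_pool.genotypes()
    return cb.CrossbredQDA(geno, geno.labels, breeds4, alpha0=80.0).fit()


@pytest.fixture(scope="session")
def small_testset(small_pool, breeds4):
    combos = cb.enumerate_combinations(breeds4)
    rng = np.random.default_rng(103)
    return cb.simulate_testset(small_pool, combos, 4, breeds4, rng)
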