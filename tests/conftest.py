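import numpy as np
import pytest

import morphopop as mp


@pytest.fixture(scope="session")
def island_genotypes():
    """Balding–Nichols genotypes at study-like conditions (smaller locus count)."""
    g, pm, truth = mp.simulate_genotypes(12, 15, 500, 0.118, seed=11)
    return g, pm, truth


@pytest.fixture(scope="session")
def small_landmark_set():
    """8 populations × 12 specimens with planted sigma2_B=2, sigma2_W=1."""
    configs, truth = mp.simulate_landmarks(8, 12, 2.0, 1.0, seed=21)
    return configs, truth


@pytest.fixture(scope="session")
def aligned_small(small_landmark_set):
    configs, _ = small_landmark_set
    return mp.gpa_align(configs, slide=True)


@pytest.fixture(scope="session")
def haplotype_sample():
    """60 sequences, 15 unique haplotypes, 42 segregating sites."""
    seqs, truth = mp.simulate_haplotypes(60, 612, 42, seed=31)
    return seqs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
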