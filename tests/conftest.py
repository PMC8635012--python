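import numpy as np

import pytest

from gradsel.genodata import GenotypeMatrix, MarkerMap
from gradsel.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_map():
    return MarkerMap(
        marker_id=np.array(["m1", "m2", "m3"], dtype=object),
        chrom=np.array(["1", "1", "1"], dtype=object),
        pos=np.array([1000, 2000, 3000]),
        allele_a=np.array(["A", "C", "G"], dtype=object),
        allele_b=np.array(["T", "G", "A"], dtype=object),
    )


@pytest.fixture
def tiny_genotypes(tiny_map):
    # 2 samples x 3 markers, one missing cell
    values = np.array([[0, 1, 2], [2, -1, 0]], dtype=np.int8)
    return GenotypeMatrix(["s1", "s2"], values), tiny_map


@pytest.fixture(scope="session")
def sim_cohort():
    """One 240-individual cohort with a strong single QTL, shared by tests."""
    cfg = SimConfig(n_individuals=240, n_snps=400, chrom_length=24_000_000, seed=7,
                    qtls=((200, 1.5, (0,)),))
    H, M, P = simulate_cohort(cfg)
    return cfg, H, M, P
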