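import numpy as np
import pytest

from noiasim.genome import GenomeMap, Population, random_pairs, sample_base_le, uniform_genome


@pytest.fixture
def small_genome():
    """60 QTL on one 100-cM chromosome, 30 epistatic pairs."""
    g = uniform_genome(1, 100.0, 60, seed=7)
    g.qtl_index = np.arange(60)
    g.pair_list = random_pairs(60, 30, seed=7)
    return g


@pytest.fixture
def small_base(small_genome):
    return sample_base_le(200, small_genome, 0.1, 0.9, seed=7)


@pytest.fixture
def two_locus_genome():
    g = GenomeMap(chromosomes=[(0, 100.0)], loci_chrom=[0, 0], loci_pos=[10.0, 20.0],
                  qtl_index=np.array([0, 1]), pair_list=np.array([[0, 1]]))
    return g


def hwe_population(q, n, L, seed):
    """Population of n individuals at HWE with per-locus frequency q."""
    rng = np.random.default_rng(seed)
    q = np.broadcast_to(np.asarray(q, float), (L,))
    haps = (rng.random((n, 2, L)) < q[None, None, :]).astype(np.uint8)
    return Population.from_haplotypes(haps)


@pytest.fixture
def hwe_pop_factory():
    return hwe_population
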