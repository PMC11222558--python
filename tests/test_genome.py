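"""Base sampling, meiosis, selfing, breeding schemes."""

import numpy as np
import pytest

from noiasim.genome import (
    GenomeMap,
    InvalidConfiguration,
    Population,
    ThreeWayConfig,
    allele_frequencies,
    genotype_frequencies,
    mate,
    meiosis,
    random_pairs,
    run_ipg_scheme,
    run_threeway_scheme,
    sample_base_le,
    self_pollinate,
    simulate_ld_base,
    uniform_genome,
    _gametes,
)
from noiasim._rng import child_rng


class TestBaseLE:
    def test_shape_and_frequency_bounds(self, small_genome):
        pop = sample_base_le(100, small_genome, 0.05, 0.95, seed=1)
        assert pop.dosage.shape == (100, 60)
        assert set(np.unique(pop.dosage)) <= {0, 1, 2}

    def test_degenerate_uniform_hits_half(self, small_genome):
        pop = sample_base_le(4000, small_genome, 0.5, 0.5, seed=2)
        q = allele_frequencies(pop)
        # binomial SE at q=0.5 with 8000 draws
        assert np.all(np.abs(q - 0.5) < 4 * np.sqrt(0.25 / 8000))

    def test_empirical_frequency_matches_binomial_oracle(self, small_genome):
        n = 10000
        pop = sample_base_le(n, small_genome, 0.3, 0.3, seed=3)
        q = allele_frequencies(pop)
        se = np.sqrt(0.3 * 0.7 / (2 * n))
        assert np.all(np.abs(q - 0.3) < 4 * se)

    def test_loci_uncorrelated_in_le(self, small_genome):
        pop = sample_base_le(3000, small_genome, 0.4, 0.6, seed=4)
        d = pop.dosage.astype(float)
        c = np.corrcoef(d[:, :12].T)
        off = c[np.triu_indices(12, 1)]
        assert np.max(np.abs(off)) < 4 / np.sqrt(3000)

    @pytest.mark.parametrize("n,low,high", [(1, 0.1, 0.9), (10, 0.0, 0.9), (10, 0.5, 0.2)])
    def test_invalid_configuration(self, small_genome, n, low, high):
        with pytest.raises(InvalidConfiguration):
            sample_base_le(n, small_genome, low, high, seed=0)


class TestMeiosis:
    def test_homozygous_parent_gamete_identity(self, small_genome):
        hap = np.ones((2, 60), dtype=np.uint8)
        g = meiosis(hap, small_genome, seed=0)
        assert np.array_equal(g, hap[0])

    def test_haldane_recombinant_fraction(self, two_locus_genome):
        # doubly heterozygous parent in coupling, loci 10 cM apart
        parent = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        haps = np.broadcast_to(parent, (100_000, 2, 2)).copy()
        rng = child_rng(5, "test-haldane")
        gam = _gametes(haps, two_locus_genome.recombination_fractions(), rng)
        rec = np.mean(gam[:, 0] != gam[:, 1])
        expected = 0.5 * (1 - np.exp(-0.2))  # 0.0906
        assert abs(rec - expected) < 4 * np.sqrt(expected * (1 - expected) / 100_000)

    def test_le_mode_mendelian_segregation(self, two_locus_genome):
        parent = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        haps = np.broadcast_to(parent, (100_000, 2, 2)).copy()
        rng = child_rng(6, "test-le")
        gam = _gametes(haps, np.array([0.5]), rng)
        assert abs(gam[:, 0].mean() - 0.5) < 4 * np.sqrt(0.25 / 100_000)
        # loci transmitted independently in LE mode
        corr = np.corrcoef(gam[:, 0], gam[:, 1])[0, 1]
        assert abs(corr) < 4 / np.sqrt(100_000)


class TestMating:
    def test_opposite_homozygotes_give_heterozygotes(self, small_genome):
        haps = np.zeros((2, 2, 60), dtype=np.uint8)
        haps[1] = 1
        pop = Population.from_haplotypes(haps)
        off = mate(pop, np.zeros(20, int), np.ones(20, int), small_genome, mode="le", seed=1)
        assert np.all(off.dosage == 1)

    def test_offspring_mean_is_midparent(self, small_genome):
        base = sample_base_le(2, small_genome, 0.2, 0.8, seed=9)
        mid = base.dosage.mean(axis=0)
        off = mate(base, np.zeros(4000, int), np.ones(4000, int), small_genome, mode="le", seed=2)
        se = np.sqrt(0.5 / 4000) * 2
        assert np.all(np.abs(off.dosage.mean(axis=0) - mid) < 6 * se + 0.05)

    def test_selfing_rejected_in_mate(self, small_base, small_genome):
        with pytest.raises(InvalidConfiguration):
            mate(small_base, np.array([0]), np.array([0]), small_genome, mode="le")

    def test_no_mutation_alleles_from_parents(self, small_genome):
        base = sample_base_le(2, small_genome, 0.3, 0.7, seed=10)
        off = mate(base, np.zeros(50, int), np.ones(50, int), small_genome, mode="le", seed=3)
        for j in range(60):
            parental = set(base.haplotypes[:, :, j].ravel())
            assert set(off.haplotypes[:, :, j].ravel()) <= parental


class TestSelfing:
    def test_pedigree_expected_inbreeding_closed_form(self):
        # 1 - (1/2)^t for a non-inbred founder
        assert 1 - 0.5**4 == pytest.approx(0.9375)
        assert round(1 - 0.5**4, 3) == 0.938
        assert 1 - 0.5**1 == pytest.approx(0.5)

    def test_realized_heterozygosity_markov_oracle(self, small_genome, hwe_pop_factory):
        # per-locus Markov chain: P(still het after t selfings) = (1/2)^t
        founders = hwe_pop_factory(0.5, 300, 60, seed=11)
        het0 = founders.dosage == 1
        lines = self_pollinate(founders.haplotypes, small_genome, 4, mode="le", seed=12)
        het4 = Population.from_haplotypes(lines).dosage == 1
        frac = het4[het0].mean()
        n_het = het0.sum()
        assert abs(frac - 0.0625) < 4 * np.sqrt(0.0625 * 0.9375 / n_het)


class TestWrightFisher:
    def test_zero_history_exact_half(self):
        g = uniform_genome(2, 50.0, 100, seed=13)
        pop, _ = simulate_ld_base(40, g, historical_generations=0, historical_n=50,
                                  maf_min=0.05, seed=13)
        assert pop.dosage.shape == (40, 200)
        assert np.all(allele_frequencies(pop) == 0.5)

    def test_founders_start_at_exactly_half(self):
        from noiasim.genome import _founder_haplotypes
        rng = child_rng(0, "t")
        haps = _founder_haplotypes(30, 50, rng)
        assert np.all(haps.sum(axis=(0, 1)) == 30)

    def test_ld_decay_with_map_distance(self):
        # linked loci keep higher r^2 than unlinked loci after drift
        g = GenomeMap(chromosomes=[(0, 200.0), (1, 200.0)],
                      loci_chrom=[0, 0, 1], loci_pos=[50.0, 50.0 + 1e-6, 50.0],
                      qtl_index=np.arange(3))
        r2_near, r2_far = [], []
        for rep in range(25):
            pop, _ = simulate_ld_base(60, g, historical_generations=40, historical_n=40,
                                      maf_min=0.05, seed=100 + rep)
            d = pop.dosage.astype(float)
            if d[:, 0].std() > 0 and d[:, 1].std() > 0 and d[:, 2].std() > 0:
                r2_near.append(np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2)
                r2_far.append(np.corrcoef(d[:, 0], d[:, 2])[0, 1] ** 2)
        assert np.mean(r2_near) > np.mean(r2_far)

    def test_retained_qtl_respect_maf_filter(self):
        g = uniform_genome(5, 100.0, 1000, seed=14)
        pop, g2 = simulate_ld_base(100, g, historical_generations=200, historical_n=200,
                                   maf_min=0.05, n_qtl=500, n_pairs=100, seed=14)
        q = allele_frequencies(pop)[g2.qtl_index]
        maf = np.minimum(q, 1 - q)
        assert maf.mean() >= 0.05
        assert g2.n_qtl == 500 and g2.n_pairs == 100


class TestIpgScheme:
    def test_descendant_count_default_design(self, small_genome):
        base = sample_base_le(100, small_genome, 0.1, 0.9, seed=15)
        pop = run_ipg_scheme(base, small_genome, 4, 150, 150, 5, mode="le", seed=15)
        assert (pop.generation >= 1).sum() == 3000
        assert pop.n == 3100

    def test_minimal_scheme_grows_by_one(self, small_genome):
        base = sample_base_le(10, small_genome, 0.1, 0.9, seed=16)
        pop = run_ipg_scheme(base, small_genome, 1, 2, 1, 1, mode="le", seed=16)
        assert pop.n == 11

    def test_neutral_drift_centered_on_zero(self, small_genome):
        deltas = []
        for rep in range(10):
            base = sample_base_le(100, small_genome, 0.3, 0.7, seed=30 + rep)
            pop = run_ipg_scheme(base, small_genome, 4, 150, 150, 5, mode="le", seed=30 + rep)
            q0 = allele_frequencies(pop, np.flatnonzero(pop.generation == 0))
            q4 = allele_frequencies(pop, np.flatnonzero(pop.generation == 4))
            deltas.append(np.mean(q4 - q0))
        # drift SD per locus ~ sqrt(q p t / 2N); the mean over 60 loci x 10 reps is tiny
        assert abs(np.mean(deltas)) < 3 * np.std(deltas, ddof=1) / np.sqrt(len(deltas)) + 1e-3

    def test_pedigree_parents_exist(self, small_genome):
        base = sample_base_le(20, small_genome, 0.1, 0.9, seed=17)
        pop = run_ipg_scheme(base, small_genome, 2, 10, 10, 2, mode="le", seed=17)
        off = pop.generation >= 1
        assert np.all(pop.sire[off] >= 0) and np.all(pop.dam[off] >= 0)
        assert np.all(pop.generation[pop.sire[off]] < pop.generation[off])


class TestThreeWayScheme:
    @pytest.fixture
    def inbred_bases(self, small_genome):
        b1 = sample_base_le(20, small_genome, 0.2, 0.8, seed=18)
        b2 = sample_base_le(20, small_genome, 0.2, 0.8, seed=19)
        h1 = self_pollinate(b1.haplotypes, small_genome, 4, mode="le", seed=20)
        h2 = self_pollinate(b2.haplotypes, small_genome, 4, mode="le", seed=21)
        return (Population.from_haplotypes(h1), Population.from_haplotypes(h2))

    def test_plot_counts_and_balance(self, small_genome, inbred_bases):
        b1, b2 = inbred_bases
        cfg = ThreeWayConfig(generations=4, n_lines1=20, n_lines2=10, seeds_per_cross=5,
                             plots_per_line1=5, plots_per_hybrid=10, n_base_plots=100,
                             mode="le")
        res = run_threeway_scheme(b1, b2, small_genome, cfg, seed=22)
        assert res.plots.n == 3 * 100  # generations 2-4, 20 lines x 5 plots
        for t in (2, 3, 4):
            sel = res.plots.generation == t
            counts = np.bincount(res.plots.i1[sel])
            assert np.all(counts[counts > 0] == 5)
        assert np.all(res.plots.i2a != res.plots.i2b)

    def test_insufficient_design_rejected(self, small_genome, inbred_bases):
        b1, b2 = inbred_bases
        cfg = ThreeWayConfig(n_lines1=20, n_lines2=10, plots_per_line1=5,
                             plots_per_hybrid=7, n_base_plots=100, mode="le")
        with pytest.raises(InvalidConfiguration):
            run_threeway_scheme(b1, b2, small_genome, cfg, seed=23)

    def test_twoway_dosage_is_grandparent_mean(self, small_genome, inbred_bases):
        from noiasim.variance import ppg_plot_arrays
        b1, b2 = inbred_bases
        cfg = ThreeWayConfig(generations=2, n_lines1=20, n_lines2=10, seeds_per_cross=5,
                             plots_per_line1=5, plots_per_hybrid=10, n_base_plots=100,
                             plot_generations=(2,), mode="le")
        res = run_threeway_scheme(b1, b2, small_genome, cfg, seed=24)
        t1, t2, t2a, t2b = ppg_plot_arrays(res.lines1, res.lines2, res.plots,
                                           small_genome.qtl_index)
        assert np.allclose(t2, 0.5 * (t2a + t2b))


class TestFrequencies:
    def test_all_bb_genotype(self, small_genome):
        pop = Population.from_haplotypes(np.zeros((5, 2, 60), dtype=np.uint8))
        q = allele_frequencies(pop)
        gf = genotype_frequencies(pop)
        assert np.all(q == 0) and np.all(gf[:, 0] == 1)

    def test_non_hwe_mixture(self):
        haps = np.zeros((10, 2, 4), dtype=np.uint8)
        haps[5:] = 1  # half BB, half bb
        pop = Population.from_haplotypes(haps)
        gf = genotype_frequencies(pop)
        assert np.allclose(allele_frequencies(pop), 0.5)
        assert np.allclose(gf[:, 1], 0.0)

    def test_hwe_heterozygosity(self, hwe_pop_factory):
        pop = hwe_pop_factory(0.5, 5000, 20, seed=25)
        gf = genotype_frequencies(pop)
        assert np.all(np.abs(gf[:, 1] - 0.5) < 4 * np.sqrt(0.25 / 5000))

    def test_empty_subset_errors(self, small_base):
        with pytest.raises(InvalidConfiguration):
            allele_frequencies(small_base, subset=np.array([], dtype=int))
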