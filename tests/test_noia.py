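"""Covariates, design matrices and functional <-> statistical transforms."""

import numpy as np
import pytest

from noiasim.noia import (
    Anchor,
    DegenerateAnchorError,
    T1_STATES,
    T2_STATES,
    build_W_ipg,
    build_W_ppg,
    epistasis_covariate,
    epistatic_additive_contribution,
    functional_to_statistical_ipg,
    h_covariates_freq,
    h_covariates_genofreq,
    h_d3,
    pair_transform_matrices_ppg,
    statistical_to_functional_ipg,
    t_covariates,
    t_d3,
)


class TestCovariates:
    @pytest.mark.parametrize("dosage,ta,td", [(0, -1, 0), (1, 0, 1), (2, 1, 0)])
    def test_t_covariates_coding(self, dosage, ta, td):
        a, d = t_covariates(dosage)
        assert (a, d) == (ta, td)

    def test_t_covariates_rejects_bad_dosage(self):
        with pytest.raises(ValueError):
            t_covariates(3)

    @pytest.mark.parametrize(
        "dosage,q,expected",
        [(1, 0.5, (0.0, 0.5)), (0, 0.3, (-0.6, -0.18)), (0, 0.0, (0.0, 0.0))],
    )
    def test_h_freq_examples(self, dosage, q, expected):
        assert h_covariates_freq(dosage, q) == pytest.approx(expected)

    def test_genofreq_equals_freq_under_hwe(self):
        q = 0.4
        p = 1 - q
        for dos in (0, 1, 2):
            ha1, hd1 = h_covariates_freq(dos, q)
            ha2, hd2 = h_covariates_genofreq(dos, p**2, 2 * p * q, q**2)
            assert ha1 == pytest.approx(ha2, abs=1e-12)
            assert hd1 == pytest.approx(hd2, abs=1e-12)

    def test_genofreq_no_heterozygotes(self):
        # p_BB = p_bb = 0.5, p_Bb = 0: numerators with p_Bb vanish
        for dos, expect_zero in ((0, True), (2, True)):
            _, hd = h_covariates_genofreq(dos, 0.5, 0.0, 0.5)
            assert (hd == 0) == expect_zero

    def test_genofreq_zero_denominator_flagged_zero(self):
        # all heterozygotes: denominator is zero, h_d defined as 0
        _, hd = h_covariates_genofreq(1, 0.0, 1.0, 0.0)
        assert hd == 0.0

    def test_h_a_centered_under_genotype_frequencies(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(3))
        ha = np.array([h_covariates_genofreq(d, *f)[0] for d in range(3)])
        assert float(f @ ha) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_orthogonality_of_h_covariates(self):
        # with genotype-frequency weights, cov(h_a, h_d) = 0 for any distribution
        rng = np.random.default_rng(1)
        for _ in range(50):
            f = rng.dirichlet(np.ones(3))
            ha = np.array([h_covariates_genofreq(d, *f)[0] for d in range(3)])
            hd = np.array([h_covariates_genofreq(d, *f)[1] for d in range(3)])
            assert float(f @ (ha * hd)) == pytest.approx(0.0, abs=1e-10)
            assert float(f @ hd) == pytest.approx(0.0, abs=1e-10)

    def test_epistasis_covariate_products(self):
        assert epistasis_covariate(-1, 1) == -1
        assert epistasis_covariate(0, 1) == 0
        assert epistasis_covariate(-1.0, -1.0) == 1.0


class TestDesignMatricesIPG:
    def test_dimensions_and_ones_column(self):
        anchor = Anchor.from_allele_frequencies(np.array([0.3, 0.6]))
        blk = build_W_ipg(anchor, 0, 1)
        assert blk.W_f.shape == (9, 6) and blk.W_s.shape == (9, 6)
        assert np.all(blk.W_f[:, 0] == 1) and np.all(blk.W_s[:, 0] == 1)

    def test_left_inverse_property(self):
        anchor = Anchor.from_allele_frequencies(np.array([0.2, 0.8]))
        W_s = build_W_ipg(anchor, 0, 1).W_s
        left = np.linalg.solve(W_s.T @ W_s, W_s.T)
        assert np.allclose(left @ W_s, np.eye(6), atol=1e-10)

    def test_frequency_matrix_cancellation(self):
        # transforms with and without a diagonal genotype-frequency weight agree
        rng = np.random.default_rng(2)
        for _ in range(20):
            q = rng.uniform(0.05, 0.95, 2)
            anchor = Anchor.from_allele_frequencies(q)
            blk = build_W_ipg(anchor, 0, 1)
            Ef = rng.normal(size=6)
            plain = functional_to_statistical_ipg(Ef, blk.W_f, blk.W_s)
            # joint genotype frequencies under HWE + LE, locus k fastest
            fk = np.array([(1 - q[0]) ** 2, 2 * q[0] * (1 - q[0]), q[0] ** 2])
            fl = np.array([(1 - q[1]) ** 2, 2 * q[1] * (1 - q[1]), q[1] ** 2])
            F = np.diag(np.kron(fl, fk))
            weighted = np.linalg.solve(blk.W_s.T @ F @ blk.W_s,
                                       blk.W_s.T @ F @ blk.W_f @ Ef)
            assert np.allclose(plain, weighted, atol=1e-10)

    def test_row_order_invariance(self):
        # any consistent joint-genotype row order yields the identical transform
        anchor = Anchor.from_allele_frequencies(np.array([0.35, 0.65]))
        blk = build_W_ipg(anchor, 0, 1)
        Ef = np.array([0.0, 1.0, -0.5, 0.3, 0.2, 0.7])
        base = functional_to_statistical_ipg(Ef, blk.W_f, blk.W_s)
        perm = np.random.default_rng(3).permutation(9)
        permuted = functional_to_statistical_ipg(Ef, blk.W_f[perm], blk.W_s[perm])
        assert np.allclose(base, permuted, atol=1e-10)

    def test_degenerate_anchor_raises(self):
        anchor = Anchor.from_allele_frequencies(np.array([0.0, 0.5]))
        with pytest.raises(DegenerateAnchorError):
            build_W_ipg(anchor, 0, 1)


class TestTransformsIPG:
    def test_pure_additive_passes_through(self):
        anchor = Anchor.from_allele_frequencies(np.array([0.17, 0.83]))
        blk = build_W_ipg(anchor, 0, 1)
        Es = functional_to_statistical_ipg([1, 2.0, -1.0, 0, 0, 0], blk.W_f, blk.W_s)
        assert Es[1] == pytest.approx(2.0, abs=1e-10)
        assert Es[2] == pytest.approx(-1.0, abs=1e-10)

    def test_alpha_closed_form_with_dominance(self):
        # alpha_k = a_k + (1 - 2 q_k) d_k when there is no epistasis
        anchor = Anchor.from_allele_frequencies(np.array([0.3, 0.5]))
        blk = build_W_ipg(anchor, 0, 1)
        Es = functional_to_statistical_ipg([0, 1.0, 0, 0.5, 0, 0], blk.W_f, blk.W_s)
        assert Es[1] == pytest.approx(1.0 + (1 - 0.6) * 0.5, abs=1e-10)  # 1.2

    def test_epistatic_contribution_reads_alpha_slot(self):
        anchor = Anchor.from_allele_frequencies(np.array([0.5, 0.7]))
        ck, cl = epistatic_additive_contribution(1.0, anchor, 0, 1)
        assert ck == pytest.approx(2 * 0.7 - 1, abs=1e-10)  # 0.4
        assert cl == pytest.approx(0.0, abs=1e-10)  # q_k = 0.5
        assert epistatic_additive_contribution(0.0, anchor, 0, 1) == pytest.approx((0, 0))

    def test_alpha_decomposition_identity(self):
        # full transform alpha_k = a_k + (1-2q_k) d_k + (aa)^k for random inputs
        rng = np.random.default_rng(4)
        for _ in range(200):
            q = rng.uniform(0.05, 0.95, 2)
            anchor = Anchor.from_allele_frequencies(q)
            blk = build_W_ipg(anchor, 0, 1)
            a_k, a_l, d_k, d_l, aa = rng.normal(size=5)
            Es = functional_to_statistical_ipg([0, a_k, a_l, d_k, d_l, aa],
                                               blk.W_f, blk.W_s)
            epk, _ = epistatic_additive_contribution(aa, anchor, 0, 1)
            assert Es[1] == pytest.approx(a_k + (1 - 2 * q[0]) * d_k + epk, abs=1e-10)

    def test_round_trip_identities(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            q = rng.uniform(0.05, 0.95, 2)
            anchor = Anchor.from_allele_frequencies(q)
            blk = build_W_ipg(anchor, 0, 1)
            Es = rng.normal(size=6)
            Ef = statistical_to_functional_ipg(Es, blk.W_f, blk.W_s)
            back = functional_to_statistical_ipg(Ef, blk.W_f, blk.W_s)
            assert np.allclose(back, Es, atol=1e-10)
            Ef2 = rng.normal(size=6)
            fwd = functional_to_statistical_ipg(Ef2, blk.W_f, blk.W_s)
            assert np.allclose(statistical_to_functional_ipg(fwd, blk.W_f, blk.W_s),
                               Ef2, atol=1e-10)

    def test_delta_equals_d_and_aa_preserved(self):
        # the model restriction delta = d, (alpha alpha) = (aa) in every output
        rng = np.random.default_rng(6)
        for _ in range(100):
            geno = rng.dirichlet(np.ones(3), size=2)
            anchor = Anchor(q=(geno[:, 1] + 2 * geno[:, 2]) / 2, geno=geno, basis="genotype")
            ta, td, ha, hd, ok = anchor.class_covariates()
            if not np.all(ok):
                continue
            blk = build_W_ipg(anchor, 0, 1)
            Ef = rng.normal(size=6)
            Es = functional_to_statistical_ipg(Ef, blk.W_f, blk.W_s)
            assert Es[3] == pytest.approx(Ef[3], abs=1e-10)
            assert Es[4] == pytest.approx(Ef[4], abs=1e-10)
            assert Es[5] == pytest.approx(Ef[5], abs=1e-10)

    def test_no_adjustment_at_half_without_dominance(self):
        anchor = Anchor.from_allele_frequencies(np.array([0.5, 0.5]))
        blk = build_W_ipg(anchor, 0, 1)
        Ef = statistical_to_functional_ipg([0, 1.3, -0.2, 0, 0, 0], blk.W_f, blk.W_s)
        assert Ef[1] == pytest.approx(1.3, abs=1e-10)


class TestPpg:
    @pytest.mark.parametrize("t1,t2,expected", [(-1, 1, 1.0), (-1, -1, 0.0), (-1, 0, 0.5)])
    def test_t_d3_expected_heterozygosity(self, t1, t2, expected):
        assert t_d3(t1, t2) == pytest.approx(expected)

    def test_h_d3_substitution_examples(self):
        assert h_d3(-1, -1, 0.5, 0.5, 0.5, 0.5) == pytest.approx(-0.5)
        assert h_d3(-1, 1, 0.5, 0.5, 0.5, 0.5) == pytest.approx(0.5)
        # general: t1=-1, t2=1 -> 2 q1 p2
        assert h_d3(-1, 1, 0.3, 0.7, 0.8, 0.2) == pytest.approx(2 * 0.3 * 0.2)

    def test_state_tables(self):
        assert len(T1_STATES) == 15 and len(T2_STATES) == 15
        assert set(T1_STATES) == {-1.0, 0.0, 1.0}
        assert set(T2_STATES) == {-1.0, -0.5, 0.0, 0.5, 1.0}

    def test_pair_matrix_dimensions_and_ones(self):
        blk = build_W_ppg(0.3, 0.6, 0.5, 0.2)
        assert blk.W_f.shape == (225, 8) and blk.W_s.shape == (225, 8)
        assert np.all(blk.W_f[:, 0] == 1)

    def test_symmetric_frequencies_equal_alphas(self):
        blk = build_W_ppg(0.4, 0.6, 0.4, 0.6)
        Ef = np.array([0, 1.0, 0.5, 1.0, 0.5, 0.3, -0.4, 0.7])
        Es = np.linalg.solve(blk.W_s.T @ blk.W_s, blk.W_s.T @ blk.W_f @ Ef)
        assert Es[1] == pytest.approx(Es[3], abs=1e-10)  # alpha_k1 == alpha_k2
        assert Es[2] == pytest.approx(Es[4], abs=1e-10)

    def test_delta3_and_aa3_equal_functional(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            q = rng.uniform(0.1, 0.9, 4)
            blk = build_W_ppg(*q)
            a_k, a_l, d_k, d_l, aa = rng.normal(size=5)
            Ef = np.array([0, a_k, a_l, a_k, a_l, d_k, d_l, aa])
            Es = np.linalg.solve(blk.W_s.T @ blk.W_s, blk.W_s.T @ blk.W_f @ Ef)
            assert Es[5] == pytest.approx(d_k, abs=1e-10)
            assert Es[6] == pytest.approx(d_l, abs=1e-10)
            assert Es[7] == pytest.approx(aa, abs=1e-10)

    def test_forward_backward_round_trip(self):
        rng = np.random.default_rng(8)
        q1 = rng.uniform(0.1, 0.9, 2)
        q2 = rng.uniform(0.1, 0.9, 2)
        pairs = np.array([[0, 1]])
        M_fs = pair_transform_matrices_ppg(q1, q2, pairs, "fs")[0]
        M_sf = pair_transform_matrices_ppg(q1, q2, pairs, "sf")[0]
        for _ in range(100):
            Es = rng.normal(size=8)
            assert np.allclose(M_fs @ (M_sf @ Es), Es, atol=1e-10)

    def test_degenerate_ppg_anchor_raises(self):
        with pytest.raises(DegenerateAnchorError):
            build_W_ppg(0.0, 0.5, 0.5, 0.5)

    def test_h_d3_centering_over_random_mating_plots(self, hwe_pop_factory):
        # expectation of h_d3 over plots produced by random mating ~ 0
        rng = np.random.default_rng(9)
        pop1 = hwe_pop_factory(0.35, 4000, 1, seed=10)
        pop2 = hwe_pop_factory(0.6, 4000, 1, seed=11)
        t1 = pop1.dosage[:, 0].astype(float) - 1
        t2a = pop2.dosage[:2000, 0].astype(float) - 1
        t2b = pop2.dosage[2000:, 0].astype(float) - 1
        t2 = 0.5 * (t2a + t2b)
        q1 = t1.mean() / 2 + 0.5
        q2 = 0.5 * (t2a.mean() + t2b.mean()) / 2 + 0.5
        vals = h_d3(t1[:2000], t2, q1, 1 - q1, q2, 1 - q2)
        assert abs(vals.mean()) < 4 * vals.std() / np.sqrt(len(vals))
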