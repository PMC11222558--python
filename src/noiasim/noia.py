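"""NOIA covariates and functional <-> statistical effect transforms.

Functional effects (a, d, (aa)) act on genotype covariates t that depend only
on the genotype itself; statistical effects (alpha, delta, (alpha alpha)) act
on orthogonalized covariates h anchored to population allele or genotype
frequencies. For a locus pair the two parameterizations are linked through
genetic-effect design matrices W_f and W_s over the joint genotype classes:

    W_s E_s = W_f E_f        =>        E_s = (W_s'W_s)^-1 W_s' W_f E_f

and the reverse direction with the roles of W_f and W_s exchanged. Because the
two design matrices span the same column space, the projection is exact and a
diagonal genotype-frequency weight matrix cancels from the equation.

Genotype coding: dosage of allele b is 0/1/2 for genotypes BB/Bb/bb.

For individual phenotypes (iPG) the pair matrices are 9 x 6 over the 9 joint
genotype classes (locus k index varying fastest). For three-way hybrid plot
phenotypes (pPG), a single locus has 15 plot states: 3 population-1 parental
genotypes x 5 two-way parental dosage levels (-1, -0.5, 0, 0.5, 1, the
two-way dosage varying fastest); a locus pair therefore spans 225 joint plot
states and the pair matrices are 225 x 8 (locus k state varying fastest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Population, genotype_frequencies

_DEN_TOL = 1e-12


class DegenerateAnchorError(np.linalg.LinAlgError):
    """Anchoring frequencies leave the statistical design matrix singular."""


# ---------------------------------------------------------------------------
# Scalar/array covariates
# ---------------------------------------------------------------------------


def t_covariates(dosage):
    """Functional covariates (t_a, t_d): BB/Bb/bb -> (-1,0), (0,1), (1,0)."""
    dosage = np.asarray(dosage)
    if np.any((dosage < 0) | (dosage > 2)):
        raise ValueError("dosage must be 0, 1 or 2")
    return dosage - 1.0, (dosage == 1).astype(float)


def h_covariates_freq(dosage, q):
    """Statistical covariates from allele frequency q (valid for h_d under HWE)."""
    dosage = np.asarray(dosage)
    q = np.asarray(q, dtype=float)
    p = 1.0 - q
    h_a = dosage - 2.0 * q
    h_d = np.where(dosage == 0, -2.0 * q**2, np.where(dosage == 1, 2.0 * p * q, -2.0 * p**2))
    return h_a, h_d


def h_covariates_genofreq(dosage, p_BB, p_Bb, p_bb):
    """Statistical covariates from genotype frequencies (HWE not required).

    h_d uses the shared denominator p_BB + p_bb - (p_BB - p_bb)^2; when the
    denominator vanishes (monomorphic locus or an all-heterozygote class
    structure) h_d is defined as 0.
    """
    dosage = np.asarray(dosage)
    p_BB, p_Bb, p_bb = (np.asarray(x, dtype=float) for x in (p_BB, p_Bb, p_bb))
    h_a = dosage - (p_Bb + 2.0 * p_bb)
    den = p_BB + p_bb - (p_BB - p_bb) ** 2
    safe = np.where(np.abs(den) > _DEN_TOL, den, 1.0)
    h_d = np.where(
        dosage == 0,
        -2.0 * p_Bb * p_bb / safe,
        np.where(dosage == 1, 4.0 * p_BB * p_bb / safe, -2.0 * p_BB * p_Bb / safe),
    )
    h_d = np.where(np.abs(den) > _DEN_TOL, h_d, 0.0)
    return h_a, h_d


def epistasis_covariate(cov_k, cov_l):
    """Additive-by-additive interaction covariate: the product of the two
    additive covariates of the pair (same individual, loci k and l)."""
    return np.asarray(cov_k) * np.asarray(cov_l)


# ---------------------------------------------------------------------------
# Anchoring frequencies
# ---------------------------------------------------------------------------


@dataclass
class Anchor:
    """Reference frequencies that statistical effects are tied to.

    `basis` selects the covariate form: "genotype" uses the genotype-frequency
    covariates (exact for populations out of Hardy-Weinberg equilibrium, the
    default for descendant generations); "allele" uses the allele-frequency
    covariates (h_d valid under HWE only).
    """

    q: np.ndarray  # (L,) allele-b frequency
    geno: np.ndarray  # (L, 3) genotype frequencies [BB, Bb, bb]
    basis: str = "genotype"

    @classmethod
    def from_population(cls, pop_or_dosage, subset=None, basis: str = "genotype") -> "Anchor":
        geno = genotype_frequencies(pop_or_dosage, subset)
        q = (geno[:, 1] + 2.0 * geno[:, 2]) / 2.0
        return cls(q=q, geno=geno, basis=basis)

    @classmethod
    def from_allele_frequencies(cls, q) -> "Anchor":
        q = np.asarray(q, dtype=float)
        p = 1.0 - q
        geno = np.stack([p**2, 2 * p * q, q**2], axis=1)
        return cls(q=q, geno=geno, basis="allele")

    @property
    def n_loci(self) -> int:
        return len(self.q)

    def class_covariates(self):
        """Per-locus class values: t_a, t_d, h_a, h_d as (L, 3) arrays, plus an
        `ok` mask marking loci whose statistical design is non-degenerate."""
        L = self.n_loci
        dos = np.broadcast_to(np.arange(3)[None, :], (L, 3))
        ta = dos - 1.0
        td = (dos == 1).astype(float)
        if self.basis == "allele":
            q = self.q[:, None]
            ha, hd = h_covariates_freq(dos, np.broadcast_to(q, (L, 3)))
        else:
            ha, hd = h_covariates_genofreq(
                dos,
                np.broadcast_to(self.geno[:, [0]], (L, 3)),
                np.broadcast_to(self.geno[:, [1]], (L, 3)),
                np.broadcast_to(self.geno[:, [2]], (L, 3)),
            )
        polymorphic = (self.q > _DEN_TOL) & (self.q < 1 - _DEN_TOL)
        ok = polymorphic & (np.abs(hd).max(axis=1) > _DEN_TOL)
        return ta, td, ha, hd, ok


# ---------------------------------------------------------------------------
# iPG design matrices (9 x 6) and transforms
# ---------------------------------------------------------------------------


@dataclass
class EffectBlock:
    """Design matrices (and optionally effect vectors) for one locus pair."""

    W_f: np.ndarray
    W_s: np.ndarray
    E_f: np.ndarray | None = None
    E_s: np.ndarray | None = None


def _pair_W(ta_k, td_k, xa_k, xd_k, ta_l, td_l, xa_l, xd_l):
    """9x6 (or batched (..., 9, 6)) pair design matrix from 3-class vectors.

    Column layout: [1, J (x) v_k^a, v_l^a (x) J, J (x) v_k^d, v_l^d (x) J,
    v_l^a (x) v_k^a], with the locus-k genotype index varying fastest in rows.
    """
    tile = lambda v: np.tile(v, 3) if v.ndim == 1 else np.tile(v, (1, 3))
    rep = lambda v: np.repeat(v, 3, axis=-1)
    one = np.ones_like(tile(ta_k))
    cols = [one, tile(xa_k), rep(xa_l), tile(xd_k), rep(xd_l), rep(xa_l) * tile(xa_k)]
    return np.stack(cols, axis=-1)


def build_W_ipg(anchor: Anchor, k: int, l: int) -> EffectBlock:
    """Functional and statistical 9x6 design matrices for QTL pair (k, l)."""
    ta, td, ha, hd, ok = anchor.class_covariates()
    W_f = _pair_W(ta[k], td[k], ta[k], td[k], ta[l], td[l], ta[l], td[l])
    W_s = _pair_W(ta[k], td[k], ha[k], hd[k], ta[l], td[l], ha[l], hd[l])
    if not (ok[k] and ok[l]):
        raise DegenerateAnchorError(
            f"anchoring frequencies at loci {k},{l} give a singular statistical design"
        )
    return EffectBlock(W_f=W_f, W_s=W_s)


def _left_solve(W_target, W_source, E, err="design matrix"):
    A = W_target.T @ W_target
    try:
        return np.linalg.solve(A, W_target.T @ (W_source @ np.asarray(E, dtype=float)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateAnchorError(f"singular {err}") from exc


def functional_to_statistical_ipg(E_f, W_f, W_s) -> np.ndarray:
    """E_s = (W_s'W_s)^-1 W_s' W_f E_f; layout (mu, a_k, a_l, d_k, d_l, (aa))
    -> (mu, alpha_k, alpha_l, delta_k, delta_l, (alpha alpha))."""
    return _left_solve(W_s, W_f, E_f, err="W_s'W_s (degenerate anchoring frequencies)")


def statistical_to_functional_ipg(E_s, W_f, W_s) -> np.ndarray:
    """E_f = (W_f'W_f)^-1 W_f' W_s E_s (inverse direction; round trip is identity)."""
    return _left_solve(W_f, W_s, E_s, err="W_f'W_f")


def epistatic_additive_contribution(aa_kl: float, anchor: Anchor, k: int, l: int):
    """Additive substitution contributions of a pair's epistasis at each locus.

    Transforms E_f = (1, 0, 0, 0, 0, (aa)) and reads the alpha slots."""
    blk = build_W_ipg(anchor, k, l)
    E_s = functional_to_statistical_ipg([1.0, 0, 0, 0, 0, aa_kl], blk.W_f, blk.W_s)
    return E_s[1], E_s[2]


# Batched pair/single transforms ------------------------------------------------


def _batch_pair_W(ta, td, xa, xd, kk, ll):
    """(P, 9, 6) pair design matrices for index arrays kk, ll into (L,3) tables."""
    return _pair_W(ta[kk], td[kk], xa[kk], xd[kk], ta[ll], td[ll], xa[ll], xd[ll])


def _batch_single_W(ta, td, xa, xd, idx):
    one = np.ones((len(idx), 3))
    return np.stack([one, xa[idx], xd[idx]], axis=-1)


def pair_transform_matrices_ipg(anchor: Anchor, pairs: np.ndarray, direction="fs"):
    """Per-pair 6x6 transform matrices M with E_out = M @ E_in.

    direction 'fs': functional -> statistical; 'sf': the reverse. Only pairs
    whose two loci are non-degenerate are transformable; returns (M, ok_pair).
    """
    ta, td, ha, hd, ok = anchor.class_covariates()
    kk, ll = pairs[:, 0], pairs[:, 1]
    ok_pair = ok[kk] & ok[ll]
    M = np.zeros((len(pairs), 6, 6))
    if np.any(ok_pair):
        k, l = kk[ok_pair], ll[ok_pair]
        W_f = _batch_pair_W(ta, td, ta, td, k, l)
        W_s = _batch_pair_W(ta, td, ha, hd, k, l)
        src, tgt = (W_f, W_s) if direction == "fs" else (W_s, W_f)
        A = np.einsum("pij,pik->pjk", tgt, tgt)
        B = np.einsum("pij,pik->pjk", tgt, src)
        M[ok_pair] = np.linalg.solve(A, B)
    return M, ok_pair


def single_transform_matrices_ipg(anchor: Anchor, loci: np.ndarray, direction="fs"):
    """Per-locus 3x3 transform matrices for unpaired QTL; returns (M, ok)."""
    ta, td, ha, hd, ok = anchor.class_covariates()
    ok_loc = ok[loci]
    M = np.zeros((len(loci), 3, 3))
    if np.any(ok_loc):
        idx = loci[ok_loc]
        W_f = _batch_single_W(ta, td, ta, td, idx)
        W_s = _batch_single_W(ta, td, ha, hd, idx)
        src, tgt = (W_f, W_s) if direction == "fs" else (W_s, W_f)
        A = np.einsum("pij,pik->pjk", tgt, tgt)
        B = np.einsum("pij,pik->pjk", tgt, src)
        M[ok_loc] = np.linalg.solve(A, B)
    return M, ok_loc


def statistical_covariates_ipg(dosage: np.ndarray, anchor: Anchor):
    """(H_a, H_d) covariate matrices (n x L) for a dosage matrix."""
    _, _, ha, hd, _ = anchor.class_covariates()
    cols = np.arange(dosage.shape[1])[None, :]
    return ha[cols, dosage], hd[cols, dosage]


def functional_covariates_ipg(dosage: np.ndarray):
    """(T_a, T_d) covariate matrices (n x L)."""
    return dosage - 1.0, (dosage == 1).astype(float)


# ---------------------------------------------------------------------------
# pPG: three-way hybrid plot covariates and design matrices (225 x 8)
# ---------------------------------------------------------------------------

# 15 single-locus plot states: population-1 parental genotype (slow) x
# two-way parental dosage (fast).
T1_STATES = np.repeat([-1.0, 0.0, 1.0], 5)
T2_STATES = np.tile([-1.0, -0.5, 0.0, 0.5, 1.0], 3)


def t_d3(t1, t2):
    """Plot dominance covariate: expected heterozygosity of the plot's plants
    given the population-1 parental genotype t1 and two-way dosage t2."""
    t1, t2 = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float)
    return 0.25 * ((1 - t1) * (t2 + 1) + (t1 + 1) * (1 - t2))


def h_d3(t1, t2, q1, p1, q2, p2):
    """Statistical plot dominance covariate anchored to the two populations'
    allele frequencies (generalized dominance relationship element)."""
    t1, t2 = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float)
    return (
        0.5 * (1 - t1) * (t2 + 1) * q1 * p2
        + 0.5 * (t1 + 1) * (1 - t2) * p1 * q2
        - 0.5 * (1 - t1) * (1 - t2) * q1 * q2
        - 0.5 * (t1 + 1) * (t2 + 1) * p1 * p2
    )


def _ppg_locus_class_vectors(q1, q2):
    """Per-state covariates for one locus: (t_a1, t_a2, t_d3, h_a1, h_a2, h_d3),
    each a 15-vector over the plot states."""
    ta1, ta2 = T1_STATES, T2_STATES
    td3 = t_d3(ta1, ta2)
    ha1 = ta1 - 2.0 * q1
    ha2 = ta2 - 2.0 * q2
    hd3 = h_d3(ta1, ta2, q1, 1 - q1, q2, 1 - q2)
    return ta1, ta2, td3, ha1, ha2, hd3


def _ppg_pair_W(vk, vl):
    """(225, 8) pair design matrix from two locus class-vector tuples.

    Column layout: [1, 1/2 a_k^1, 1/2 a_l^1, 1/2 a_k^2, 1/2 a_l^2, d_k, d_l,
    (1/2(a_l^1+a_l^2)) * (1/2(a_k^1+a_k^2))]; locus-k state varies fastest.
    """
    a1k, a2k, dk = vk
    a1l, a2l, dl = vl
    tile = lambda v: np.tile(v, 15)
    rep = lambda v: np.repeat(v, 15)
    one = np.ones(225)
    ep = rep(0.5 * (a1l + a2l)) * tile(0.5 * (a1k + a2k))
    return np.stack(
        [one, tile(0.5 * a1k), rep(0.5 * a1l), tile(0.5 * a2k), rep(0.5 * a2l),
         tile(dk), rep(dl), ep],
        axis=-1,
    )


def build_W_ppg(q_k1: float, q_l1: float, q_k2: float, q_l2: float) -> EffectBlock:
    """Functional and statistical 225x8 design matrices for a pPG locus pair.

    E_f layout: (1, a_k, a_l, a_k, a_l, d_k, d_l, (aa)) — the additive
    functional effect is repeated for the two parental origins. E_s layout:
    (mu, alpha_k1, alpha_l1, alpha_k2, alpha_l2, delta_k3, delta_l3,
    (alpha alpha)_3).
    """
    for q in (q_k1, q_l1, q_k2, q_l2):
        if not (_DEN_TOL < q < 1 - _DEN_TOL):
            raise DegenerateAnchorError("pPG anchoring requires 0 < q < 1 in both populations")
    tk = _ppg_locus_class_vectors(q_k1, q_k2)
    tl = _ppg_locus_class_vectors(q_l1, q_l2)
    W_f = _ppg_pair_W((tk[0], tk[1], tk[2]), (tl[0], tl[1], tl[2]))
    W_s = _ppg_pair_W((tk[3], tk[4], tk[5]), (tl[3], tl[4], tl[5]))
    return EffectBlock(W_f=W_f, W_s=W_s)


def _ppg_single_W(q1, q2, statistical):
    ta1, ta2, td3, ha1, ha2, hd3 = _ppg_locus_class_vectors(q1, q2)
    if statistical:
        return np.stack([np.ones(15), 0.5 * ha1, 0.5 * ha2, hd3], axis=-1)
    return np.stack([np.ones(15), 0.5 * ta1, 0.5 * ta2, td3], axis=-1)


def pair_transform_matrices_ppg(q1: np.ndarray, q2: np.ndarray, pairs: np.ndarray, direction="fs"):
    """Per-pair 8x8 pPG transform matrices at the two populations' frequencies."""
    M = np.empty((len(pairs), 8, 8))
    for i, (k, l) in enumerate(pairs):
        blk = build_W_ppg(q1[k], q1[l], q2[k], q2[l])
        src, tgt = (blk.W_f, blk.W_s) if direction == "fs" else (blk.W_s, blk.W_f)
        M[i] = np.linalg.solve(tgt.T @ tgt, tgt.T @ src)
    return M


def single_transform_matrices_ppg(q1, q2, loci, direction="fs"):
    """Per-locus 4x4 pPG transforms for unpaired QTL: (1, a, a, d) <-> (mu,
    alpha1, alpha2, delta3)."""
    M = np.empty((len(loci), 4, 4))
    for i, j in enumerate(loci):
        W_f = _ppg_single_W(q1[j], q2[j], statistical=False)
        W_s = _ppg_single_W(q1[j], q2[j], statistical=True)
        src, tgt = (W_f, W_s) if direction == "fs" else (W_s, W_f)
        M[i] = np.linalg.solve(tgt.T @ tgt, tgt.T @ src)
    return M


def plot_covariates_ppg(t1: np.ndarray, t2: np.ndarray, q1: np.ndarray, q2: np.ndarray, basis="statistical"):
    """Per-plot covariate matrices for pPG genetic values.

    t1: (n_plots, L) population-1 parental genotype codes (-1/0/1);
    t2: (n_plots, L) two-way parental dosages (mean of the two grandparental
    line codes). Returns (C_a1, C_a2, C_d) where the plot additive covariates
    carry the factor 1/2 of the plot model.
    """
    if basis == "statistical":
        return (
            0.5 * (t1 - 2.0 * q1[None, :]),
            0.5 * (t2 - 2.0 * q2[None, :]),
            h_d3(t1, t2, q1[None, :], 1 - q1[None, :], q2[None, :], 1 - q2[None, :]),
        )
    return 0.5 * t1, 0.5 * t2, t_d3(t1, t2)
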