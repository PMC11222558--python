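"""Genetic variances by individual and by locus, for iPG and pPG data.

Two approximations of the genetic variance are supported, mirroring how the
quantities are defined in quantitative-genetic practice:

* **by individual** — the population variance (divisor n) of per-individual
  summed genetic values (u, v, (uu)); captures covariances between loci and
  between family members.
* **by locus** — the sum over loci of per-locus variances computed from the
  locus' genotype-class distribution; assumes linkage equilibrium (no
  covariance between loci). Under HWE the additive term reduces to the
  familiar 2 p_j q_j alpha_j^2.

The statistical effects attached to a population can be re-derived from the
fixed functional effects at any anchoring frequencies (the default for
descendant data is the pooled genotype frequencies of the analyzed
generations), since functional effects are frequency-free objects.
"""

from __future__ import annotations

import numpy as np

from .models import FunctionalEffects, StatisticalEffectsIPG, StatisticalEffectsPPG, VarianceComponents
from .noia import (
    Anchor,
    functional_covariates_ipg,
    pair_transform_matrices_ipg,
    pair_transform_matrices_ppg,
    plot_covariates_ppg,
    single_transform_matrices_ipg,
    single_transform_matrices_ppg,
    statistical_covariates_ipg,
    t_d3,
)

# ---------------------------------------------------------------------------
# Transform contexts (batched forward/backward NOIA over a whole genome)
# ---------------------------------------------------------------------------


class IpgTransformContext:
    """Precomputed per-pair / per-locus NOIA transforms at fixed anchoring."""

    def __init__(self, anchor: Anchor, pairs: np.ndarray, n_qtl: int):
        self.anchor = anchor
        self.pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        self.n_qtl = n_qtl
        self.singles = np.setdiff1d(np.arange(n_qtl), self.pairs.ravel())
        self.M_pair, self.ok_pair = pair_transform_matrices_ipg(anchor, self.pairs, "fs") \
            if len(self.pairs) else (np.zeros((0, 6, 6)), np.zeros(0, bool))
        self.Mb_pair, _ = pair_transform_matrices_ipg(anchor, self.pairs, "sf") \
            if len(self.pairs) else (np.zeros((0, 6, 6)), np.zeros(0, bool))
        self.M_single, self.ok_single = single_transform_matrices_ipg(anchor, self.singles, "fs") \
            if len(self.singles) else (np.zeros((0, 3, 3)), np.zeros(0, bool))
        self.Mb_single, _ = single_transform_matrices_ipg(anchor, self.singles, "sf") \
            if len(self.singles) else (np.zeros((0, 3, 3)), np.zeros(0, bool))

    def forward(self, a, d, aa) -> StatisticalEffectsIPG:
        """Functional -> statistical at the context anchoring.

        Pairs or loci with degenerate anchoring (drifted to fixation) fall back
        to the allele-frequency closed form alpha = a + (1-2q)d + (2q_partner-1)aa;
        their variance contribution is zero at such frequencies.
        """
        a, d, aa = (np.asarray(x, float) for x in (a, d, aa))
        L = self.n_qtl
        alpha = np.empty(L)
        delta = np.empty(L)
        aas = np.empty(len(self.pairs))
        q = self.anchor.q
        if len(self.pairs):
            k, l = self.pairs[:, 0], self.pairs[:, 1]
            Ef = np.stack([np.ones(len(k)), a[k], a[l], d[k], d[l], aa], axis=1)
            Es = np.einsum("pij,pj->pi", self.M_pair, Ef)
            okp = self.ok_pair
            alpha[k[okp]], alpha[l[okp]] = Es[okp, 1], Es[okp, 2]
            delta[k[okp]], delta[l[okp]] = Es[okp, 3], Es[okp, 4]
            aas[okp] = Es[okp, 5]
            bad = ~okp
            if np.any(bad):
                kb, lb = k[bad], l[bad]
                alpha[kb] = a[kb] + (1 - 2 * q[kb]) * d[kb] + (2 * q[lb] - 1) * aa[bad]
                alpha[lb] = a[lb] + (1 - 2 * q[lb]) * d[lb] + (2 * q[kb] - 1) * aa[bad]
                delta[kb], delta[lb] = d[kb], d[lb]
                aas[bad] = aa[bad]
        if len(self.singles):
            s = self.singles
            Ef = np.stack([np.ones(len(s)), a[s], d[s]], axis=1)
            Es = np.einsum("pij,pj->pi", self.M_single, Ef)
            oks = self.ok_single
            alpha[s[oks]], delta[s[oks]] = Es[oks, 1], Es[oks, 2]
            sb = s[~oks]
            alpha[sb] = a[sb] + (1 - 2 * q[sb]) * d[sb]
            delta[sb] = d[sb]
        return StatisticalEffectsIPG(alpha, delta, aas, self.anchor)

    def backward(self, alpha, delta, alpha_alpha) -> FunctionalEffects:
        """Statistical -> functional (the SS_NOIA back-transform)."""
        alpha, delta, aa_s = (np.asarray(x, float) for x in (alpha, delta, alpha_alpha))
        L = self.n_qtl
        a = np.empty(L)
        d = np.empty(L)
        aa = np.empty(len(self.pairs))
        q = self.anchor.q
        if len(self.pairs):
            k, l = self.pairs[:, 0], self.pairs[:, 1]
            Es = np.stack([np.zeros(len(k)), alpha[k], alpha[l], delta[k], delta[l], aa_s], axis=1)
            Ef = np.einsum("pij,pj->pi", self.Mb_pair, Es)
            okp = self.ok_pair
            a[k[okp]], a[l[okp]] = Ef[okp, 1], Ef[okp, 2]
            d[k[okp]], d[l[okp]] = Ef[okp, 3], Ef[okp, 4]
            aa[okp] = Ef[okp, 5]
            bad = ~okp
            if np.any(bad):
                kb, lb = k[bad], l[bad]
                aa[bad] = aa_s[bad]
                d[kb], d[lb] = delta[kb], delta[lb]
                a[kb] = alpha[kb] - (1 - 2 * q[kb]) * delta[kb] - (2 * q[lb] - 1) * aa_s[bad]
                a[lb] = alpha[lb] - (1 - 2 * q[lb]) * delta[lb] - (2 * q[kb] - 1) * aa_s[bad]
        if len(self.singles):
            s = self.singles
            Es = np.stack([np.zeros(len(s)), alpha[s], delta[s]], axis=1)
            Ef = np.einsum("pij,pj->pi", self.Mb_single, Es)
            oks = self.ok_single
            a[s[oks]], d[s[oks]] = Ef[oks, 1], Ef[oks, 2]
            sb = s[~oks]
            d[sb] = delta[sb]
            a[sb] = alpha[sb] - (1 - 2 * q[sb]) * delta[sb]
        return FunctionalEffects(a=a, d=d, aa=aa)


class PpgTransformContext:
    """Precomputed pPG NOIA transforms at the two base populations' frequencies."""

    def __init__(self, q1: np.ndarray, q2: np.ndarray, pairs: np.ndarray, n_qtl: int):
        self.q1, self.q2 = np.asarray(q1, float), np.asarray(q2, float)
        self.pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        self.n_qtl = n_qtl
        self.singles = np.setdiff1d(np.arange(n_qtl), self.pairs.ravel())
        self.M_pair = pair_transform_matrices_ppg(self.q1, self.q2, self.pairs, "fs") \
            if len(self.pairs) else np.zeros((0, 8, 8))
        self.M_single = single_transform_matrices_ppg(self.q1, self.q2, self.singles, "fs") \
            if len(self.singles) else np.zeros((0, 4, 4))

    def forward(self, a, d, aa) -> StatisticalEffectsPPG:
        a, d, aa = (np.asarray(x, float) for x in (a, d, aa))
        L = self.n_qtl
        a1, a2 = np.empty(L), np.empty(L)
        d3 = np.empty(L)
        aa3 = np.empty(len(self.pairs))
        if len(self.pairs):
            k, l = self.pairs[:, 0], self.pairs[:, 1]
            Ef = np.stack([np.ones(len(k)), a[k], a[l], a[k], a[l], d[k], d[l], aa], axis=1)
            Es = np.einsum("pij,pj->pi", self.M_pair, Ef)
            a1[k], a1[l] = Es[:, 1], Es[:, 2]
            a2[k], a2[l] = Es[:, 3], Es[:, 4]
            d3[k], d3[l] = Es[:, 5], Es[:, 6]
            aa3 = Es[:, 7]
        if len(self.singles):
            s = self.singles
            Ef = np.stack([np.ones(len(s)), a[s], a[s], d[s]], axis=1)
            Es = np.einsum("pij,pj->pi", self.M_single, Ef)
            a1[s], a2[s], d3[s] = Es[:, 1], Es[:, 2], Es[:, 3]
        return StatisticalEffectsPPG(a1, a2, d3, aa3, self.q1, self.q2)


def derive_statistical_ipg(effects: FunctionalEffects, anchor: Anchor, pairs) -> StatisticalEffectsIPG:
    """Statistical effects implied by fixed functional effects at `anchor`."""
    ctx = IpgTransformContext(anchor, pairs, effects.n_qtl)
    return ctx.forward(effects.a, effects.d, effects.aa)


def derive_statistical_ppg(effects: FunctionalEffects, q1, q2, pairs) -> StatisticalEffectsPPG:
    ctx = PpgTransformContext(q1, q2, pairs, effects.n_qtl)
    return ctx.forward(effects.a, effects.d, effects.aa)


# ---------------------------------------------------------------------------
# Genetic values (iPG)
# ---------------------------------------------------------------------------


def genetic_values_ipg(dosage: np.ndarray, effects, pairs, basis: str = None):
    """Per-individual genetic values (u, v, uu).

    `effects` is FunctionalEffects (t covariates) or StatisticalEffectsIPG
    (h covariates at the effects' anchoring frequencies).
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if isinstance(effects, FunctionalEffects):
        Ca, Cd = functional_covariates_ipg(dosage)
        e1, e2, e3 = effects.a, effects.d, effects.aa
    elif isinstance(effects, StatisticalEffectsIPG):
        if effects.anchor is None:
            raise ValueError("statistical effects require anchoring frequencies")
        Ca, Cd = statistical_covariates_ipg(dosage, effects.anchor)
        e1, e2, e3 = effects.alpha, effects.delta, effects.alpha_alpha
    else:
        raise TypeError("effects must be FunctionalEffects or StatisticalEffectsIPG")
    u = Ca @ e1
    v = Cd @ e2
    if len(pairs):
        uu = (Ca[:, pairs[:, 0]] * Ca[:, pairs[:, 1]]) @ e3
    else:
        uu = np.zeros(dosage.shape[0])
    return u, v, uu


def variance_by_individual(u, v, uu, residual=None, basis="statistical") -> VarianceComponents:
    """Population variance (divisor n) of the summed genetic values."""
    u = np.asarray(u, float)
    if u.size < 2:
        raise ValueError("variance by individual needs at least 2 individuals")
    return VarianceComponents(
        mode="by_individual",
        basis=basis,
        additive=float(np.var(u)),
        dominance=float(np.var(v)),
        epistasis=float(np.var(uu)),
        residual=None if residual is None else float(np.var(residual)),
    )


def _class_moments(values: np.ndarray, freqs: np.ndarray):
    """First/second moments of per-locus 3-class covariate values under the
    per-locus class frequencies. values, freqs: (L, 3)."""
    m1 = (freqs * values).sum(axis=1)
    m2 = (freqs * values**2).sum(axis=1)
    return m1, m2


def variance_by_locus_ipg(effects, anchor: Anchor = None, pairs=None, residual=None) -> VarianceComponents:
    """Sum of per-locus variances from the genotype-class distribution.

    Statistical effects use their own anchoring; for FunctionalEffects an
    explicit `anchor` supplies the genotype-class frequencies. Epistatic terms
    assume linkage equilibrium: var(h_ep) = E[h_k^2] E[h_l^2] - (E[h_k] E[h_l])^2.
    """
    if isinstance(effects, StatisticalEffectsIPG):
        anchor = effects.anchor if anchor is None else anchor
        ta, td, ha, hd, _ = anchor.class_covariates()
        Ca, Cd = ha, hd
        e1, e2, e3 = effects.alpha, effects.delta, effects.alpha_alpha
        basis = "statistical"
    else:
        if anchor is None:
            raise ValueError("functional by-locus variance needs an anchor for class frequencies")
        ta, td, ha, hd, _ = anchor.class_covariates()
        Ca, Cd = ta, td
        e1, e2, e3 = effects.a, effects.d, effects.aa
        basis = "functional"
    freqs = anchor.geno
    ma1, ma2 = _class_moments(Ca, freqs)
    md1, md2 = _class_moments(Cd, freqs)
    var_a = ma2 - ma1**2
    var_d = md2 - md1**2
    additive = float(np.sum(var_a * e1**2))
    dominance = float(np.sum(var_d * e2**2))
    epistasis = 0.0
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2) if pairs is not None else np.empty((0, 2), int)
    if len(pairs):
        k, l = pairs[:, 0], pairs[:, 1]
        var_ep = ma2[k] * ma2[l] - (ma1[k] * ma1[l]) ** 2
        epistasis = float(np.sum(var_ep * e3**2))
    return VarianceComponents(
        mode="by_locus", basis=basis,
        additive=additive, dominance=dominance, epistasis=epistasis,
        residual=None if residual is None else float(np.var(residual)),
    )


# ---------------------------------------------------------------------------
# pPG genetic values and variances
# ---------------------------------------------------------------------------


def ppg_plot_arrays(lines1, lines2, plots, qtl_index):
    """Per-plot parental genotype codes over the QTL.

    Returns (t1, t2, t2a, t2b): t1 is the population-1 parental line code
    (-1/0/1), t2 the two-way parental dosage 0.5*(t2a + t2b).
    """
    d1 = lines1.dosage[:, qtl_index].astype(float) - 1.0
    d2 = lines2.dosage[:, qtl_index].astype(float) - 1.0
    t1 = d1[plots.i1]
    t2a = d2[plots.i2a]
    t2b = d2[plots.i2b]
    return t1, 0.5 * (t2a + t2b), t2a, t2b


def genetic_values_ppg(lines1, lines2, plots, qtl_index, pairs, effects):
    """Per-line and per-plot pPG genetic values.

    Returns dict with `u1` (population-1 lines appearing in `plots`), `u2`
    (population-2 lines appearing), `v3` and `uu3` (plots). Line-level
    additive values use covariate 1/2*h1 for population 1 and 1/4*h2 for
    population 2: each plot receives its line value once from population 1 and
    the sum of its two grandparental line values from population 2.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    qtl_index = np.asarray(qtl_index, dtype=int)
    lines1_used = np.unique(plots.i1)
    lines2_used = np.unique(np.concatenate([plots.i2a, plots.i2b]))
    d1 = lines1.dosage[lines1_used][:, qtl_index].astype(float) - 1.0
    d2 = lines2.dosage[lines2_used][:, qtl_index].astype(float) - 1.0
    t1, t2, _, _ = ppg_plot_arrays(lines1, lines2, plots, qtl_index)
    if isinstance(effects, StatisticalEffectsPPG):
        q1, q2 = effects.q1, effects.q2
        C1 = 0.5 * (d1 - 2.0 * q1[None, :])
        C2 = 0.25 * (d2 - 2.0 * q2[None, :])
        Ca1, Ca2, Cd = plot_covariates_ppg(t1, t2, q1, q2, basis="statistical")
        u1 = C1 @ effects.alpha1
        u2 = C2 @ effects.alpha2
        v3 = Cd @ effects.delta3
        e3 = effects.alpha_alpha3
        Cae = Ca1 + Ca2
    else:
        C1 = 0.5 * d1
        C2 = 0.25 * d2
        Cd = t_d3(t1, t2)
        u1 = C1 @ effects.a
        u2 = C2 @ effects.a
        v3 = Cd @ effects.d
        e3 = effects.aa
        Cae = 0.5 * (t1 + t2)
    if len(pairs):
        uu3 = (Cae[:, pairs[:, 0]] * Cae[:, pairs[:, 1]]) @ e3
    else:
        uu3 = np.zeros(plots.n)
    return {"u1": u1, "u2": u2, "v3": v3, "uu3": uu3,
            "lines1_used": lines1_used, "lines2_used": lines2_used}


def variance_ppg(effects, lines1, lines2, plots, qtl_index, pairs,
                 mode: str = "by_individual", residual=None) -> VarianceComponents:
    """pPG variance components.

    by_individual: population variances of per-line u1, u2 and per-plot v3,
    uu3. by_locus: per-locus variances of the same covariates (linkage
    equilibrium assumed between loci).
    """
    basis = "statistical" if isinstance(effects, StatisticalEffectsPPG) else "functional"
    vals = genetic_values_ppg(lines1, lines2, plots, qtl_index, pairs, effects)
    if mode == "by_individual":
        return VarianceComponents(
            mode=mode, basis=basis,
            additive1=float(np.var(vals["u1"])),
            additive2=float(np.var(vals["u2"])),
            dominance3=float(np.var(vals["v3"])),
            epistasis3=float(np.var(vals["uu3"])),
            residual=None if residual is None else float(np.var(residual)),
        )
    if mode != "by_locus":
        raise ValueError("mode must be by_locus or by_individual")
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    qtl_index = np.asarray(qtl_index, dtype=int)
    d1 = lines1.dosage[vals["lines1_used"]][:, qtl_index].astype(float) - 1.0
    d2 = lines2.dosage[vals["lines2_used"]][:, qtl_index].astype(float) - 1.0
    t1, t2, _, _ = ppg_plot_arrays(lines1, lines2, plots, qtl_index)
    if basis == "statistical":
        C1 = 0.5 * (d1 - 2.0 * effects.q1[None, :])
        C2 = 0.25 * (d2 - 2.0 * effects.q2[None, :])
        Ca1p, Ca2p, Cd = plot_covariates_ppg(t1, t2, effects.q1, effects.q2, basis="statistical")
        Cae = Ca1p + Ca2p
        e1, e2, ed, ee = effects.alpha1, effects.alpha2, effects.delta3, effects.alpha_alpha3
    else:
        C1, C2 = 0.5 * d1, 0.25 * d2
        Cd = t_d3(t1, t2)
        Cae = 0.5 * (t1 + t2)
        e1, e2, ed, ee = effects.a, effects.a, effects.d, effects.aa
    additive1 = float(np.sum(np.var(C1, axis=0) * e1**2))
    additive2 = float(np.sum(np.var(C2, axis=0) * e2**2))
    dominance3 = float(np.sum(np.var(Cd, axis=0) * ed**2))
    epistasis3 = 0.0
    if len(pairs):
        k, l = pairs[:, 0], pairs[:, 1]
        m1 = Cae.mean(axis=0)
        m2 = (Cae**2).mean(axis=0)
        var_ep = m2[k] * m2[l] - (m1[k] * m1[l]) ** 2
        epistasis3 = float(np.sum(var_ep * ee**2))
    return VarianceComponents(
        mode=mode, basis=basis,
        additive1=additive1, additive2=additive2,
        dominance3=dominance3, epistasis3=epistasis3,
        residual=None if residual is None else float(np.var(residual)),
    )
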