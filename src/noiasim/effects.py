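"""Simulation of functional QTL effects meeting statistical variance targets.

Two strategies:

* **SS_NOIA** — sample *statistical* effects from prior distributions
  (alpha* ~ N(0, sigma2_A); dominance degree d_d ~ N(0.19, 0.097) so that
  delta* = d_d * |alpha*| induces directional dominance; (alpha alpha)* ~
  N(0, sigma2_AA)), rescale each class so the base-population statistical
  variance (by locus or by individual) hits the target exactly, then
  back-transform to functional effects with the NOIA left inverse at the
  base-population frequencies. Only defined for single-population (iPG) data:
  for three-way-hybrid (pPG) data the backward transform would return two
  different functional additive effects per QTL, contradicting the
  one-functional-effect-per-locus model.

* **SF_GA** — a real-coded genetic algorithm over candidate functional
  effects (a*, d_d*, (aa)*), scored by the negative summed absolute
  deviations of the implied base-population statistical variances from the
  targets. Candidates pass through a Lamarckian "rescale repair" step that
  jointly scales the three effect classes onto (or as close as possible to)
  the target-variance manifold in closed form, leaving the GA to optimize
  the allocation of effects across loci — the part that matters when two
  parental populations must realize different additive variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng
from .genome import GenomeMap, Population
from .models import FunctionalEffects, GAConfig, StatisticalEffectsIPG, VarianceTargets
from .noia import Anchor
from .variance import (
    IpgTransformContext,
    PpgTransformContext,
    genetic_values_ipg,
    ppg_plot_arrays,
    variance_by_individual,
    variance_by_locus_ipg,
)

DOMINANCE_DEGREE_MEAN = 0.19
DOMINANCE_DEGREE_VAR = 0.097


class UnsupportedSetting(ValueError):
    """The requested method/mode combination is not defined for the data type."""


# ---------------------------------------------------------------------------
# Rescaling
# ---------------------------------------------------------------------------


def rescale_to_target(effects: np.ndarray, prior_variance: float, target_variance: float) -> np.ndarray:
    """Scale an effect vector by sqrt(target/prior) so its variance class hits
    the target exactly. A zero target zeroes the vector."""
    effects = np.asarray(effects, dtype=float)
    if target_variance == 0:
        return np.zeros_like(effects)
    if prior_variance <= 0:
        raise ValueError("prior variance is zero but the target is positive")
    return effects * np.sqrt(target_variance / prior_variance)


# ---------------------------------------------------------------------------
# iPG fitness / anchoring context
# ---------------------------------------------------------------------------


class IpgAnchorContext:
    """Base-population anchoring for iPG effect simulation.

    Precomputes the NOIA transforms and whatever the variance mode needs:
    per-locus covariate class variances (by_locus) or the covariate matrices
    over base individuals (by_individual).
    """

    def __init__(self, base: Population, genome: GenomeMap, mode: str, basis: str = "genotype"):
        self.genome = genome
        self.mode = mode
        self.qtl = np.asarray(genome.qtl_index, dtype=int)
        self.pairs = np.asarray(genome.pair_list, dtype=int).reshape(-1, 2)
        self.dosage = base.dosage[:, self.qtl]
        self.anchor = Anchor.from_population(self.dosage, basis=basis)
        self.ctx = IpgTransformContext(self.anchor, self.pairs, len(self.qtl))

    def statistical_variances(self, alpha, delta, aas):
        stats = StatisticalEffectsIPG(alpha, delta, aas, self.anchor)
        if self.mode == "by_locus":
            vc = variance_by_locus_ipg(stats, pairs=self.pairs)
        else:
            u, v, uu = genetic_values_ipg(self.dosage, stats, self.pairs)
            vc = variance_by_individual(u, v, uu)
        return vc.additive, vc.dominance, vc.epistasis


def ss_noia(base: Population, genome: GenomeMap, targets: VarianceTargets, seed: int = 0,
            basis: str = "genotype", max_rescale_iter: int = 5) -> FunctionalEffects:
    """Sample statistical effects, rescale to the targets, back-transform.

    The rescaling loop iterates the three per-class rescalings to a fixed
    point; because each statistical variance class depends only on its own
    effects, the loop converges at the first iteration in both modes.
    """
    if targets.is_ppg:
        raise UnsupportedSetting(
            "SS_NOIA is undefined for pPG targets: the backward NOIA transform "
            "would yield two functional additive effects per QTL"
        )
    ac = IpgAnchorContext(base, genome, targets.mode, basis)
    rng = child_rng(seed, "ss-noia")
    L, P = len(ac.qtl), len(ac.pairs)
    alpha = rng.normal(0.0, np.sqrt(targets.additive), L) if targets.additive else np.zeros(L)
    dd = rng.normal(DOMINANCE_DEGREE_MEAN, np.sqrt(DOMINANCE_DEGREE_VAR), L)
    delta = dd * np.abs(alpha) if targets.dominance else np.zeros(L)
    if targets.dominance and not targets.additive:
        # dominance without additive variance: fall back to direct sampling
        delta = rng.normal(0.0, np.sqrt(targets.dominance), L)
    aas = rng.normal(0.0, np.sqrt(targets.epistasis), P) if targets.epistasis else np.zeros(P)
    for _ in range(max_rescale_iter):
        A, D, AA = ac.statistical_variances(alpha, delta, aas)
        alpha = rescale_to_target(alpha, A, targets.additive)
        delta = rescale_to_target(delta, D, targets.dominance)
        aas = rescale_to_target(aas, AA, targets.epistasis)
        A, D, AA = ac.statistical_variances(alpha, delta, aas)
        if (abs(A - targets.additive) + abs(D - targets.dominance)
                + abs(AA - targets.epistasis)) < 1e-8 * max(targets.total(), 1.0):
            break
    func = ac.ctx.backward(alpha, delta, aas)
    func.dd = np.divide(func.d, np.abs(func.a), out=np.zeros_like(func.d),
                        where=np.abs(func.a) > 0)
    return func


# ---------------------------------------------------------------------------
# Fitness functions
# ---------------------------------------------------------------------------


def _quad_coeffs(x, y):
    """Coefficients of var(s*x + y) = s^2*a + 2s*b + c for centered moments."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ xc / len(x)), float(xc @ yc / len(x)), float(yc @ yc / len(x))


class _IpgEvaluator:
    """Fitness and repair machinery for iPG SF_GA."""

    def __init__(self, base, genome, targets: VarianceTargets, basis="genotype"):
        if targets.is_ppg:
            raise UnsupportedSetting("iPG fitness requires iPG targets")
        self.targets = targets
        self.ac = IpgAnchorContext(base, genome, targets.mode, basis)
        self.pairs = self.ac.pairs
        if targets.mode == "by_locus":
            _, _, ha, hd, _ = self.ac.anchor.class_covariates()
            freqs = self.ac.anchor.geno
            m1a = (freqs * ha).sum(1)
            m2a = (freqs * ha**2).sum(1)
            self.var_a = m2a - m1a**2
            m1d = (freqs * hd).sum(1)
            self.var_d = (freqs * hd**2).sum(1) - m1d**2
            if len(self.pairs):
                k, l = self.pairs[:, 0], self.pairs[:, 1]
                self.var_ep = m2a[k] * m2a[l] - (m1a[k] * m1a[l]) ** 2
            else:
                self.var_ep = np.zeros(0)
        else:
            from .noia import statistical_covariates_ipg
            self.Ha, self.Hd = statistical_covariates_ipg(self.ac.dosage, self.ac.anchor)
            if len(self.pairs):
                self.Hep = self.Ha[:, self.pairs[:, 0]] * self.Ha[:, self.pairs[:, 1]]
            else:
                self.Hep = np.zeros((self.ac.dosage.shape[0], 0))

    # linear decomposition: alpha = alpha(a) + alpha(d) + alpha(aa)
    def alpha_parts(self, a, d, aa):
        z = np.zeros_like(a)
        zp = np.zeros_like(aa)
        return (
            self.ac.ctx.forward(a, z, zp).alpha,
            self.ac.ctx.forward(z, d, zp).alpha,
            self.ac.ctx.forward(z, z, aa).alpha,
        )

    def variances(self, alpha, delta, aas):
        if self.targets.mode == "by_locus":
            return (
                float(np.sum(self.var_a * alpha**2)),
                float(np.sum(self.var_d * delta**2)),
                float(np.sum(self.var_ep * aas**2)),
            )
        u = self.Ha @ alpha
        v = self.Hd @ delta
        uu = self.Hep @ aas
        return float(np.var(u)), float(np.var(v)), float(np.var(uu))

    def fitness_of(self, A, D, AA):
        t = self.targets
        return -(abs(A - t.additive) + abs(D - t.dominance) + abs(AA - t.epistasis))

    def evaluate(self, a, dd, aa, repair=True):
        """Return (fitness, repaired a, dd, aa)."""
        d = dd * np.abs(a)
        ax, dx, ex = self.alpha_parts(a, d, aa)
        D0 = self.variances(np.zeros_like(ax), d, aa)[1]
        AA0 = self.variances(ax, d, aa)[2] if len(aa) else 0.0
        if not repair:
            alpha = ax + dx + ex
            A, D, AA = self.variances(alpha, d, aa)
            return self.fitness_of(A, D, AA), a, dd, aa
        t = self.targets
        s_aa = 0.0 if t.epistasis == 0 else (np.sqrt(t.epistasis / AA0) if AA0 > 0 else 1.0)
        k_d = 0.0 if t.dominance == 0 else (np.sqrt(t.dominance / D0) if D0 > 0 else 1.0)
        # additive variance as a quadratic in the a-block scale s
        if self.targets.mode == "by_locus":
            w = np.sqrt(self.var_a)
            x, y = w * ax, w * (k_d * dx + s_aa * ex)
            qa, qb, qc = float(x @ x), float(x @ y), float(y @ y)
        else:
            qa, qb, qc = _quad_coeffs(self.Ha @ ax, self.Ha @ (k_d * dx + s_aa * ex))
        s_a = _solve_scale_quadratic(qa, qb, qc, t.additive)
        a2 = s_a * a
        dd2 = dd * (k_d / s_a) if (s_a > 0 and t.dominance > 0) else np.zeros_like(dd)
        aa2 = s_aa * aa
        alpha = s_a * ax + k_d * dx + s_aa * ex
        A, D, AA = self.variances(alpha, k_d * d, aa2)
        return self.fitness_of(A, D, AA), a2, dd2, aa2


def _solve_scale_quadratic(qa, qb, qc, target):
    """Smallest positive s with qa*s^2 + 2*qb*s + qc = target, or the
    feasibility-maximizing s when the target is unreachable."""
    if qa <= 0:
        return 1.0
    disc = qb**2 - qa * (qc - target)
    if disc >= 0:
        roots = [(-qb + np.sqrt(disc)) / qa, (-qb - np.sqrt(disc)) / qa]
        pos = [r for r in roots if r > 0]
        if pos:
            return min(pos, key=lambda r: abs(np.log(max(r, 1e-12))))
    s = -qb / qa  # vertex: closest approach
    return s if s > 0 else 1.0


class _PpgEvaluator:
    """Fitness and repair machinery for pPG SF_GA (by-individual mode only)."""

    def __init__(self, base1, base2, base_plots, genome, targets: VarianceTargets):
        if not targets.is_ppg:
            raise UnsupportedSetting("pPG fitness requires pPG targets")
        if targets.mode != "by_individual":
            raise UnsupportedSetting(
                "pPG effect search is only defined with variance by individual; "
                "the by-locus condition admits no solution"
            )
        self.targets = targets
        self.qtl = np.asarray(genome.qtl_index, dtype=int)
        self.pairs = np.asarray(genome.pair_list, dtype=int).reshape(-1, 2)
        d1 = base1.dosage[:, self.qtl].astype(float)
        d2 = base2.dosage[:, self.qtl].astype(float)
        self.q1 = d1.mean(0) / 2.0
        self.q2 = d2.mean(0) / 2.0
        self.ctx = PpgTransformContext(self.q1, self.q2, self.pairs, len(self.qtl))
        # line-level additive covariates; plot-level dominance/epistasis covariates
        self.C1 = 0.5 * ((d1 - 1.0) - 2.0 * self.q1[None, :])
        self.C2 = 0.25 * ((d2 - 1.0) - 2.0 * self.q2[None, :])
        t1, t2, _, _ = ppg_plot_arrays(base1, base2, base_plots, self.qtl)
        from .noia import plot_covariates_ppg
        Ca1, Ca2, self.Cd = plot_covariates_ppg(t1, t2, self.q1, self.q2, "statistical")
        Cae = Ca1 + Ca2
        if len(self.pairs):
            self.Cep = Cae[:, self.pairs[:, 0]] * Cae[:, self.pairs[:, 1]]
        else:
            self.Cep = np.zeros((base_plots.n, 0))

    def parts(self, a, d, aa):
        z = np.zeros_like(a)
        zp = np.zeros_like(aa)
        fa = self.ctx.forward(a, z, zp)
        fd = self.ctx.forward(z, d, zp)
        fe = self.ctx.forward(z, z, aa)
        return fa, fd, fe

    def fitness_of(self, A1, A2, D3, AA3):
        t = self.targets
        return -(abs(A1 - t.additive1) + abs(A2 - t.additive2)
                 + abs(D3 - t.dominance3) + abs(AA3 - t.epistasis3))

    def evaluate(self, a, dd, aa, repair=True):
        d = dd * np.abs(a)
        fa, fd, fe = self.parts(a, d, aa)
        t = self.targets
        v3 = self.Cd @ d  # delta3 = d exactly
        uu3 = self.Cep @ aa
        D0 = float(np.var(v3))
        AA0 = float(np.var(uu3)) if len(aa) else 0.0
        u1a, u1d, u1e = self.C1 @ fa.alpha1, self.C1 @ fd.alpha1, self.C1 @ fe.alpha1
        u2a, u2d, u2e = self.C2 @ fa.alpha2, self.C2 @ fd.alpha2, self.C2 @ fe.alpha2
        if not repair:
            A1, A2 = float(np.var(u1a + u1d + u1e)), float(np.var(u2a + u2d + u2e))
            return self.fitness_of(A1, A2, D0, AA0), a, dd, aa
        s_aa = 0.0 if t.epistasis3 == 0 else (np.sqrt(t.epistasis3 / AA0) if AA0 > 0 else 1.0)
        k_d = 0.0 if t.dominance3 == 0 else (np.sqrt(t.dominance3 / D0) if D0 > 0 else 1.0)
        qa1 = _quad_coeffs(u1a, k_d * u1d + s_aa * u1e)
        qa2 = _quad_coeffs(u2a, k_d * u2d + s_aa * u2e)
        s_a = self._best_scale(qa1, qa2)
        a2 = s_a * a
        dd2 = dd * (k_d / s_a) if (s_a > 0 and t.dominance3 > 0) else np.zeros_like(dd)
        aa2 = s_aa * aa
        A1 = qa1[0] * s_a**2 + 2 * qa1[1] * s_a + qa1[2]
        A2 = qa2[0] * s_a**2 + 2 * qa2[1] * s_a + qa2[2]
        f = self.fitness_of(A1, A2, k_d**2 * D0 if t.dominance3 else 0.0,
                            s_aa**2 * AA0 if t.epistasis3 else 0.0)
        return f, a2, dd2, aa2

    def _best_scale(self, qa1, qa2):
        """1-D minimization of |A1(s)-T1| + |A2(s)-T2| over candidate points."""
        t = self.targets
        cands = [1.0]
        for (qa, qb, qc), T in ((qa1, t.additive1), (qa2, t.additive2)):
            if qa > 0:
                disc = qb**2 - qa * (qc - T)
                if disc >= 0:
                    cands += [(-qb + np.sqrt(disc)) / qa, (-qb - np.sqrt(disc)) / qa]
                cands.append(-qb / qa)
        cands = np.array([c for c in cands if c > 0] or [1.0])
        A1 = qa1[0] * cands**2 + 2 * qa1[1] * cands + qa1[2]
        A2 = qa2[0] * cands**2 + 2 * qa2[1] * cands + qa2[2]
        obj = np.abs(A1 - t.additive1) + np.abs(A2 - t.additive2)
        return float(cands[np.argmin(obj)])


def fitness_ipg(a, dd, aa, base: Population, genome: GenomeMap, targets: VarianceTargets,
                basis: str = "genotype") -> float:
    """f_iPG = -|sigma2_A* - sigma2_A| - |sigma2_D* - sigma2_D| - |sigma2_AA* - sigma2_AA|
    for candidate functional effects (a*, d_d*, (aa)*) with d* = d_d* |a*|."""
    ev = _IpgEvaluator(base, genome, targets, basis)
    f, *_ = ev.evaluate(np.asarray(a, float), np.asarray(dd, float), np.asarray(aa, float),
                        repair=False)
    return f


def fitness_ppg(a, dd, aa, base1, base2, base_plots, genome, targets: VarianceTargets) -> float:
    """f_pPG with four absolute-deviation terms over sigma2_A1, sigma2_A2,
    sigma2_D3, sigma2_AA3, computed by individual on the base plot set."""
    ev = _PpgEvaluator(base1, base2, base_plots, genome, targets)
    f, *_ = ev.evaluate(np.asarray(a, float), np.asarray(dd, float), np.asarray(aa, float),
                        repair=False)
    return f


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class SFGAResult:
    effects: FunctionalEffects
    fitness: float
    converged: bool
    generations: int
    history: list = field(default_factory=list)


def sf_ga_optimize(base, genome: GenomeMap, targets: VarianceTargets, ga: GAConfig = None,
                   base2=None, base_plots=None, basis: str = "genotype") -> SFGAResult:
    """Genetic-algorithm search for functional effects meeting the targets.

    Real-coded GA: tournament selection, blend crossover, per-gene Gaussian
    mutation, elitism, and (by default) a Lamarckian closed-form rescale
    repair of every candidate. Initial candidates are sampled like the
    SS_NOIA priors. Terminates when the best fitness reaches
    -tolerance_frac * (summed targets) or the generation budget is exhausted
    (the best candidate is then returned with converged=False).
    """
    ga = ga or GAConfig()
    rng = child_rng(ga.seed, "sf-ga")
    if targets.is_ppg:
        if base2 is None or base_plots is None:
            raise UnsupportedSetting("pPG optimization needs base2 and a base plot set")
        ev = _PpgEvaluator(base, base2, base_plots, genome, targets)
        sd_a = np.sqrt(targets.additive1 + targets.additive2)
        sd_aa = np.sqrt(targets.epistasis3) if targets.epistasis3 else 0.0
    else:
        ev = _IpgEvaluator(base, genome, targets, basis)
        sd_a = np.sqrt(targets.additive) if targets.additive else 1.0
        sd_aa = np.sqrt(targets.epistasis) if targets.epistasis else 0.0
    L, P = genome.n_qtl, genome.n_pairs
    n_pop = ga.population_size
    tol = ga.tolerance_frac * targets.total()
    sd_dd = np.sqrt(DOMINANCE_DEGREE_VAR)
    mut_sd = np.concatenate([
        np.full(L, ga.mutation_scale * sd_a),
        np.full(L, ga.mutation_scale * sd_dd),
        np.full(P, ga.mutation_scale * (sd_aa if sd_aa else 1.0)),
    ])

    def split(theta):
        return theta[:L], theta[L:2 * L], theta[2 * L:]

    pop = np.empty((n_pop, 2 * L + P))
    pop[:, :L] = rng.normal(0.0, sd_a, (n_pop, L))
    pop[:, L:2 * L] = rng.normal(DOMINANCE_DEGREE_MEAN, sd_dd, (n_pop, L))
    pop[:, 2 * L:] = rng.normal(0.0, sd_aa, (n_pop, P)) if sd_aa else 0.0

    n_elite = max(1, int(round(ga.elitism_frac * n_pop)))
    best_theta, best_f = None, -np.inf
    history = []
    gen = 0
    for gen in range(ga.max_generations + 1):
        fits = np.empty(n_pop)
        for i in range(n_pop):
            a, dd, aa = split(pop[i])
            f, a2, dd2, aa2 = ev.evaluate(a, dd, aa, repair=ga.repair)
            fits[i] = f
            if ga.repair:
                pop[i] = np.concatenate([a2, dd2, aa2])
        order = np.argsort(fits)[::-1]
        if fits[order[0]] > best_f:
            best_f = fits[order[0]]
            best_theta = pop[order[0]].copy()
        history.append(best_f)
        if best_f >= -tol or gen == ga.max_generations:
            break
        # next generation
        elite = pop[order[:n_elite]]
        n_child = n_pop - n_elite
        # tournament selection (size 3)
        t_idx = rng.integers(0, n_pop, (2 * n_child, 3))
        winners = t_idx[np.arange(2 * n_child), np.argmax(fits[t_idx], axis=1)]
        p1, p2 = pop[winners[:n_child]], pop[winners[n_child:]]
        u = rng.uniform(-0.25, 1.25, p1.shape)
        cross = rng.random(n_child) < ga.crossover_prob
        child = np.where(cross[:, None], u * p1 + (1 - u) * p2, p1)
        mut = rng.random(child.shape) < ga.mutation_prob
        child = child + mut * rng.normal(0.0, 1.0, child.shape) * mut_sd[None, :]
        pop = np.vstack([elite, child])

    a, dd, aa = split(best_theta)
    func = FunctionalEffects(a=a, d=dd * np.abs(a), aa=aa, dd=dd)
    return SFGAResult(effects=func, fitness=float(best_f),
                      converged=bool(best_f >= -tol), generations=gen, history=history)
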