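# Methods

## The problem

Stochastic simulators of breeding programs transmit *functional* locus effects
through Mendelian inheritance: each QTL j carries an additive value a_j and a
dominance value d_j, and each interacting pair (k, l) an additive-by-additive
value (aa)_kl, acting on genotype covariates that depend only on the genotype
(t^a = -1/0/1, t^d = 0/1/0 for BB/Bb/bb, t^ep = t^a_k t^a_l). Breeders,
however, specify the populations they want by *statistical* variance
components (sigma2_A, sigma2_D, sigma2_AA) estimated from orthogonal
regression (snpBLUP/GBLUP-type) models whose covariates h^a, h^d, h^ep are
anchored to allele or genotype frequencies. With any dominance or epistasis
the two parameterizations differ — part of the functional dominance and
epistasis appears as additive substitution effect at the population level —
so sampling functional effects directly from the target variances produces
populations with the wrong statistical properties. This package constructs
functional effect sets whose implied statistical variances match the targets
in a base population, and verifies that descendant populations bred from that
base still (approximately) realize them.

## Covariates and the NOIA transform

Statistical covariates per locus: h^a = dosage - 2q (allele-frequency form)
or dosage - p_Bb - 2 p_bb (genotype-frequency form; the two coincide when q
is the observed frequency); h^d = (-2q^2, 2pq, -2p^2) under HWE, or the
genotype-frequency three-case form with shared denominator
p_BB + p_bb - (p_BB - p_bb)^2 otherwise. The genotype-frequency form is the
default whenever the population is not guaranteed to be in HWE (descendant
generations, pooled generations, inbred lines); with it h^a and h^d have
weighted mean zero and are weighted-orthogonal for *any* genotype
distribution. Fixed loci (q in {0, 1}) define h^a = h^d = 0 rather than
erroring, so loci drifted to fixation are handled; they contribute no
variance.

For a locus pair, functional and statistical effect vectors (dimension 6:
mu, a_k, a_l, d_k, d_l, (aa)) are linked through 9 x 6 design matrices over
the 9 joint genotype classes (locus-k index fastest):
E_s = (W_s' W_s)^(-1) W_s' W_f E_f, and the reverse with W_f and W_s
exchanged. Because the two matrices span the same column space the projection
is exact: the round trip is the identity, a diagonal genotype-frequency
weight matrix cancels, delta = d and (alpha alpha) = (aa) always, and the
additive substitution effect obeys the closed form
alpha_k = a_k + (1 - 2 q_k) d_k + (aa)^k_kl, where the epistatic contribution
comes from transforming E_f = (1, 0, 0, 0, 0, (aa)). All of these are tested
to 1e-10.

### Three-way hybrid (plot) layout

For plot phenotypes of three-way hybrids, a locus has 15 plot states: the
population-1 parental genotype t1 in {-1, 0, 1} crossed with the two-way
parental dosage t2 in {-1, -0.5, 0, 0.5, 1} (t2 is exactly the mean of the
two grandparental line codes; no hybrid genotypes are simulated). The plot
covariates are (t1 + t2)/2 for additive, the expected plot heterozygosity
t^d_3 = [(1 - t1)(t2 + 1) + (t1 + 1)(1 - t2)]/4 for dominance, and the
product of the additive covariates for epistasis; their statistical
counterparts are h_1 = t1 - 2 q1, h_2 = t2 - 2 q2 and the generalized plot
dominance element h^d_3 (a four-term expression in the two populations'
allele frequencies that reduces to the classical single-cross dominance
codings when both parents are fully inbred). A pair of loci therefore spans
15 x 15 = 225 joint states, and the pair design matrices are 225 x 8 with
effect vectors (mu, alpha_k1, alpha_l1, alpha_k2, alpha_l2, delta_k3,
delta_l3, (alpha alpha)_3); the functional vector repeats a_k and a_l because
the same functional additive effect underlies both parental origins. The
same exact-projection properties hold (round trip, delta_3 = d,
(alpha alpha)_3 = (aa)); they are what validates this joint-state layout.
Anchoring frequencies for the plot model are always those of the two inbred
base populations.

## Variances

Two approximations are computed, each tagged with its mode and basis:

* **by individual** — population variance (divisor n) of per-individual
  summed values u_i = sum_j h^a alpha (and v_i, (uu)_i analogously); captures
  linkage-disequilibrium and family covariances.
* **by locus** — sum over loci of the genotype-class variance of the locus
  covariate times the squared effect; assumes linkage equilibrium. Under HWE
  the additive term is 2 p q alpha^2, the dominance term (2pq)^2 delta^2 and
  the pair term 4 p_k q_k p_l q_l (aa)^2 (tested against brute-force
  three-genotype expectations).

For plot data the by-individual additive components are defined per *line*:
sigma2_A1 is the variance over population-1 lines of sum_j (h_1/2) alpha_1,
and sigma2_A2 the variance over population-2 lines of sum_j (h_line/4)
alpha_2 — each plot receives one population-1 line value and the *sum* of its
two grandparental population-2 line values, matching the (Z_a + Z_b) u_2
incidence of the plot GBLUP model. This definition is what makes the
estimated and calculated additive-2 components comparable, and it implies the
characteristic factor of about 4 between sigma2_A1 and sigma2_A2 at equal
substitution effects and frequencies (relationship of a plot to its inbred
parent versus to one grandparent of its two-way parent).

Descendant ("output") variances for individual data re-derive the statistical
effects from the fixed functional effects at the pooled genotype frequencies
of the analyzed generations; the alternative (keeping base anchoring) is
available as an explicit anchor argument. Plot-data variances keep the base
anchoring throughout.

## Effect simulation

**SS_NOIA** samples statistical effects from priors — alpha* ~ N(0, sigma2_A);
dominance degree d_d ~ N(0.19, 0.097) (mean 0.19, variance 0.097), giving
delta* = d_d |alpha*| and hence directional dominance positively coupled to
the additive effect; (alpha alpha)* ~ N(0, sigma2_AA) — rescales each class
by sqrt(target/prior variance) computed on the base population in the chosen
mode, and back-transforms per pair to functional effects at base-population
frequencies. Because each statistical variance class depends only on its own
effect class, one rescaling pass per class is exact (the fixed-point loop in
the code converges at its first iteration); base-population variances match
the targets to machine precision in both modes. SS_NOIA is undefined for the
plot data type: the backward transform would return two different functional
additive effects per QTL, contradicting the single-functional-effect model.

**SF_GA** searches functional-effect space directly with a real-coded genetic
algorithm over the concatenated (a*, d_d*, (aa)*) vector: tournament
selection (size 3), blend crossover, per-gene Gaussian mutation (sigma = 10%
of the prior SD per class), 5% elitism, initial population drawn from the
SS_NOIA priors. Fitness is the negative summed absolute deviation of the
implied base-population statistical variances from the targets (three terms
for individual data, four for plot data). Every candidate passes through a
Lamarckian *rescale repair*: the dominance and epistasis classes are scaled
onto their targets in closed form (their variances are exactly quadratic in
the class scales), and the additive-block scale is then chosen by solving the
resulting scalar quadratic (individual data: exact root when reachable) or a
one-dimensional absolute-deviation minimization (plot data, where additive-1
and additive-2 cannot both be scaled independently). The repair leaves the GA
to optimize what scaling cannot: the allocation of effects across loci, which
is exactly the degree of freedom needed to realize two different additive
variances for the two parental populations of a three-way hybrid program.
With repair the individual-data search typically reaches fitness ~0 within a
couple of generations; plot-data searches converge within tens of
generations. Plot-data fitness is only defined with variance by individual
(the by-locus condition admits no solution); requesting it raises an error.
Termination: best fitness >= -0.1% of the summed targets, or the generation
budget (best candidate returned with a non-convergence flag).

## Genome and breeding simulation

Haplotypes are explicit (n x 2 x L bit arrays). Recombination follows
Haldane's model implemented as a Markov switch chain: between adjacent loci
at map distance d Morgans a gamete switches parental haplotype with
probability (1 - e^(-2d))/2, chromosomes assort independently, and the
chromosome-start haplotype is a fair coin — mathematically identical to
Poisson-distributed crossovers with uniform positions and fully vectorizable.
Linkage-equilibrium mode uses switch probability 1/2 everywhere. No mutation
occurs during breeding; every offspring allele is a parental allele.

Linkage-disequilibrium base populations come from a forward Wright-Fisher
history: founders carry allele b on exactly half the chromosomes at every
locus (all frequencies start at exactly 0.5), then discrete generations of
random union of gametes. QTL are drawn afterwards from loci with minor allele
frequency >= 0.05 (for two diverged populations: in each of them, since a
locus fixed in one population has no statistical anchoring there). Each QTL
belongs to at most one epistatic pair.

Breeding schemes use random selection throughout. Individual data: per
generation, parents sampled uniformly, random sire/dam pairs, fixed offspring
per mating (default 4 generations x 150 matings x 5 offspring = 3000
descendants from a base of 100). Plot data: inbred lines are developed by
four single-seed-descent selfings (pedigree-expected inbreeding
1 - (1/2)^4 = 0.9375), two-way hybrids pair population-2 lines of successive
generations, and three-way plots mate population-1 lines with two-way hybrids
in a balanced design (each line in 5 matings, each hybrid in 10, one plot per
mating; 1000 plots in each of generations 2-4).

Phenotypes are the functional genetic values plus i.i.d. normal residuals; a
plot is treated as infinitely many plants of one mating, so its genetic value
is the exact expectation over offspring genotypes given the parents (verified
against a Monte-Carlo offspring oracle). Truth components are stored with
every record.

## GRMs and AI-REML

Estimation GRMs use the QTL as the marker panel and anchor at the observed
frequencies of the analyzed individuals: G_A = H_a H_a' / (tr/n), G_D
likewise from h^d covariates, G_AA = (G_A o G_A) / (tr/n) (Hadamard square).
Plot data adds G_A1/G_A2 over parental lines (each plot linked to its two
population-2 grandparents by a summed incidence), G_D3 from the generalized
plot dominance covariate, and G_AA3 from plot additive rows built on
parental-line genotype means. Every matrix is blended as 0.95 G + 0.05 I
(configurable). The blend is standard mixed-model practice — G_D and G_AA are
singular whenever markers are fewer than records, and software that inverts G
cannot run without it — and it is scientifically consequential here: the
identity admixture lets the dominance/epistasis components absorb
residual-like variance, which is precisely the estimation behavior (dominance
re-estimated above its input, residual below) that the validation loop is
meant to reproduce. With blend = 0 the internal REML returns an essentially
unbiased residual instead.

Variance components are re-estimated by average-information REML
(y = 1 mu + sum_c Z_c g_c + e, g_c ~ N(0, G_c sigma2_c)): AI updates with
step halving against the exact restricted log-likelihood, an EM-REML fallback
step when the AI direction fails, estimates floored at 1e-8 var(y)
(boundary), convergence on |delta logL| < tol. Single-genetic-component
models take a fast path (one eigendecomposition, O(n) iterations). For dense
multi-component models with n > 1600 the score traces tr(P V_c) use a seeded
Hutchinson estimator (64 Rademacher probes; the log-likelihood, AI matrix and
quadratic forms remain exact), which keeps four-component fits at n = 3000
around 4 s on one core. Standard errors come from the inverse AI matrix.

## Replication design and desk-scale choices

Experiments nest scheme replicates (breeding + phenotype + variance) inside
effect replicates, aggregated as mean ± SD (divisor n - 1). Default replicate
counts are 10 x 2 (individual data) and 5 x 1 (plot data) rather than the
full 30 x 8 replication design. Wright-Fisher histories are scaled by preserving
the drift ratio t/(2N): 200 generations at N = 200 for the
linkage-disequilibrium genome (ratio 0.5, as in a 1000-generation history at
N = 1000), and 150 common + 15 diverged generations at N = 150 for the
two-population case (divergence ratio 0.05). The plot-data genome is scaled
to 300 QTL / 150 pairs on 3 x 400 loci, but the breeding-scheme sizes
(200/100 lines, 1000 plots per generation) are kept at their full design
values because line counts set the per-generation drift and family covariance
that the output variances are compared against; halving them visibly inflates
the descendant dominance variance. Seeds follow a one-master-seed policy with
named child streams per operation, so replicates are individually
reproducible.

## What the generator does and does not emulate

The synthetic populations reproduce drift, recombination-driven LD decay,
directional dominance coupled to additive effect size, pairwise epistasis,
inbreeding under single-seed descent, and the plot-phenotype structure of a
three-way hybrid program. They do not include mutation during breeding,
selection on phenotype, genotype-by-environment interaction, multi-allelic
QTL, markers distinct from QTL, replicated plots or spatial field effects,
or higher-order/dominance-involving epistasis. Passing tests therefore
demonstrate internal consistency of the functional/statistical transformation
machinery under the stated model, not robustness of the method on real data
where those excluded features exist.

## Numerical notes and known limitations

* Transforms at degenerate anchorings (monomorphic loci, zero dominance
  denominator) fall back to the allele-frequency closed form; such loci carry
  zero variance so the choice does not affect variance accounting.
* The by-locus epistatic variance ignores cross-pair covariances (linkage
  equilibrium assumed); under LD the by-locus and by-individual numbers
  legitimately differ, which is a finding the simulator reports rather than
  corrects.
* Sample variances of genetic values use divisor n; replicate aggregation
  uses divisor n - 1. Both are deliberate and documented at the call sites.
* The GA is stochastic; with repair it is robust for the individual-data
  settings, but plot-data targets far from the reachable additive-1/additive-2
  ray (e.g., a single-QTL genome) are provably unattainable and are reported
  with a non-convergence flag rather than an exception.
* Dense REML is capped by memory/time to desk scales (a few thousand
  records); the Hutchinson traces introduce O(1/sqrt(64)) relative noise into
  the scores (not the likelihood), negligible next to the sampling noise of
  the estimates.
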