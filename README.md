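# noiasim

Stochastic quantitative-genetics simulator that generates **functional** QTL
effects — additive (a), dominance (d) and additive×additive epistasis ((aa)) —
such that simulated base *and descendant* populations realize user-specified
**statistical** variance components (σ²_A, σ²_D, σ²_AA), the quantities
breeders actually estimate from orthogonal snpBLUP/GBLUP models.

## Why

Breeding-program simulators transmit functional locus effects through
Mendelian inheritance, but the parameters users have in hand are statistical
variance components from population-level models. With dominance or epistasis
the two parameterizations differ: a locus' substitution effect is

    α_j = a_j + (1 − 2 q_j) d_j + (αα)^j ,

i.e. part of the functional dominance and epistasis shows up as additive
substitution effect, with weights set by allele frequencies. Sampling
functional effects naively from the target variances therefore produces
populations with the wrong statistical properties. `noiasim` solves the
inverse problem with the NOIA (natural and orthogonal interactions) design-
matrix algebra, which links the two effect bases exactly over the joint
genotype classes of each locus pair:

    E_s = (W_s′ W_s)⁻¹ W_s′ W_f E_f        (and the reverse direction)

Two simulation strategies are provided:

* **SS_NOIA** — sample statistical effects (α\* ~ N(0, σ²_A); dominance degree
  d_d ~ N(0.19, 0.097) with δ\* = d_d·|α\*|; (αα)\* ~ N(0, σ²_AA)), rescale each
  class to hit the targets exactly in the base population (by locus or by
  individual), back-transform to functional effects.
* **SF_GA** — a real-coded genetic algorithm over candidate functional
  effects, scored by the deviation of the implied base-population statistical
  variances from the targets, with a closed-form rescale repair step. This is
  the route for three-way hybrid (plot-phenotype) data, where the two parental
  populations must explain *different* additive variances (σ²_A,1, σ²_A,2)
  while sharing one functional effect per QTL.

Around the core the package provides a haplotype-level genome simulator
(linkage-equilibrium bases, forward Wright–Fisher LD genomes, Haldane
recombination, selfing / single-seed descent, random-mating and three-way
hybrid crop breeding schemes), phenotype generation with truth tracking,
genomic relationship matrices (G_A, G_D = dominance, G_AA = Hadamard square;
plot-data variants including a generalized hybrid dominance relationship), and
an internal average-information REML to close the validation loop:
simulate → breed → re-estimate.

## Worked example

Simulate the individual-phenotype design: 100 base individuals, 2000 QTL in
1000 epistatic pairs, targets σ²_A = 400, σ²_D = 100, σ²_AA = 100, σ²_e = 100,
then four generations of 150 random matings × 5 offspring:

```python
import numpy as np
from noiasim import (uniform_genome, random_pairs, sample_base_le, ss_noia,
                     run_ipg_scheme, VarianceTargets, derive_statistical_ipg,
                     variance_by_locus_ipg, genetic_values_ipg,
                     variance_by_individual)
from noiasim.noia import Anchor

genome = uniform_genome(1, 100.0, 2000, seed=1)
genome.qtl_index = np.arange(2000)
genome.pair_list = random_pairs(2000, 1000, seed=1)
base = sample_base_le(100, genome, 0.05, 0.95, seed=1)

targets = VarianceTargets.ipg(400, 100, 100, 100, mode="by_locus")
func = ss_noia(base, genome, targets, seed=1)   # functional effects

anchor0 = Anchor.from_population(base.dosage, basis="genotype")
stats0 = derive_statistical_ipg(func, anchor0, genome.pair_list)
v0 = variance_by_locus_ipg(stats0, pairs=genome.pair_list)
print(f"base by-locus:      A={v0.additive:.1f}  D={v0.dominance:.1f}  AA={v0.epistasis:.1f}")

pop = run_ipg_scheme(base, genome, generations=4, n_parents=150,
                     n_matings=150, offspring_per_mating=5, mode="le", seed=1)
desc = np.flatnonzero(pop.generation >= 1)
anchor = Anchor.from_population(pop.dosage, subset=desc, basis="genotype")
stats = derive_statistical_ipg(func, anchor, genome.pair_list)
v1 = variance_by_locus_ipg(stats, pairs=genome.pair_list)
u, v, uu = genetic_values_ipg(pop.dosage[desc][:, genome.qtl_index],
                              stats, genome.pair_list)
v2 = variance_by_individual(u, v, uu)
print(f"gens 1-4 by-locus:  A={v1.additive:.1f}  D={v1.dominance:.1f}  AA={v1.epistasis:.1f}")
print(f"gens 1-4 by-indiv:  A={v2.additive:.1f}  D={v2.dominance:.1f}  AA={v2.epistasis:.1f}")
```

prints

```
base by-locus:      A=400.0  D=100.0  AA=100.0
gens 1-4 by-locus:  A=410.0  D=103.1  AA=99.5
gens 1-4 by-indiv:  A=423.5  D=126.9  AA=101.6
```

The base population realizes the inputs exactly (SS_NOIA rescales to machine
precision). After four generations of drift the by-locus variances stay close
to the inputs, while the by-individual dominance variance is inflated by
full-sib covariance — the characteristic pattern of this design. The same
functional effects drive any descendant genotype: no re-anchoring is needed to
simulate phenotypes, only to *interpret* them statistically.

Replicated table-style experiments are one call (`noiasim.experiment.
run_experiment`) or one CLI invocation (`noiasim experiment --config cfg.yaml
--seed 1 --out results/`), producing per-replicate and mean ± SD tables for
the estimated, calculated-statistical (by individual / by locus) and
calculated-functional variance rows.

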