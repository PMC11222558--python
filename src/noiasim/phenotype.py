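"""Phenotype generation under the functional genotype-value models.

Individual phenotypes: y_i = mu + sum_j t^a_{j,i} a_j + sum_j t^d_{j,i} d_j
+ sum_pairs t^ep (aa) + e_i, with e ~ N(0, sigma2_e).

Three-way hybrid plot phenotypes: the plot is treated as infinitely many
plants of the same mating, so its genetic value is the expectation over
offspring genotypes given the parents: additive covariate (t1 + t2)/2,
dominance covariate t^d_3 (the plot's expected heterozygosity), epistatic
covariate the product of the two additive covariates. The only noise beyond
the genetics is the plot residual e ~ N(0, sigma2_e).

The realized genetic components (u*, v*, (uu)*) and residual draws are stored
so that estimation bias can be measured against the simulated truth:
phenotype = mu + u* + v* + (uu)* + e holds exactly, record by record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .models import FunctionalEffects
from .noia import t_d3
from .variance import genetic_values_ipg, ppg_plot_arrays


@dataclass
class PhenotypeTable:
    """Phenotypes with retained truth components."""

    y: np.ndarray
    e: np.ndarray
    u: np.ndarray
    v: np.ndarray
    uu: np.ndarray
    generation: np.ndarray
    mu: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": self.generation, "y": self.y, "e": self.e,
             "u_star": self.u, "v_star": self.v, "uu_star": self.uu}
        )


def simulate_phenotypes_ipg(pop, genome, effects: FunctionalEffects, sigma2_e: float,
                            mu: float = 0.0, seed: int = 0, subset=None) -> PhenotypeTable:
    """Individual phenotypes from functional effects."""
    if sigma2_e < 0:
        raise ValueError("residual variance must be >= 0")
    idx = np.arange(pop.n) if subset is None else np.asarray(subset)
    dosage = pop.dosage[idx][:, genome.qtl_index]
    u, v, uu = genetic_values_ipg(dosage, effects, genome.pair_list)
    rng = child_rng(seed, "phenotypes-ipg")
    e = rng.normal(0.0, np.sqrt(sigma2_e), len(idx))
    return PhenotypeTable(y=mu + u + v + uu + e, e=e, u=u, v=v, uu=uu,
                          generation=pop.generation[idx], mu=mu)


def simulate_phenotypes_ppg(plots, lines1, lines2, genome, effects: FunctionalEffects,
                            sigma2_e: float, mu: float = 0.0, seed: int = 0) -> PhenotypeTable:
    """Three-way hybrid plot phenotypes from functional effects."""
    if sigma2_e < 0:
        raise ValueError("residual variance must be >= 0")
    qtl = np.asarray(genome.qtl_index, dtype=int)
    pairs = np.asarray(genome.pair_list, dtype=int).reshape(-1, 2)
    t1, t2, _, _ = ppg_plot_arrays(lines1, lines2, plots, qtl)
    Ca = 0.5 * (t1 + t2)
    u = Ca @ effects.a
    v = t_d3(t1, t2) @ effects.d
    if len(pairs):
        uu = (Ca[:, pairs[:, 0]] * Ca[:, pairs[:, 1]]) @ effects.aa
    else:
        uu = np.zeros(plots.n)
    rng = child_rng(seed, "phenotypes-ppg")
    e = rng.normal(0.0, np.sqrt(sigma2_e), plots.n)
    return PhenotypeTable(y=mu + u + v + uu + e, e=e, u=u, v=v, uu=uu,
                          generation=plots.generation, mu=mu)
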