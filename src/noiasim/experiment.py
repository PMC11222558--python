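"""End-to-end pipeline drivers: the three worked examples, with nested
replication (outer loop over effect simulations, inner loop over breeding
scheme + phenotype + variance runs) and mean +/- SD aggregation.

Example 1 — individual phenotypes, linkage-equilibrium genome: 100 base
individuals, 2000 QTL (1000 epistatic pairs), four generations of 150 random
matings x 5 offspring (3000 descendants).

Example 2 — as Example 1 but on a linkage-disequilibrium genome built by a
forward Wright-Fisher history; QTL drawn from loci with MAF >= 0.05,
inheritance with recombination.

Example 3 — plot phenotypes of three-way hybrids: two diverged inbred base
populations, single-seed-descent line development, two-way and three-way
crossing; SF_GA with variance by individual is the only supported effect
method for this data type.

Default replicate counts (10 x 2) and Wright-Fisher histories are desk-scale
reductions of the full 30 x 8 replication design; population and mating sizes
are kept at their design values because they set the drift and family-
covariance structure of the output variances.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .effects import UnsupportedSetting, sf_ga_optimize, ss_noia
from .genome import (
    GenomeMap,
    Population,
    ThreeWayConfig,
    run_ipg_scheme,
    run_threeway_scheme,
    sample_base_le,
    self_pollinate,
    simulate_diverged_bases,
    simulate_ld_base,
    uniform_genome,
    random_pairs,
)
from .gblup import aireml, build_grms_ipg
from .models import GAConfig, VarianceTargets
from .noia import Anchor
from .phenotype import simulate_phenotypes_ipg, simulate_phenotypes_ppg
from .variance import (
    derive_statistical_ipg,
    derive_statistical_ppg,
    genetic_values_ipg,
    variance_by_individual,
    variance_by_locus_ipg,
    variance_ppg,
)


@dataclass
class ExperimentConfig:
    """Configuration for one replicated simulation experiment."""

    example: int = 1  # 1 | 2 | 3
    method: str = "ss_noia"  # ss_noia | sf_ga
    mode: str = "by_locus"  # by_locus | by_individual
    targets: VarianceTargets = None
    n_effect_replicates: int = 10
    n_scheme_replicates: int = 2
    estimate: bool = False  # REML re-estimation (iPG only)
    seed: int = 0
    mu: float = 0.0
    # genome
    n_qtl: int = 2000
    n_pairs: int = 1000
    n_base: int = 100
    freq_low: float = 0.05
    freq_high: float = 0.95
    n_chromosomes: int = 5
    chrom_length_cm: float = 230.0
    loci_per_chrom: int = 1000
    historical_generations: int = 200
    historical_n: int = 200
    diverge_generations: int = 15
    maf_min: float = 0.05
    # iPG breeding scheme
    generations: int = 4
    n_parents: int = 150
    n_matings: int = 150
    offspring_per_mating: int = 5
    self_generations: int = 4
    # nested settings
    ga: GAConfig = field(default_factory=GAConfig)
    threeway: ThreeWayConfig = field(default_factory=ThreeWayConfig)

    def __post_init__(self):
        if self.targets is None:
            if self.example == 3:
                self.targets = VarianceTargets.ppg(200.0, 37.5, 50.0, 62.5, 100.0,
                                                   mode="by_individual")
            else:
                self.targets = VarianceTargets.ipg(400.0, 100.0, 100.0, 100.0, mode=self.mode)
        if self.n_effect_replicates < 1 or self.n_scheme_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.example == 3:
            if self.method != "sf_ga" or self.targets.mode != "by_individual":
                raise UnsupportedSetting(
                    "pPG (example 3) supports only SF_GA with variance by individual: "
                    "SS_NOIA would yield two functional additive effects per QTL, and "
                    "the by-locus condition admits no solution"
                )
        if self.targets.mode != self.mode:
            self.targets.mode = self.mode


def config_from_dict(raw: dict) -> ExperimentConfig:
    raw = dict(raw)
    if "targets" in raw and isinstance(raw["targets"], dict):
        raw["targets"] = VarianceTargets(**raw["targets"])
    if "ga" in raw and isinstance(raw["ga"], dict):
        raw["ga"] = GAConfig(**raw["ga"])
    if "threeway" in raw and isinstance(raw["threeway"], dict):
        raw["threeway"] = ThreeWayConfig(**raw["threeway"])
    return ExperimentConfig(**raw)


# ---------------------------------------------------------------------------
# Single replicates
# ---------------------------------------------------------------------------


def _ipg_genome_and_base(cfg: ExperimentConfig, seed: int):
    if cfg.example == 1:
        genome = uniform_genome(1, 100.0, cfg.n_qtl, seed=seed)
        genome.qtl_index = np.arange(cfg.n_qtl)
        genome.pair_list = random_pairs(cfg.n_qtl, cfg.n_pairs, seed=seed)
        base = sample_base_le(cfg.n_base, genome, cfg.freq_low, cfg.freq_high, seed=seed)
        return base, genome, "le"
    genome = uniform_genome(cfg.n_chromosomes, cfg.chrom_length_cm, cfg.loci_per_chrom, seed=seed)
    base, genome = simulate_ld_base(
        cfg.n_base, genome, cfg.historical_generations, cfg.historical_n,
        cfg.maf_min, n_qtl=cfg.n_qtl, n_pairs=cfg.n_pairs, seed=seed,
    )
    # downstream breeding only needs the QTL loci
    baseq = Population(base.haplotypes[:, :, genome.qtl_index],
                       base.generation, base.sire, base.dam)
    return baseq, genome.subset_to_qtl(), "ld"


def simulate_ipg_effects(cfg: ExperimentConfig, base, genome, effect_seed: int):
    if cfg.method == "ss_noia":
        return ss_noia(base, genome, cfg.targets, seed=effect_seed), None
    ga = GAConfig(**{**asdict(cfg.ga), "seed": effect_seed})
    res = sf_ga_optimize(base, genome, cfg.targets, ga)
    return res.effects, res


def run_ipg_replicate(cfg: ExperimentConfig, base, genome, mode, func, scheme_seed: int):
    """One breeding + phenotype + variance run for a fixed effect set.

    Calculated variances use data from the descendant generations (1..g):
    statistical effects are re-derived from the functional effects at the
    pooled descendant genotype frequencies.
    """
    pop = run_ipg_scheme(base, genome, cfg.generations, cfg.n_parents, cfg.n_matings,
                         cfg.offspring_per_mating, mode=mode, seed=scheme_seed)
    desc = np.flatnonzero(pop.generation >= 1)
    ph = simulate_phenotypes_ipg(pop, genome, func, cfg.targets.residual, mu=cfg.mu,
                                 seed=scheme_seed, subset=desc)
    dosage = pop.dosage[desc][:, genome.qtl_index]
    anchor = Anchor.from_population(dosage, basis="genotype")
    stats = derive_statistical_ipg(func, anchor, genome.pair_list)
    rows = {}
    vl = variance_by_locus_ipg(stats, pairs=genome.pair_list, residual=ph.e)
    rows["calc_stat_by_locus"] = vl
    u, v, uu = genetic_values_ipg(dosage, stats, genome.pair_list)
    rows["calc_stat_by_individual"] = variance_by_individual(u, v, uu, residual=ph.e)
    uf, vf, uuf = genetic_values_ipg(dosage, func, genome.pair_list)
    rows["calc_func_by_individual"] = variance_by_individual(uf, vf, uuf, residual=ph.e,
                                                             basis="functional")
    if cfg.estimate:
        grms = build_grms_ipg(dosage)
        reml = aireml(ph.y, grms, tol=1e-4)
        rows["estimated"] = reml
    return rows


def run_ppg_replicate(cfg: ExperimentConfig, b1, b2, genome, q1, q2, func, scheme_seed: int):
    res3 = run_threeway_scheme(b1, b2, genome, cfg.threeway, seed=scheme_seed)
    ph = simulate_phenotypes_ppg(res3.plots, res3.lines1, res3.lines2, genome, func,
                                 cfg.targets.residual, mu=cfg.mu, seed=scheme_seed)
    stats = derive_statistical_ppg(func, q1, q2, genome.pair_list)
    rows = {}
    rows["calc_stat_by_individual"] = variance_ppg(
        stats, res3.lines1, res3.lines2, res3.plots, genome.qtl_index,
        genome.pair_list, mode="by_individual", residual=ph.e)
    rows["calc_stat_by_locus"] = variance_ppg(
        stats, res3.lines1, res3.lines2, res3.plots, genome.qtl_index,
        genome.pair_list, mode="by_locus", residual=ph.e)
    rows["calc_func_by_individual"] = variance_ppg(
        func, res3.lines1, res3.lines2, res3.plots, genome.qtl_index,
        genome.pair_list, mode="by_individual", residual=ph.e)
    return rows


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

_IPG_COMPONENTS = ("additive", "epistasis", "dominance", "residual")
_PPG_COMPONENTS = ("additive1", "additive2", "dominance3", "epistasis3", "residual")


def _flatten(rows: dict, effect_rep: int, scheme_rep: int, components):
    out = []
    for quantity, vc in rows.items():
        if quantity == "estimated":
            vals = vc.estimates
        else:
            vals = vc.as_dict()
        for comp in components:
            if comp in vals and vals[comp] is not None:
                out.append({"effect_rep": effect_rep, "scheme_rep": scheme_rep,
                            "quantity": quantity, "component": comp,
                            "value": float(vals[comp])})
    return out


def run_experiment(cfg: ExperimentConfig):
    """Nested-replication experiment; returns (per-replicate DataFrame,
    aggregated DataFrame with mean and SD per quantity x component)."""
    master = child_rng(cfg.seed, "experiment", cfg.example, cfg.method, cfg.mode)
    records = []
    components = _PPG_COMPONENTS if cfg.example == 3 else _IPG_COMPONENTS
    for er in range(cfg.n_effect_replicates):
        eseed = int(master.integers(2**31 - 1))
        if cfg.example == 3:
            genome0 = uniform_genome(cfg.n_chromosomes, cfg.chrom_length_cm,
                                     cfg.loci_per_chrom, seed=eseed)
            p1, p2, genome0 = simulate_diverged_bases(
                cfg.n_base, cfg.n_base, genome0, cfg.historical_generations,
                cfg.diverge_generations, cfg.historical_n, cfg.maf_min,
                n_qtl=cfg.n_qtl, n_pairs=cfg.n_pairs, seed=eseed)
            genome = genome0.subset_to_qtl()
            h1 = p1.haplotypes[:, :, genome0.qtl_index]
            h2 = p2.haplotypes[:, :, genome0.qtl_index]
            b1 = Population.from_haplotypes(
                self_pollinate(h1, genome, cfg.self_generations, mode="ld", seed=eseed + 1))
            b2 = Population.from_haplotypes(
                self_pollinate(h2, genome, cfg.self_generations, mode="ld", seed=eseed + 2))
            base_plots = run_threeway_scheme(b1, b2, genome, cfg.threeway, seed=eseed + 3).base_plots
            ga = GAConfig(**{**asdict(cfg.ga), "seed": eseed})
            res = sf_ga_optimize(b1, genome, cfg.targets, ga, base2=b2, base_plots=base_plots)
            func = res.effects
            q1 = b1.dosage[:, genome.qtl_index].mean(0) / 2.0
            q2 = b2.dosage[:, genome.qtl_index].mean(0) / 2.0
            for sr in range(cfg.n_scheme_replicates):
                sseed = int(master.integers(2**31 - 1))
                rows = run_ppg_replicate(cfg, b1, b2, genome, q1, q2, func, sseed)
                records += _flatten(rows, er, sr, components)
        else:
            base, genome, mode = _ipg_genome_and_base(cfg, eseed)
            func, _ = simulate_ipg_effects(cfg, base, genome, eseed)
            for sr in range(cfg.n_scheme_replicates):
                sseed = int(master.integers(2**31 - 1))
                rows = run_ipg_replicate(cfg, base, genome, mode, func, sseed)
                records += _flatten(rows, er, sr, components)
    df = pd.DataFrame(records)
    agg = aggregate_results(df)
    return df, agg


def aggregate_results(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (divisor n-1) per quantity x component, in table layout."""
    g = df.groupby(["quantity", "component"])["value"]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)}).reset_index()
    return out
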