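"""File I/O: TSV schemas for genotypes, maps, effects, phenotypes and variance
reports; YAML experiment configuration; optional VCF export.

All tabular artifacts are plain TSV so that runs can be diffed and versioned.
Genotypes are stored as b-allele dosage (0/1/2); haplotype phase is an
internal simulation detail and is not round-tripped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeMap, PlotPedigree, Population
from .models import FunctionalEffects, StatisticalEffectsIPG, StatisticalEffectsPPG


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------


def write_genome_map(genome: GenomeMap, path):
    pair_id = np.full(genome.n_loci, -1)
    for pid, (k, l) in enumerate(genome.pair_list):
        pair_id[genome.qtl_index[k]] = pid
        pair_id[genome.qtl_index[l]] = pid
    is_qtl = np.zeros(genome.n_loci, dtype=int)
    is_qtl[genome.qtl_index] = 1
    pd.DataFrame(
        {"chromosome": genome.loci_chrom, "locus": np.arange(genome.n_loci),
         "position_cm": genome.loci_pos, "is_qtl": is_qtl, "pair_id": pair_id}
    ).to_csv(path, sep="\t", index=False)


def read_genome_map(path) -> GenomeMap:
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "locus", "position_cm", "is_qtl", "pair_id"}
    if not required.issubset(df.columns):
        raise ConfigError(f"genome map must have columns {sorted(required)}")
    qtl = df.index[df["is_qtl"] == 1].to_numpy()
    loc_to_qtl = {int(df.loc[i, "locus"]): j for j, i in enumerate(qtl)}
    pairs = {}
    for i in qtl:
        pid = int(df.loc[i, "pair_id"])
        if pid >= 0:
            pairs.setdefault(pid, []).append(loc_to_qtl[int(df.loc[i, "locus"])])
    pair_list = np.array([sorted(v) for _, v in sorted(pairs.items())], dtype=int).reshape(-1, 2)
    chrom_ids = sorted(df["chromosome"].unique())
    lengths = {c: float(df[df["chromosome"] == c]["position_cm"].max()) for c in chrom_ids}
    return GenomeMap(
        chromosomes=[(c, lengths[c]) for c in chrom_ids],
        loci_chrom=df["chromosome"].to_numpy(),
        loci_pos=df["position_cm"].to_numpy(),
        qtl_index=qtl,
        pair_list=pair_list,
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def write_genotypes(pop: Population, path):
    """Rows = individuals (id, generation, sire, dam), columns = loci dosages."""
    meta = pop.pedigree_frame()
    dos = pd.DataFrame(pop.dosage, columns=[f"L{j}" for j in range(pop.n_loci)])
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> Population:
    df = pd.read_csv(path, sep="\t")
    loci = [c for c in df.columns if c.startswith("L")]
    if not loci:
        raise ConfigError("genotype file has no locus columns (L0, L1, ...)")
    dos = df[loci].to_numpy().astype(np.uint8)
    # phase is not stored: split dosage into a canonical haplotype pair
    h1 = (dos >= 1).astype(np.uint8)
    h2 = (dos == 2).astype(np.uint8)
    return Population(
        np.stack([h1, h2], axis=1),
        df["generation"].to_numpy(),
        df["sire"].to_numpy(),
        df["dam"].to_numpy(),
    )


def export_vcf(pop: Population, genome: GenomeMap, path):
    """Diploid GT export; loci become pseudo-markers with cM stored in INFO."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=CM,Number=1,Type=Float,Description="Map position in cM">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c, _len in genome.chromosomes:
        header.contigs.add(str(c))
    for i in range(pop.n):
        header.add_sample(f"ind{i}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        haps = pop.haplotypes
        for j in range(genome.n_loci):
            rec = vcf.new_record(
                contig=str(genome.loci_chrom[j]),
                start=int(round(genome.loci_pos[j] * 1e4)),
                alleles=("A", "B"),
                id=f"L{j}",
            )
            rec.info["CM"] = float(genome.loci_pos[j])
            for i in range(pop.n):
                rec.samples[i]["GT"] = (int(haps[i, 0, j]), int(haps[i, 1, j]))
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Effects, phenotypes, variances, plots
# ---------------------------------------------------------------------------


def write_effects(func: FunctionalEffects, genome: GenomeMap, path, stats=None):
    """Effects TSV: functional values per QTL, pair membership, and (optionally)
    the statistical counterparts with their anchoring frequencies."""
    L = func.n_qtl
    pair_id = np.full(L, -1)
    pair_aa = np.full(L, np.nan)
    for pid, (k, l) in enumerate(np.asarray(genome.pair_list).reshape(-1, 2)):
        pair_id[[k, l]] = pid
        pair_aa[[k, l]] = func.aa[pid]
    df = pd.DataFrame(
        {"qtl": np.arange(L), "locus": genome.qtl_index, "a": func.a, "d": func.d,
         "dd": func.dd if func.dd is not None else np.nan,
         "pair_id": pair_id, "aa": pair_aa}
    )
    if isinstance(stats, StatisticalEffectsIPG):
        df["alpha"] = stats.alpha
        df["delta"] = stats.delta
        aa_s = np.full(L, np.nan)
        for pid, (k, l) in enumerate(np.asarray(genome.pair_list).reshape(-1, 2)):
            aa_s[[k, l]] = stats.alpha_alpha[pid]
        df["alpha_alpha"] = aa_s
        df["anchor_q"] = stats.anchor.q
    elif isinstance(stats, StatisticalEffectsPPG):
        df["alpha1"] = stats.alpha1
        df["alpha2"] = stats.alpha2
        df["delta3"] = stats.delta3
        aa_s = np.full(L, np.nan)
        for pid, (k, l) in enumerate(np.asarray(genome.pair_list).reshape(-1, 2)):
            aa_s[[k, l]] = stats.alpha_alpha3[pid]
        df["alpha_alpha3"] = aa_s
        df["anchor_q1"] = stats.q1
        df["anchor_q2"] = stats.q2
    df.to_csv(path, sep="\t", index=False)


def read_effects(path) -> FunctionalEffects:
    df = pd.read_csv(path, sep="\t")
    paired = df[df["pair_id"] >= 0].sort_values(["pair_id", "qtl"])
    aa = paired.groupby("pair_id")["aa"].first().to_numpy() if len(paired) else np.empty(0)
    dd = df["dd"].to_numpy()
    return FunctionalEffects(a=df["a"].to_numpy(), d=df["d"].to_numpy(), aa=aa,
                             dd=None if np.all(np.isnan(dd)) else dd)


def write_phenotypes(table, path, plots: PlotPedigree = None):
    df = table.frame()
    df.insert(0, "id", np.arange(len(df)))
    if plots is not None:
        df["i1"] = plots.i1
        df["i2a"] = plots.i2a
        df["i2b"] = plots.i2b
    df.to_csv(path, sep="\t", index=False)


def write_variance_report(components: list, path):
    """components: list of (label, VarianceComponents)."""
    rows = []
    for label, vc in components:
        for comp, val in vc.as_dict().items():
            rows.append({"quantity": label, "component": comp, "basis": vc.basis,
                         "mode": vc.mode, "value": val})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------


def load_config(path):
    """Parse a YAML experiment configuration into ExperimentConfig."""
    from .experiment import config_from_dict

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("experiment config must be a YAML mapping")
    return config_from_dict(raw)
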