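"""Genome and population simulation: base sampling, meiosis, breeding schemes.

Genotypes are haplotype-resolved: a population stores an (n, 2, L) uint8 array
over the mapped loci, with allele *b* coded 1, so the dosage at a locus is the
count of b alleles (0/1/2 ~ genotypes BB/Bb/bb).

Recombination follows Haldane's model (Poisson crossovers, no interference),
implemented as a Markov switch chain along each chromosome: between adjacent
loci at map distance d Morgans the gamete switches parental haplotype with
probability r = (1 - exp(-2d))/2, and chromosomes assort independently
(switch probability 1/2 at chromosome boundaries). This is mathematically
identical to sampling Poisson(length) crossover points uniformly. In linkage-
equilibrium (LE) mode every locus segregates independently (r = 1/2 everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_rng


class InvalidConfiguration(ValueError):
    """Raised when a simulation request is internally inconsistent."""


class InsufficientSegregation(RuntimeError):
    """Raised when fewer segregating loci remain than requested QTL."""


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------


@dataclass
class GenomeMap:
    """Chromosome map with designated QTL and epistatic pairs.

    Parameters
    ----------
    chromosomes : list of (id, length_cM)
    loci_chrom : int array (L,), chromosome index of each locus
    loci_pos : float array (L,), position in cM, strictly increasing per chromosome
    qtl_index : int array, indices into loci designated as QTL
    pair_list : int array (n_pairs, 2), epistatic pairs as indices into `qtl_index`
    """

    chromosomes: list
    loci_chrom: np.ndarray
    loci_pos: np.ndarray
    qtl_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    pair_list: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self):
        self.loci_chrom = np.asarray(self.loci_chrom, dtype=np.int64)
        self.loci_pos = np.asarray(self.loci_pos, dtype=float)
        self.qtl_index = np.asarray(self.qtl_index, dtype=np.int64)
        self.pair_list = np.asarray(self.pair_list, dtype=np.int64).reshape(-1, 2)
        for c in np.unique(self.loci_chrom):
            pos = self.loci_pos[self.loci_chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise InvalidConfiguration("locus positions must strictly increase within a chromosome")
        if self.pair_list.size:
            flat = self.pair_list.ravel()
            if np.any(self.pair_list[:, 0] == self.pair_list[:, 1]):
                raise InvalidConfiguration("epistatic pair members must be distinct QTL")
            if len(np.unique(flat)) != len(flat):
                raise InvalidConfiguration("each QTL may appear in at most one epistatic pair")
            if flat.max(initial=-1) >= self.n_qtl:
                raise InvalidConfiguration("pair_list refers to QTL outside qtl_index")

    @property
    def n_loci(self) -> int:
        return len(self.loci_pos)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_index)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_list)

    def recombination_fractions(self) -> np.ndarray:
        """Per-interval recombination fraction between adjacent loci (length L-1).

        Haldane map function within chromosomes; 0.5 across chromosome breaks.
        """
        d = np.diff(self.loci_pos) / 100.0  # Morgans
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        r[np.diff(self.loci_chrom) != 0] = 0.5
        return r

    def subset_to_qtl(self) -> "GenomeMap":
        """Restrict the map to the QTL loci (pairs keep their identity)."""
        g = replace(
            self,
            loci_chrom=self.loci_chrom[self.qtl_index],
            loci_pos=self.loci_pos[self.qtl_index],
            qtl_index=np.arange(self.n_qtl),
            pair_list=self.pair_list.copy(),
        )
        return g


def uniform_genome(
    n_chromosomes: int,
    chrom_length_cm: float,
    loci_per_chrom: int,
    seed: int = 0,
) -> GenomeMap:
    """Genome with locus positions drawn uniformly on each chromosome."""
    rng = child_rng(seed, "genome-positions")
    chroms, pos = [], []
    for c in range(n_chromosomes):
        p = np.sort(rng.uniform(0.0, chrom_length_cm, size=loci_per_chrom))
        # enforce strict monotonicity against duplicate draws
        p += np.arange(loci_per_chrom) * 1e-9
        chroms.append(np.full(loci_per_chrom, c))
        pos.append(p)
    return GenomeMap(
        chromosomes=[(c, chrom_length_cm) for c in range(n_chromosomes)],
        loci_chrom=np.concatenate(chroms),
        loci_pos=np.concatenate(pos),
    )


def random_pairs(n_qtl: int, n_pairs: int, seed: int = 0) -> np.ndarray:
    """Disjoint epistatic QTL pairs; each QTL in at most one pair."""
    if 2 * n_pairs > n_qtl:
        raise InvalidConfiguration("not enough QTL for the requested pair count")
    rng = child_rng(seed, "qtl-pairs")
    perm = rng.permutation(n_qtl)[: 2 * n_pairs]
    return perm.reshape(n_pairs, 2)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Haplotype-resolved genotypes with pedigree and generation labels."""

    haplotypes: np.ndarray  # (n, 2, L) uint8
    generation: np.ndarray  # (n,) int
    sire: np.ndarray  # (n,) int, -1 for founders
    dam: np.ndarray  # (n,) int

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n = self.haplotypes.shape[0]
        self.generation = np.asarray(self.generation, dtype=np.int64).reshape(n)
        self.sire = np.asarray(self.sire, dtype=np.int64).reshape(n)
        self.dam = np.asarray(self.dam, dtype=np.int64).reshape(n)

    @classmethod
    def from_haplotypes(cls, haps, generation=0, sire=None, dam=None):
        n = haps.shape[0]
        gen = np.full(n, generation) if np.isscalar(generation) else generation
        s = np.full(n, -1) if sire is None else sire
        d = np.full(n, -1) if dam is None else dam
        return cls(haps, gen, s, d)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def dosage(self) -> np.ndarray:
        """(n, L) count of allele b."""
        return self.haplotypes.sum(axis=1)

    def subset(self, idx) -> "Population":
        idx = np.asarray(idx)
        return Population(self.haplotypes[idx], self.generation[idx], self.sire[idx], self.dam[idx])

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "generation": self.generation,
                "sire": self.sire,
                "dam": self.dam,
            }
        )


def concat_populations(pops: list) -> Population:
    """Stack populations; pedigree indices are assumed already global."""
    return Population(
        np.concatenate([p.haplotypes for p in pops]),
        np.concatenate([p.generation for p in pops]),
        np.concatenate([p.sire for p in pops]),
        np.concatenate([p.dam for p in pops]),
    )


def allele_frequencies(pop: Population, subset=None) -> np.ndarray:
    """Per-locus frequency q_j of allele b in the (sub)population."""
    dos = pop.dosage if subset is None else pop.dosage[np.asarray(subset)]
    if dos.shape[0] == 0:
        raise InvalidConfiguration("empty subset")
    return dos.mean(axis=0) / 2.0


def genotype_frequencies(pop_or_dosage, subset=None) -> np.ndarray:
    """(L, 3) genotype frequencies [p_BB, p_Bb, p_bb] (dosage 0, 1, 2)."""
    dos = pop_or_dosage.dosage if isinstance(pop_or_dosage, Population) else np.asarray(pop_or_dosage)
    if subset is not None:
        dos = dos[np.asarray(subset)]
    if dos.shape[0] == 0:
        raise InvalidConfiguration("empty subset")
    n = dos.shape[0]
    out = np.empty((dos.shape[1], 3))
    for g in range(3):
        out[:, g] = (dos == g).sum(axis=0) / n
    return out


# ---------------------------------------------------------------------------
# Meiosis and mating
# ---------------------------------------------------------------------------


def _gametes(haps: np.ndarray, r_adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per input individual. haps: (m, 2, L) -> (m, L)."""
    m, _, L = haps.shape
    start = (rng.random(m) < 0.5).astype(np.int64)
    if L > 1:
        switch = (rng.random((m, L - 1)) < r_adj[None, :]).astype(np.int64)
        which = np.empty((m, L), dtype=np.int64)
        which[:, 0] = start
        which[:, 1:] = (start[:, None] + np.cumsum(switch, axis=1)) % 2
    else:
        which = start[:, None]
    rows = np.arange(m)[:, None]
    return haps[rows, which, np.arange(L)[None, :]]


def _r_for_mode(genome: GenomeMap, mode: str) -> np.ndarray:
    if mode == "le":
        return np.full(max(genome.n_loci - 1, 0), 0.5)
    if mode == "ld":
        return genome.recombination_fractions()
    raise InvalidConfiguration(f"unknown inheritance mode {mode!r}")


def meiosis(parent_haplotypes: np.ndarray, genome: GenomeMap, seed=None, mode: str = "ld", rng=None) -> np.ndarray:
    """Single gamete (L,) from one parent's (2, L) haplotypes."""
    if rng is None:
        rng = child_rng(0 if seed is None else seed, "meiosis")
    return _gametes(np.asarray(parent_haplotypes, dtype=np.uint8)[None], _r_for_mode(genome, mode), rng)[0]


def mate(
    pop: Population,
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    genome: GenomeMap,
    mode: str = "ld",
    rng=None,
    seed=None,
    generation: int = 1,
) -> Population:
    """Offspring of the given sire/dam index pairs (one offspring per pair).

    Selfing is deliberately rejected here; use `self_pollinate`.
    """
    sire_idx = np.asarray(sire_idx)
    dam_idx = np.asarray(dam_idx)
    if np.any(sire_idx == dam_idx):
        raise InvalidConfiguration("selfing only permitted via self_pollinate")
    if rng is None:
        rng = child_rng(0 if seed is None else seed, "mate")
    r = _r_for_mode(genome, mode)
    g1 = _gametes(pop.haplotypes[sire_idx], r, rng)
    g2 = _gametes(pop.haplotypes[dam_idx], r, rng)
    haps = np.stack([g1, g2], axis=1)
    return Population.from_haplotypes(haps, generation=generation, sire=sire_idx, dam=dam_idx)


def self_pollinate(
    line_haplotypes: np.ndarray,
    genome: GenomeMap,
    generations: int,
    single_seed: bool = True,
    mode: str = "ld",
    rng=None,
    seed=None,
) -> np.ndarray:
    """Repeated self-fertilization; returns final haplotypes.

    Accepts a single individual (2, L) or a batch (m, 2, L); with `single_seed`
    one descendant is kept per line per mini-generation (single seed descent).
    Pedigree-expected inbreeding after t generations from a non-inbred founder
    is 1 - (1/2)^t.
    """
    if generations < 1:
        raise InvalidConfiguration("selfing requires generations >= 1")
    haps = np.asarray(line_haplotypes, dtype=np.uint8)
    squeeze = haps.ndim == 2
    if squeeze:
        haps = haps[None]
    if not single_seed:
        raise InvalidConfiguration("only single seed descent is implemented")
    if rng is None:
        rng = child_rng(0 if seed is None else seed, "self")
    r = _r_for_mode(genome, mode)
    for _ in range(generations):
        g1 = _gametes(haps, r, rng)
        g2 = _gametes(haps, r, rng)
        haps = np.stack([g1, g2], axis=1)
    return haps[0] if squeeze else haps


# ---------------------------------------------------------------------------
# Base populations
# ---------------------------------------------------------------------------


def sample_base_le(
    n: int,
    genome: GenomeMap,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
    seed: int = 0,
) -> Population:
    """Base population in linkage equilibrium by binomial sampling.

    Per-locus target frequency of allele b ~ U(freq_low, freq_high); haplotype
    alleles are independent Bernoulli draws, so loci are mutually independent.
    """
    if n < 2 or genome.n_loci == 0:
        raise InvalidConfiguration("need n >= 2 individuals and a non-empty genome")
    if not (0 < freq_low <= freq_high < 1):
        raise InvalidConfiguration("need 0 < freq_low <= freq_high < 1")
    rng = child_rng(seed, "base-le")
    q = rng.uniform(freq_low, freq_high, size=genome.n_loci)
    haps = (rng.random((n, 2, genome.n_loci)) < q[None, None, :]).astype(np.uint8)
    return Population.from_haplotypes(haps, generation=0)


def _founder_haplotypes(n: int, n_loci: int, rng) -> np.ndarray:
    """(n, 2, L) founder haplotypes with allele b on exactly half the
    chromosomes at every locus, so all starting frequencies are exactly 0.5."""
    u = rng.random((2 * n, n_loci))
    ranks = np.argsort(u, axis=0)
    haps = np.zeros((2 * n, n_loci), dtype=np.uint8)
    haps[ranks[:n], np.arange(n_loci)[None, :]] = 1
    return haps.reshape(n, 2, n_loci)


def _wright_fisher(haps: np.ndarray, r: np.ndarray, n_out: int, generations: int, rng) -> np.ndarray:
    """Forward Wright-Fisher: random union of gametes, discrete generations."""
    for _ in range(generations):
        cur_n = haps.shape[0]
        sires = rng.integers(0, cur_n, size=n_out)
        dams = rng.integers(0, cur_n, size=n_out)
        g1 = _gametes(haps[sires], r, rng)
        g2 = _gametes(haps[dams], r, rng)
        haps = np.stack([g1, g2], axis=1)
    return haps


def _draw_qtl(genome, segregating_mask, n_qtl, n_pairs, rng):
    eligible = np.flatnonzero(segregating_mask)
    if len(eligible) < n_qtl:
        raise InsufficientSegregation(
            f"only {len(eligible)} segregating loci available, {n_qtl} QTL requested"
        )
    qtl = np.sort(rng.choice(eligible, size=n_qtl, replace=False))
    pairs = random_pairs(n_qtl, n_pairs, seed=int(rng.integers(2**31 - 1))) if n_pairs else np.empty((0, 2), int)
    return replace(genome, qtl_index=qtl, pair_list=pairs)


def simulate_ld_base(
    n: int,
    genome: GenomeMap,
    historical_generations: int,
    historical_n: int,
    maf_min: float = 0.05,
    n_qtl: int = 0,
    n_pairs: int = 0,
    seed: int = 0,
):
    """LD base population via forward Wright-Fisher drift from frequency 0.5.

    All loci start at frequency 0.5 in a founder population of `historical_n`
    individuals; `historical_generations` of random union of gametes with
    recombination build up linkage disequilibrium and a drift-shaped allele
    frequency spectrum. QTL (if requested) are then drawn from loci with
    MAF >= maf_min, and `n` base individuals are produced.

    Returns (Population, GenomeMap with QTL designated).
    """
    if historical_generations < 0:
        raise InvalidConfiguration("historical_generations must be >= 0")
    if not (0 < maf_min < 0.5):
        raise InvalidConfiguration("maf_min must lie in (0, 0.5)")
    rng = child_rng(seed, "ld-base")
    r = genome.recombination_fractions()
    if historical_generations == 0:
        # no drift: the base is a founder set with all frequencies exactly 0.5
        pop = Population.from_haplotypes(_founder_haplotypes(n, genome.n_loci, rng))
    else:
        haps = _founder_haplotypes(historical_n, genome.n_loci, rng)
        haps = _wright_fisher(haps, r, historical_n, historical_generations, rng)
        # generation 0: n base individuals from the final historical generation
        sires = rng.integers(0, historical_n, size=n)
        dams = rng.integers(0, historical_n, size=n)
        base = np.stack([_gametes(haps[sires], r, rng), _gametes(haps[dams], r, rng)], axis=1)
        pop = Population.from_haplotypes(base, generation=0)
    if n_qtl:
        q = allele_frequencies(pop)
        seg = np.minimum(q, 1 - q) >= maf_min
        genome = _draw_qtl(genome, seg, n_qtl, n_pairs, rng)
    return pop, genome


def simulate_diverged_bases(
    n1: int,
    n2: int,
    genome: GenomeMap,
    common_generations: int,
    diverge_generations: int,
    historical_n: int,
    maf_min: float = 0.05,
    n_qtl: int = 0,
    n_pairs: int = 0,
    seed: int = 0,
):
    """Two diverged base populations from a split Wright-Fisher history.

    A common historical population drifts for `common_generations`, is split
    into two populations of `historical_n` each, which drift independently for
    `diverge_generations`. QTL are drawn from loci with MAF >= maf_min in
    *both* populations (a locus fixed in one population has no statistical
    anchoring there). Returns (pop1, pop2, genome).
    """
    rng = child_rng(seed, "diverged-base")
    r = genome.recombination_fractions()
    haps = _founder_haplotypes(historical_n, genome.n_loci, rng)
    haps = _wright_fisher(haps, r, historical_n, common_generations, rng)
    h1 = _wright_fisher(haps, r, historical_n, diverge_generations, rng)
    h2 = _wright_fisher(haps, r, historical_n, diverge_generations, rng)

    def _sample(h, n):
        s = rng.integers(0, h.shape[0], size=n)
        d = rng.integers(0, h.shape[0], size=n)
        return np.stack([_gametes(h[s], r, rng), _gametes(h[d], r, rng)], axis=1)

    pop1 = Population.from_haplotypes(_sample(h1, n1), generation=0)
    pop2 = Population.from_haplotypes(_sample(h2, n2), generation=0)
    if n_qtl:
        q1 = allele_frequencies(pop1)
        q2 = allele_frequencies(pop2)
        seg = (np.minimum(q1, 1 - q1) >= maf_min) & (np.minimum(q2, 1 - q2) >= maf_min)
        genome = _draw_qtl(genome, seg, n_qtl, n_pairs, rng)
    return pop1, pop2, genome


# ---------------------------------------------------------------------------
# Breeding schemes
# ---------------------------------------------------------------------------


def run_ipg_scheme(
    base: Population,
    genome: GenomeMap,
    generations: int = 4,
    n_parents: int = 150,
    n_matings: int = 150,
    offspring_per_mating: int = 5,
    mode: str = "le",
    seed: int = 0,
) -> Population:
    """Random-mating breeding scheme for individual-phenotype data.

    Per generation: sample `n_parents` candidates uniformly (no selection on
    phenotype), form `n_matings` random sire/dam pairs, each producing
    `offspring_per_mating` offspring. Returns a single Population holding the
    base (generation 0) and every descendant generation; pedigree indices are
    global row numbers.
    """
    if base.n == 0:
        raise InvalidConfiguration("empty base population")
    rng = child_rng(seed, "ipg-scheme")
    r = _r_for_mode(genome, mode)
    all_haps = [base.haplotypes]
    gen_labels = [np.zeros(base.n, dtype=np.int64)]
    sires = [np.full(base.n, -1)]
    dams = [np.full(base.n, -1)]
    prev_start, prev_n = 0, base.n
    offset = base.n
    for g in range(1, generations + 1):
        replace_flag = n_parents > prev_n
        parents = rng.choice(prev_n, size=n_parents, replace=replace_flag) + prev_start
        sire_idx = rng.choice(parents, size=n_matings)
        dam_idx = rng.choice(parents, size=n_matings)
        clash = sire_idx == dam_idx
        while np.any(clash):
            dam_idx[clash] = rng.choice(parents, size=clash.sum())
            clash = sire_idx == dam_idx
        sire_rep = np.repeat(sire_idx, offspring_per_mating)
        dam_rep = np.repeat(dam_idx, offspring_per_mating)
        cur = np.concatenate([h for h in all_haps]) if len(all_haps) > 1 else all_haps[0]
        g1 = _gametes(cur[sire_rep], r, rng)
        g2 = _gametes(cur[dam_rep], r, rng)
        haps = np.stack([g1, g2], axis=1)
        n_off = haps.shape[0]
        all_haps = [np.concatenate([cur, haps])]
        gen_labels.append(np.full(n_off, g))
        sires.append(sire_rep)
        dams.append(dam_rep)
        prev_start, prev_n = offset, n_off
        offset += n_off
    return Population(
        all_haps[0],
        np.concatenate(gen_labels),
        np.concatenate(sires),
        np.concatenate(dams),
    )


@dataclass
class PlotPedigree:
    """Three-way hybrid plot records.

    Each plot is the mating of one inbred line from population 1 with a two-way
    hybrid whose parents i2a, i2b are distinct inbred lines from population 2.
    Indices are rows of the corresponding line populations.
    """

    generation: np.ndarray
    i1: np.ndarray
    i2a: np.ndarray
    i2b: np.ndarray

    def __post_init__(self):
        if np.any(self.i2a == self.i2b):
            raise InvalidConfiguration("two-way hybrid parents must be distinct lines")

    @property
    def n(self) -> int:
        return len(self.i1)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"plot": np.arange(self.n), "generation": self.generation,
             "i1": self.i1, "i2a": self.i2a, "i2b": self.i2b}
        )


@dataclass
class ThreeWayConfig:
    """Three-way hybrid crop breeding scheme parameters."""

    generations: int = 4
    n_lines1: int = 200  # population-1 inbred lines per generation
    n_lines2: int = 100  # population-2 inbred lines per generation
    seeds_per_cross: int = 5
    self_generations: int = 4  # single-seed-descent mini-generations
    plots_per_line1: int = 5
    plots_per_hybrid: int = 10
    plot_generations: tuple = (2, 3, 4)
    n_base_plots: int = 1000
    mode: str = "ld"


@dataclass
class ThreeWayResult:
    lines1: Population  # all generations, generation-labelled
    lines2: Population
    hybrids: pd.DataFrame  # columns generation, i2a, i2b (rows of lines2)
    plots: PlotPedigree  # descendant plots (plot_generations)
    base_plots: PlotPedigree  # generation-0 plot set (anchoring / fitness)


def _random_distinct_pairs(n_avail: int, n_pairs: int, rng, offset: int = 0):
    s = rng.integers(0, n_avail, size=n_pairs)
    d = rng.integers(0, n_avail, size=n_pairs)
    clash = s == d
    while np.any(clash):
        d[clash] = rng.integers(0, n_avail, size=clash.sum())
        clash = s == d
    return s + offset, d + offset


def _new_inbred_lines(pool: Population, idx_range, n_new, cfg, genome, rng, generation):
    """Cross previous-generation lines, keep `seeds_per_cross` seeds per cross,
    then single-seed-descent selfing of every seed."""
    lo, hi = idx_range
    n_avail = hi - lo
    if n_new % cfg.seeds_per_cross:
        raise InvalidConfiguration("n_lines must be divisible by seeds_per_cross")
    n_cross = n_new // cfg.seeds_per_cross
    s, d = _random_distinct_pairs(n_avail, n_cross, rng, offset=lo)
    s = np.repeat(s, cfg.seeds_per_cross)
    d = np.repeat(d, cfg.seeds_per_cross)
    r = _r_for_mode(genome, cfg.mode)
    g1 = _gametes(pool.haplotypes[s], r, rng)
    g2 = _gametes(pool.haplotypes[d], r, rng)
    seeds = np.stack([g1, g2], axis=1)
    lines = self_pollinate(seeds, genome, cfg.self_generations, mode=cfg.mode, rng=rng)
    return Population.from_haplotypes(lines, generation=generation, sire=s, dam=d)


def _assign_plots(line_rows, hybrid_ids, per_line, per_hybrid, rng):
    slots1 = np.repeat(line_rows, per_line)
    slots2 = np.repeat(hybrid_ids, per_hybrid)
    if len(slots1) != len(slots2):
        raise InvalidConfiguration("plot design sides do not balance")
    rng.shuffle(slots2)
    return slots1, slots2


def run_threeway_scheme(
    base1: Population,
    base2: Population,
    genome: GenomeMap,
    config: ThreeWayConfig = None,
    seed: int = 0,
) -> ThreeWayResult:
    """Three-way hybrid breeding scheme over two inbred populations.

    Per generation, lines are crossed at random within each population, the
    seeds are taken through single-seed-descent selfing to form new inbred
    lines; two-way hybrids pair population-2 lines of generation t with lines
    of generation t-1; three-way plots mate population-1 lines with two-way
    hybrids under a balanced design (each line in `plots_per_line1` matings,
    each hybrid in `plots_per_hybrid`), one plot per mating. A generation-0
    plot set over the base lines is also produced for effect anchoring.
    """
    cfg = config or ThreeWayConfig()
    rng = child_rng(seed, "threeway-scheme")

    if cfg.n_lines1 * cfg.plots_per_line1 != cfg.n_lines2 * cfg.plots_per_hybrid:
        raise InvalidConfiguration("line/hybrid plot contributions do not balance")

    lines1 = base1
    lines2 = base2
    ranges1 = {0: (0, base1.n)}
    ranges2 = {0: (0, base2.n)}

    # base two-way hybrids: pair base-2 lines, all lines contributing equally
    perm_a = rng.permutation(base2.n)
    perm_b = np.roll(perm_a, 1)  # guarantees i2a != i2b
    hybrids = [pd.DataFrame({"generation": 0, "i2a": perm_a, "i2b": perm_b})]

    # base plots: base-1 lines x base hybrids, balanced
    if cfg.n_base_plots % base1.n or cfg.n_base_plots % base2.n:
        raise InvalidConfiguration("n_base_plots must be a multiple of both base sizes")
    h0 = hybrids[0]
    s1, hid = _assign_plots(
        np.arange(base1.n), np.arange(base2.n),
        cfg.n_base_plots // base1.n, cfg.n_base_plots // base2.n, rng,
    )
    base_plots = PlotPedigree(
        np.zeros(len(s1), dtype=np.int64), s1,
        h0["i2a"].to_numpy()[hid], h0["i2b"].to_numpy()[hid],
    )

    plot_rec = {"generation": [], "i1": [], "i2a": [], "i2b": []}
    for t in range(1, cfg.generations + 1):
        new1 = _new_inbred_lines(lines1, ranges1[t - 1], cfg.n_lines1, cfg, genome, rng, t)
        ranges1[t] = (lines1.n, lines1.n + new1.n)
        lines1 = concat_populations([lines1, new1])

        new2 = _new_inbred_lines(lines2, ranges2[t - 1], cfg.n_lines2, cfg, genome, rng, t)
        ranges2[t] = (lines2.n, lines2.n + new2.n)
        lines2 = concat_populations([lines2, new2])

        # two-way hybrids: generation-t lines x generation-(t-1) lines of pop 2
        lo_t, hi_t = ranges2[t]
        lo_p, hi_p = ranges2[t - 1]
        n_hyb = min(hi_t - lo_t, hi_p - lo_p)
        a = rng.permutation(hi_t - lo_t)[:n_hyb] + lo_t
        b = rng.permutation(hi_p - lo_p)[:n_hyb] + lo_p
        hybrids.append(pd.DataFrame({"generation": t, "i2a": a, "i2b": b}))

        if t in cfg.plot_generations:
            lo1, hi1 = ranges1[t]
            s1, hid = _assign_plots(
                np.arange(lo1, hi1), np.arange(n_hyb),
                cfg.plots_per_line1, cfg.plots_per_hybrid, rng,
            )
            plot_rec["generation"].append(np.full(len(s1), t))
            plot_rec["i1"].append(s1)
            plot_rec["i2a"].append(a[hid])
            plot_rec["i2b"].append(b[hid])

    if plot_rec["generation"]:
        plots = PlotPedigree(*(np.concatenate(plot_rec[k]) for k in ("generation", "i1", "i2a", "i2b")))
    else:
        plots = PlotPedigree(*(np.empty(0, dtype=np.int64) for _ in range(4)))
    return ThreeWayResult(lines1, lines2, pd.concat(hybrids, ignore_index=True), plots, base_plots)
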