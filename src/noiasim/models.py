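"""Shared dataclasses: effect sets, variance components, targets, GA settings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .noia import Anchor


@dataclass
class FunctionalEffects:
    """Per-QTL functional effects: what Mendelian inheritance transmits.

    These are genotype-value parameters, independent of allele frequencies:
    `a` (additive), `d` (dominance value, optionally d = dd * |a| with `dd`
    the dominance degree), and per-pair `aa` (additive x additive epistasis).
    """

    a: np.ndarray
    d: np.ndarray
    aa: np.ndarray = field(default_factory=lambda: np.empty(0))
    dd: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.aa = np.asarray(self.aa, dtype=float)
        if self.d.shape != self.a.shape:
            raise ValueError("a and d must have equal length")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.d)) and np.all(np.isfinite(self.aa))):
            raise ValueError("functional effects must be finite")

    @property
    def n_qtl(self) -> int:
        return len(self.a)


@dataclass
class StatisticalEffectsIPG:
    """Statistical (substitution-scale) effects anchored to reference frequencies."""

    alpha: np.ndarray
    delta: np.ndarray
    alpha_alpha: np.ndarray
    anchor: Anchor

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.alpha_alpha = np.asarray(self.alpha_alpha, dtype=float)


@dataclass
class StatisticalEffectsPPG:
    """pPG statistical effects: substitution effects per parental population,
    plot dominance and plot epistasis, anchored to the two base populations."""

    alpha1: np.ndarray
    alpha2: np.ndarray
    delta3: np.ndarray
    alpha_alpha3: np.ndarray
    q1: np.ndarray
    q2: np.ndarray


@dataclass
class VarianceComponents:
    """Genetic variances by component, with the calculation mode and basis tags."""

    mode: str  # by_locus | by_individual
    basis: str  # functional | statistical
    additive: float | None = None
    dominance: float | None = None
    epistasis: float | None = None
    additive1: float | None = None
    additive2: float | None = None
    dominance3: float | None = None
    epistasis3: float | None = None
    residual: float | None = None

    def as_dict(self) -> dict:
        keys = ("additive", "dominance", "epistasis", "additive1", "additive2",
                "dominance3", "epistasis3", "residual")
        return {k: getattr(self, k) for k in keys if getattr(self, k) is not None}


@dataclass
class VarianceTargets:
    """Target statistical variance components — the simulator's contract."""

    mode: str = "by_locus"
    additive: float | None = None
    dominance: float | None = None
    epistasis: float | None = None
    additive1: float | None = None
    additive2: float | None = None
    dominance3: float | None = None
    epistasis3: float | None = None
    residual: float = 0.0

    def __post_init__(self):
        if self.mode not in ("by_locus", "by_individual"):
            raise ValueError("mode must be by_locus or by_individual")
        for k, v in self.as_dict().items():
            if v is not None and v < 0:
                raise ValueError(f"target {k} must be >= 0")

    @classmethod
    def ipg(cls, additive, dominance, epistasis, residual=0.0, mode="by_locus"):
        return cls(mode=mode, additive=additive, dominance=dominance,
                   epistasis=epistasis, residual=residual)

    @classmethod
    def ppg(cls, additive1, additive2, dominance3, epistasis3, residual=0.0, mode="by_individual"):
        return cls(mode=mode, additive1=additive1, additive2=additive2,
                   dominance3=dominance3, epistasis3=epistasis3, residual=residual)

    @property
    def is_ppg(self) -> bool:
        return self.additive1 is not None

    def total(self) -> float:
        if self.is_ppg:
            return self.additive1 + self.additive2 + self.dominance3 + self.epistasis3
        return self.additive + self.dominance + self.epistasis

    def as_dict(self) -> dict:
        keys = ("additive", "dominance", "epistasis", "additive1", "additive2",
                "dominance3", "epistasis3")
        return {k: getattr(self, k) for k in keys if getattr(self, k) is not None}


@dataclass
class GAConfig:
    """Real-coded genetic-algorithm settings for functional-effect search."""

    population_size: int = 200
    max_generations: int = 2000
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1  # per-gene
    mutation_scale: float = 0.1  # fraction of the prior SD per effect class
    elitism_frac: float = 0.05
    tolerance_frac: float = 0.001  # of the summed variance targets
    repair: bool = True  # Lamarckian rescale-repair local step
    seed: int = 0

    def __post_init__(self):
        for p in (self.crossover_prob, self.mutation_prob, self.elitism_frac):
            if not 0 <= p <= 1:
                raise ValueError("GA probabilities must lie in [0, 1]")
        if self.tolerance_frac <= 0:
            raise ValueError("tolerance must be positive")
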