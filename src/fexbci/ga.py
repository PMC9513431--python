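"""Binary-encoded genetic algorithm over the 5-gene CNN hyperparameter space.

Each individual is a chromosome of concatenated binary gene segments.  A
gene spanning [u_min, u_max] with bit length l has encoding precision

    delta = (u_max - u_min) / (2^l - 1),

and l is chosen as the smallest length whose delta meets the required
precision (1 for all five integer genes: 5 bits for the [1, 20] kernel
counts, 9 bits for the [1, 512] layer widths; 33 bits total).  Decoding is
u_min + round(bits * delta), clamped to the bounds, so every raw bit string
decodes to a valid genome and encode/decode round-trips exactly on every
in-range integer.

The search loop is fitness evaluation (CNN classification accuracy, cached
by bit pattern) -> fitness-proportional roulette selection -> multipoint
crossover -> per-bit mutation -> elitist replacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fexbci.cnn import (GENE_BOUNDS, HyperparamGenome, ModelSpec, TrainConfig,
                        build_model_spec, train_model)
from fexbci.synthdata import EpochSet

__all__ = [
    "GeneSpec", "Chromosome", "GAConfig", "GAHistory",
    "make_gene_spec", "default_layout", "encode", "decode",
    "random_chromosome", "roulette_select", "multipoint_crossover", "mutate",
    "FitnessEvaluator", "HammingSurrogate", "CNNFitness", "run_ga",
]

logger = logging.getLogger(__name__)

GENE_ORDER = ("k1", "k2", "k3", "n1", "n2")


@dataclass(frozen=True)
class GeneSpec:
    """Binary encoding of one integer gene."""

    u_min: int
    u_max: int
    l: int
    delta: float

    def __post_init__(self):
        if self.u_min >= self.u_max:
            raise ValueError(f"need u_min < u_max, got [{self.u_min}, {self.u_max}]")
        if self.l < 1:
            raise ValueError(f"bit length must be >= 1, got {self.l}")


def make_gene_spec(u_min: int, u_max: int, required_precision: float = 1.0) -> GeneSpec:
    """Smallest bit length whose precision (u_max-u_min)/(2^l - 1) meets the
    requirement, with delta computed at that length."""
    if required_precision <= 0:
        raise ValueError("required_precision must be > 0")
    if int(u_min) != u_min or int(u_max) != u_max:
        raise ValueError("integer genes need integer bounds")
    span = u_max - u_min
    if span <= 0:
        raise ValueError(f"need u_min < u_max, got [{u_min}, {u_max}]")
    l = 1
    while span / (2**l - 1) > required_precision:
        l += 1
    return GeneSpec(u_min=int(u_min), u_max=int(u_max), l=l,
                    delta=span / (2**l - 1))


def default_layout() -> tuple[GeneSpec, ...]:
    """Gene specs for (k1, k2, k3, n1, n2) at integer precision."""
    return tuple(make_gene_spec(*GENE_BOUNDS[g], required_precision=1.0)
                 for g in GENE_ORDER)


@dataclass(frozen=True)
class Chromosome:
    """Concatenated binary gene segments."""

    bits: tuple[int, ...]
    layout: tuple[GeneSpec, ...]

    def __post_init__(self):
        total = sum(g.l for g in self.layout)
        if len(self.bits) != total:
            raise ValueError(f"{len(self.bits)} bits but layout needs {total}")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def key(self) -> tuple[int, ...]:
        return self.bits


def encode(genome: HyperparamGenome, layout: tuple[GeneSpec, ...] | None = None
           ) -> Chromosome:
    layout = layout or default_layout()
    bits: list[int] = []
    for name, spec in zip(GENE_ORDER, layout):
        v = getattr(genome, name)
        if not spec.u_min <= v <= spec.u_max:
            raise ValueError(f"gene {name}={v} outside [{spec.u_min}, {spec.u_max}]")
        q = round((v - spec.u_min) / spec.delta)
        bits.extend(int(b) for b in format(q, f"0{spec.l}b"))
    return Chromosome(bits=tuple(bits), layout=layout)


def decode(chrom: Chromosome) -> HyperparamGenome:
    """Per-gene u_min + round(raw * delta), clamped into [u_min, u_max]."""
    values = {}
    offset = 0
    for name, spec in zip(GENE_ORDER, chrom.layout):
        seg = chrom.bits[offset:offset + spec.l]
        offset += spec.l
        raw = int("".join(map(str, seg)), 2)
        v = spec.u_min + round(raw * spec.delta)
        values[name] = int(min(max(v, spec.u_min), spec.u_max))
    return HyperparamGenome(**values)


def random_chromosome(layout: tuple[GeneSpec, ...], rng: np.random.Generator
                      ) -> Chromosome:
    total = sum(g.l for g in layout)
    return Chromosome(bits=tuple(rng.integers(0, 2, total).tolist()), layout=layout)


def roulette_select(fitnesses, n_draws: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """Fitness-proportional sampling with replacement: P(i) = f_i / sum f.

    All-zero fitness degenerates to uniform sampling (logged), negative
    fitness is rejected.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    if (f < 0).any():
        raise ValueError("roulette selection needs nonnegative fitnesses")
    total = f.sum()
    if total == 0:
        logger.warning("all fitnesses zero; roulette falls back to uniform")
        p = np.full(len(f), 1.0 / len(f))
    else:
        p = f / total
    return rng.choice(len(f), size=n_draws, replace=True, p=p)


def multipoint_crossover(a: Chromosome, b: Chromosome,
                         points=None, n_points: int = 2,
                         rng: np.random.Generator | None = None
                         ) -> tuple[Chromosome, Chromosome]:
    """Exchange alternating segments between the cut positions.

    ``points`` are cut indices strictly inside the string (a cut at p splits
    between bit p-1 and bit p).  When omitted, ``n_points`` distinct cuts
    are drawn with ``rng``.
    """
    if len(a) != len(b) or a.layout != b.layout:
        raise ValueError("parents must share length and layout")
    L = len(a)
    if points is None:
        if rng is None:
            raise ValueError("need either explicit points or an rng")
        n = min(n_points, L - 1)
        points = sorted(rng.choice(np.arange(1, L), size=n, replace=False).tolist())
    else:
        points = sorted(int(p) for p in points)
        if len(set(points)) != len(points):
            raise ValueError(f"duplicate cut positions in {points}")
        if any(not 0 < p < L for p in points):
            raise ValueError(f"cut positions must lie strictly inside (0, {L})")
    take_b = False
    c1, c2 = [], []
    cuts = set(points)
    for i in range(L):
        if i in cuts:
            take_b = not take_b
        if take_b:
            c1.append(b.bits[i])
            c2.append(a.bits[i])
        else:
            c1.append(a.bits[i])
            c2.append(b.bits[i])
    return (Chromosome(bits=tuple(c1), layout=a.layout),
            Chromosome(bits=tuple(c2), layout=a.layout))


def mutate(chrom: Chromosome, p_per_bit: float, rng: np.random.Generator
           ) -> Chromosome:
    """Flip each bit independently with probability p_per_bit."""
    if not 0 <= p_per_bit <= 1:
        raise ValueError(f"p_per_bit must be in [0, 1], got {p_per_bit}")
    flips = rng.random(len(chrom)) < p_per_bit
    bits = tuple(int(b ^ f) for b, f in zip(chrom.bits, flips))
    return Chromosome(bits=bits, layout=chrom.layout)


# ---------------------------------------------------------------------------
# fitness

class FitnessEvaluator:
    """Caches a fitness function by chromosome bit pattern.

    A raised exception in the underlying function is logged and recorded as
    fitness 0 (the individual is simply unselectable), matching the
    propagate-but-continue contract of the search loop.
    """

    def __init__(self, fn):
        self.fn = fn
        self.cache: dict[tuple[int, ...], float] = {}
        self.hits = 0
        self.failures: list[tuple[tuple[int, ...], str]] = []

    def __call__(self, chrom: Chromosome) -> float:
        key = chrom.key
        if key in self.cache:
            self.hits += 1
            return self.cache[key]
        try:
            value = float(self.fn(chrom))
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            logger.warning("fitness evaluation failed for %s: %s", key, exc)
            self.failures.append((key, str(exc)))
            value = 0.0
        self.cache[key] = value
        return value


class HammingSurrogate:
    """Deterministic test landscape: 1 - normalised Hamming distance to a
    hidden target chromosome.  Maximum fitness 1.0 exactly at the target."""

    def __init__(self, target: Chromosome):
        self.target = target

    def __call__(self, chrom: Chromosome) -> float:
        d = sum(a != b for a, b in zip(chrom.bits, self.target.bits))
        return 1.0 - d / len(chrom)


class CNNFitness:
    """Classification accuracy of the decoded CNN on an inner validation
    split of the training data.

    ``mode='full'`` trains with the full protocol on a stratified 80/20
    inner split.  ``mode='fast'`` caps training epochs and optionally
    subsamples the training portion — a desk-scale shortcut for smoke runs,
    not the faithful protocol.
    """

    def __init__(self, data: EpochSet, mode: str = "full", seed: int = 0,
                 train_cfg: TrainConfig | None = None,
                 fast_epochs: int = 4, fast_subsample: int | None = 96):
        if mode not in ("full", "fast"):
            raise ValueError(f"mode must be full|fast, got {mode}")
        if len(np.unique(data.labels)) < 4:
            raise ValueError("fitness data must contain all 4 classes")
        self.data = data
        self.mode = mode
        self.seed = seed
        self.base_cfg = train_cfg or TrainConfig(seed=seed)
        # stratified 80/20 inner split, fixed once per evaluator
        rng = np.random.default_rng(seed)
        tr_idx, va_idx = [], []
        for cls in np.unique(data.labels):
            idx = np.flatnonzero(data.labels == cls)
            idx = rng.permutation(idx)
            cut = max(1, int(round(0.8 * len(idx))))
            cut = min(cut, len(idx) - 1)
            tr_idx.extend(idx[:cut])
            va_idx.extend(idx[cut:])
        if mode == "fast" and fast_subsample and fast_subsample < len(tr_idx):
            tr_idx = rng.permutation(tr_idx)[:fast_subsample].tolist()
        self.train_set = data.subset(np.sort(tr_idx))
        self.valid_set = data.subset(np.sort(va_idx))
        self.fast_epochs = fast_epochs

    def __call__(self, chrom: Chromosome) -> float:
        genome = decode(chrom)
        H, T = self.data.data.shape[1], self.data.data.shape[2]
        spec = build_model_spec(genome, input_shape=(H, T))
        cfg = self.base_cfg
        if self.mode == "fast":
            cfg = TrainConfig(batch_size=cfg.batch_size,
                              learning_rate=cfg.learning_rate,
                              epochs=self.fast_epochs,
                              dropout_rate=cfg.dropout_rate,
                              optimizer=cfg.optimizer, seed=self.seed)
        model = train_model(spec, self.train_set, None, cfg)
        pred = model.predict(self.valid_set)
        return float((pred == self.valid_set.labels).mean())


# ---------------------------------------------------------------------------
# the search loop

@dataclass(frozen=True)
class GAConfig:
    """Search-loop settings.

    ``selection_scaling`` controls the fitness transform fed to the roulette
    wheel: ``"none"`` is raw fitness-proportional selection; the default
    ``"boltzmann"`` uses exp(beta * (f - max f)), which keeps the wheel
    mechanism but concentrates reproduction on the leaders.  With accuracy
    fitnesses spanning a narrow band, raw proportional selection is too weak
    to converge within a 20 x 20 evaluation budget; Boltzmann scaling is the
    standard fix.  The per-bit mutation default of 0.03 is about 1/L for the
    33-bit chromosome.
    """

    population_size: int = 20
    generations: int = 20
    p_crossover: float = 0.8
    p_mutation_per_bit: float = 0.03
    n_crossover_points: int = 2
    elitism: int = 1
    seed: int = 0
    fitness_mode: str = "full"
    selection_scaling: str = "boltzmann"
    selection_beta: float = 80.0

    def __post_init__(self):
        for name in ("p_crossover", "p_mutation_per_bit"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than the population")
        if self.population_size < self.elitism + 2:
            raise ValueError("population must hold elites plus two parents")
        if self.selection_scaling not in ("none", "boltzmann"):
            raise ValueError("selection_scaling must be none|boltzmann")
        if self.selection_beta <= 0:
            raise ValueError("selection_beta must be > 0")


@dataclass
class GAHistory:
    """Per-generation record of the search."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_bits: list[tuple[int, ...]] = field(default_factory=list)
    cache_hits: int = 0

    def __len__(self) -> int:
        return len(self.best_fitness)

    def to_dataframe(self, layout=None) -> pd.DataFrame:
        rows = []
        for g, (bf, mf, bits) in enumerate(
                zip(self.best_fitness, self.mean_fitness, self.best_bits)):
            row = {"generation": g, "best": bf, "mean": mf}
            if layout is not None:
                genome = decode(Chromosome(bits=bits, layout=tuple(layout)))
                row["best_genome"] = ",".join(map(str, genome.as_tuple()))
            rows.append(row)
        return pd.DataFrame(rows)


def run_ga(fitness, cfg: GAConfig = GAConfig(),
           layout: tuple[GeneSpec, ...] | None = None
           ) -> tuple[HyperparamGenome, GAHistory]:
    """Elitist GA: evaluate -> roulette-select -> crossover -> mutate.

    ``fitness`` is any callable Chromosome -> float in [0, 1] (wrapped in a
    cache if it is not already a FitnessEvaluator).  The initial population
    is sampled uniformly over raw bit strings, i.e. hyperparameters start at
    automatically chosen values within their ranges.  Returns the best
    genome ever evaluated and the per-generation history.
    """
    layout = layout or default_layout()
    if not isinstance(fitness, FitnessEvaluator):
        fitness = FitnessEvaluator(fitness)
    rng = np.random.default_rng(cfg.seed)

    population = [random_chromosome(layout, rng) for _ in range(cfg.population_size)]
    history = GAHistory()
    best_ever: tuple[float, Chromosome] | None = None

    for _gen in range(cfg.generations):
        scores = np.array([fitness(ind) for ind in population])
        order = np.argsort(scores)[::-1]
        gen_best = population[order[0]]
        if best_ever is None or scores[order[0]] > best_ever[0]:
            best_ever = (float(scores[order[0]]), gen_best)
        history.best_fitness.append(float(best_ever[0]))
        history.mean_fitness.append(float(scores.mean()))
        history.best_bits.append(best_ever[1].bits)

        if cfg.selection_scaling == "boltzmann":
            weights = np.exp(cfg.selection_beta * (scores - scores.max()))
        else:
            weights = scores
        elites = [population[i] for i in order[:cfg.elitism]]
        n_children = cfg.population_size - cfg.elitism
        parents_idx = roulette_select(weights, n_children + (n_children % 2), rng)
        children: list[Chromosome] = []
        for i in range(0, len(parents_idx), 2):
            pa = population[parents_idx[i]]
            pb = population[parents_idx[i + 1]]
            if rng.random() < cfg.p_crossover:
                ca, cb = multipoint_crossover(pa, pb,
                                              n_points=cfg.n_crossover_points,
                                              rng=rng)
            else:
                ca, cb = pa, pb
            children.extend([mutate(ca, cfg.p_mutation_per_bit, rng),
                             mutate(cb, cfg.p_mutation_per_bit, rng)])
        population = elites + children[:n_children]

    history.cache_hits = fitness.hits
    return decode(best_ever[1]), history
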