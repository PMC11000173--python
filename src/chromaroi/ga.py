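"""Genetic-algorithm search over binary subimage subsets.

Each chromosome is a binary vector over the unfolded grid cells: gene g = 1
includes subimage g in the pooled histogram fed to PLS.  Fitness is the
RMSECV of the PLS leave-one-out cross-validation on the chromosome's
features — lower is better.  Selection is roulette-wheel on 1/RMSECV (the
standard transform for feeding a minimised error to a proportional wheel),
recombination is single-point crossover, mutation flips genes
independently, and a repair step re-establishes the 1..Nim bound on the
number of selected subimages after the operators.  Because the GA is a
metaheuristic whose outcome depends on the start, the driver supports
independent restarts (best-of-n) and a Monte-Carlo reliability loop that
reports per-subimage selection frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, DomainError
from .histograms import DEFAULT_CHANNELS, N_BINS, channel_plane
from .image_grid import RasterImage, ROIGrid
from .pls import loocv_curve, pick_lv

__all__ = [
    "Chromosome",
    "GAConfig",
    "GARunResult",
    "FitnessEvaluator",
    "init_population",
    "roulette_select",
    "crossover_single_point",
    "mutate",
    "repair",
    "evolve",
    "run_restarts",
    "monte_carlo_reliability",
]

#: Fitness sentinel for chromosomes whose feature matrix is degenerate.
WORST_FITNESS = float("inf")


@dataclass(frozen=True)
class Chromosome:
    """Binary subimage-inclusion vector with (optionally) evaluated fitness."""

    genes: np.ndarray  # (n_cells,) bool
    fitness: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", np.asarray(self.genes, dtype=bool))

    @property
    def n_selected(self) -> int:
        return int(self.genes.sum())

    def selected_indices(self) -> list[int]:
        """1-based linear cell indices of the selected subimages."""
        return [int(i) + 1 for i in np.nonzero(self.genes)[0]]

    def key(self) -> bytes:
        return np.packbits(self.genes).tobytes()


@dataclass(frozen=True)
class GAConfig:
    """GA run parameters.

    Defaults mirror the reported study conditions: population 100,
    100 generations, mutation probability 5% per gene, crossover
    (reproduction) probability 65%, 10% elitism, best of 10 restarts.
    ``nim`` caps the number of subimages per chromosome; ``None`` means the
    whole grid.  ``n_lv`` fixes the latent-variable count; when ``None``
    the count is chosen per evaluation by the parsimonious LOOCV rule up
    to ``lv_max``.
    """

    population_size: int = 100
    generations: int = 100
    elitism_rate: float = 0.10
    crossover_rate: float = 0.65
    mutation_rate: float = 0.05
    nim: int | None = None
    n_restarts: int = 10
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    n_lv: int | None = None
    lv_max: int = 5
    lv_tol: float = 0.0
    per_chromosome_mutation: bool = False

    def __post_init__(self) -> None:
        for name in ("elitism_rate", "crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} = {v} outside [0, 1]")
        if self.population_size < 2:
            raise DomainError("population_size must be >= 2")
        if self.generations < 1:
            raise DomainError("generations must be >= 1")
        if self.n_restarts < 1:
            raise DomainError("n_restarts must be >= 1")

    def resolved_nim(self, n_cells: int) -> int:
        nim = n_cells if self.nim is None else int(self.nim)
        if not (1 <= nim <= n_cells):
            raise DomainError(f"Nim = {nim} outside [1, {n_cells}]")
        return nim


@dataclass
class GARunResult:
    """Outcome of one GA run (or the best across restarts)."""

    best: Chromosome
    best_per_generation: list[float]
    seed: int
    n_evaluations: int = 0

    @property
    def best_rmsecv(self) -> float:
        assert self.best.fitness is not None
        return self.best.fitness


class FitnessEvaluator:
    """RMSECV fitness of chromosomes over a fixed sample set and grid.

    Per-cell per-channel histograms are precomputed once, so a chromosome's
    pooled feature matrix is a sum over its selected cells; evaluations are
    cached on the gene pattern (fitness is a pure function of the genes for
    fixed data), which is what makes desk-scale GA runs affordable.
    """

    def __init__(
        self,
        samples: Sequence[tuple[str, RasterImage, float]],
        grid: ROIGrid,
        channels: Sequence[str] = DEFAULT_CHANNELS,
        n_lv: int | None = None,
        lv_max: int = 5,
        lv_tol: float = 0.0,
    ) -> None:
        self.grid = grid
        self.channels = tuple(channels)
        self.n_lv = n_lv
        self.lv_max = lv_max
        self.lv_tol = lv_tol
        self.y = np.asarray([s[2] for s in samples], dtype=np.float64)
        self.sample_ids = tuple(str(s[0]) for s in samples)
        I = len(samples)
        C = len(self.channels)
        # (I, n_cells, C * 256) per-cell histogram tensor
        self._H = np.zeros((I, grid.n, C * N_BINS), dtype=np.float64)
        for si, (_, img, _) in enumerate(samples):
            planes = [channel_plane(img, ch) for ch in self.channels]
            for cell in range(grid.n):
                rs, cs = grid.cell_slices(cell + 1)
                for ci, plane in enumerate(planes):
                    h = np.bincount(plane[rs, cs].ravel(), minlength=N_BINS)
                    self._H[si, cell, ci * N_BINS:(ci + 1) * N_BINS] = h
        self._cache: dict[bytes, tuple[float, int]] = {}
        self.n_evaluations = 0
        self.n_cache_hits = 0

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    def feature_matrix(self, genes: np.ndarray) -> np.ndarray:
        """Pooled-histogram feature matrix (I x 256·C) for a gene vector."""
        genes = np.asarray(genes, dtype=bool)
        if genes.shape[0] != self.grid.n or not genes.any():
            raise DomainError("gene vector must match the grid and select >= 1 cell")
        return self._H[:, genes, :].sum(axis=1)

    def evaluate(self, genes: np.ndarray) -> tuple[float, int]:
        """(RMSECV, chosen n_lv) of the chromosome's PLS-LOOCV model."""
        genes = np.asarray(genes, dtype=bool)
        key = np.packbits(genes).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            self.n_cache_hits += 1
            return hit
        self.n_evaluations += 1
        X = self.feature_matrix(genes)
        # constant columns are invisible to the centred PLS model; dropping
        # them only cuts cost
        keep = np.ptp(X, axis=0) > 0
        X = X[:, keep]
        try:
            if X.shape[1] == 0:
                raise DegenerateInputError("all features constant")
            if self.n_lv is not None:
                lv_hi = min(self.n_lv, self.n_samples - 2, X.shape[1])
                curve, _ = loocv_curve(X, self.y, lv_hi)
                n_lv = lv_hi
            else:
                lv_hi = min(self.lv_max, self.n_samples - 2, X.shape[1])
                curve, _ = loocv_curve(X, self.y, lv_hi)
                n_lv = pick_lv(curve, tol=self.lv_tol)
            result = (float(curve[n_lv - 1]), n_lv)
        except DegenerateInputError:
            result = (WORST_FITNESS, 0)
        self._cache[key] = result
        return result

    def fitness(self, chrom: Chromosome) -> Chromosome:
        """Return the chromosome with its RMSECV fitness filled in."""
        if chrom.fitness is not None:
            return chrom
        rmsecv, _ = self.evaluate(chrom.genes)
        return replace(chrom, fitness=rmsecv)


def init_population(
    config: GAConfig, grid: ROIGrid, rng: np.random.Generator
) -> list[Chromosome]:
    """Random initial population: each chromosome draws its number of ones
    uniformly from [1, Nim] and places them uniformly without replacement."""
    nim = config.resolved_nim(grid.n)
    pop = []
    for _ in range(config.population_size):
        k = int(rng.integers(1, nim + 1))
        genes = np.zeros(grid.n, dtype=bool)
        genes[rng.choice(grid.n, size=k, replace=False)] = True
        pop.append(Chromosome(genes=genes))
    return pop


def roulette_select(
    population: Sequence[Chromosome], rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Draw two parents with probability proportional to 1/RMSECV.

    Chromosomes with non-finite fitness are excluded from the wheel;
    duplicate draws are permitted.
    """
    fitnesses = np.array(
        [c.fitness if c.fitness is not None else np.nan for c in population]
    )
    finite = np.isfinite(fitnesses)
    if not finite.any():
        raise DegenerateInputError("no chromosome with finite fitness")
    weights = np.zeros_like(fitnesses)
    with np.errstate(divide="ignore"):
        weights[finite] = 1.0 / np.maximum(fitnesses[finite], 1e-300)
    probs = weights / weights.sum()
    i, j = rng.choice(len(population), size=2, replace=True, p=probs)
    return population[int(i)], population[int(j)]


def crossover_single_point(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Single-division crossover: swap gene suffixes at a uniform cut in
    [1, L-1]."""
    if a.genes.shape != b.genes.shape:
        raise DomainError("parent gene lengths differ")
    L = a.genes.shape[0]
    if L < 2:
        return Chromosome(a.genes.copy()), Chromosome(b.genes.copy())
    cut = int(rng.integers(1, L))
    g1 = np.concatenate([a.genes[:cut], b.genes[cut:]])
    g2 = np.concatenate([b.genes[:cut], a.genes[cut:]])
    return Chromosome(g1), Chromosome(g2)


def mutate(
    chrom: Chromosome,
    rate: float,
    rng: np.random.Generator,
    per_chromosome: bool = False,
) -> Chromosome:
    """Flip genes with probability ``rate``.

    Default semantics: each gene flips independently.  With
    ``per_chromosome=True`` the whole chromosome mutates with probability
    ``rate``, flipping exactly one uniformly chosen gene.
    """
    if not (0.0 <= rate <= 1.0):
        raise DomainError(f"mutation rate {rate} outside [0, 1]")
    genes = chrom.genes.copy()
    if per_chromosome:
        if rng.random() < rate:
            pos = int(rng.integers(genes.shape[0]))
            genes[pos] = ~genes[pos]
    else:
        flips = rng.random(genes.shape[0]) < rate
        genes ^= flips
    return Chromosome(genes)


def repair(chrom: Chromosome, nim: int, rng: np.random.Generator) -> Chromosome:
    """Re-establish 1 <= ones <= Nim after crossover/mutation.

    Zero ones: set one uniformly random gene.  More than Nim ones: clear
    uniformly chosen ones down to Nim (the survivors are a subset of the
    previously set genes).
    """
    genes = chrom.genes.copy()
    ones = np.nonzero(genes)[0]
    if ones.size == 0:
        genes[int(rng.integers(genes.shape[0]))] = True
        return Chromosome(genes)
    if ones.size > nim:
        drop = rng.choice(ones, size=ones.size - nim, replace=False)
        genes[drop] = False
        return Chromosome(genes)
    return chrom


def _sorted_by_fitness(population: list[Chromosome]) -> list[Chromosome]:
    # stable sort: equal-fitness order follows position, keeping runs
    # reproducible
    return sorted(
        population,
        key=lambda c: c.fitness if c.fitness is not None else WORST_FITNESS,
    )


def evolve(
    config: GAConfig,
    evaluator: FitnessEvaluator,
    rng: np.random.Generator,
    seed_label: int = 0,
) -> GARunResult:
    """One GA run: g generations of elitism -> roulette -> crossover ->
    mutation -> repair, tracking the best chromosome ever seen."""
    grid = evaluator.grid
    nim = config.resolved_nim(grid.n)
    population = [evaluator.fitness(c) for c in init_population(config, grid, rng)]
    population = _sorted_by_fitness(population)
    best = population[0]
    best_per_generation: list[float] = []
    n_elite = math.ceil(config.elitism_rate * config.population_size)
    for _ in range(config.generations):
        next_pop = [population[i] for i in range(n_elite)]
        while len(next_pop) < config.population_size:
            pa, pb = roulette_select(population, rng)
            if rng.random() < config.crossover_rate:
                ca, cb = crossover_single_point(pa, pb, rng)
            else:
                ca, cb = Chromosome(pa.genes.copy()), Chromosome(pb.genes.copy())
            for child in (ca, cb):
                if len(next_pop) >= config.population_size:
                    break
                child = mutate(
                    child,
                    config.mutation_rate,
                    rng,
                    per_chromosome=config.per_chromosome_mutation,
                )
                child = repair(child, nim, rng)
                next_pop.append(evaluator.fitness(child))
        population = _sorted_by_fitness(next_pop)
        if population[0].fitness < best.fitness:  # type: ignore[operator]
            best = population[0]
        best_per_generation.append(float(population[0].fitness))  # type: ignore[arg-type]
    return GARunResult(
        best=best,
        best_per_generation=best_per_generation,
        seed=seed_label,
        n_evaluations=evaluator.n_evaluations,
    )


def _spawn_rngs(master_seed: int, n: int) -> list[tuple[int, np.random.Generator]]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n)
    return [
        (int(child.generate_state(1)[0] % (2**31)), np.random.Generator(np.random.PCG64(child)))
        for child in children
    ]


def run_restarts(
    config: GAConfig,
    evaluator: FitnessEvaluator,
) -> tuple[GARunResult, list[GARunResult]]:
    """Best-of-n GA: run ``config.n_restarts`` independent seeded runs and
    return the argmin-RMSECV result plus all runs (for distribution plots)."""
    runs: list[GARunResult] = []
    for label, rng in _spawn_rngs(config.seed, config.n_restarts):
        runs.append(evolve(config, evaluator, rng, seed_label=label))
    best = min(runs, key=lambda r: r.best_rmsecv)
    return best, runs


def monte_carlo_reliability(
    config: GAConfig,
    evaluator: FitnessEvaluator,
    n_mc: int,
) -> np.ndarray:
    """Per-subimage selection frequency over ``n_mc`` independent GA runs.

    Frequencies lie in [0, 1]; cell g's frequency is the fraction of runs
    whose best chromosome includes subimage g.
    """
    if n_mc < 2:
        raise DomainError("n_mc must be >= 2")
    counts = np.zeros(evaluator.grid.n, dtype=np.float64)
    for _, rng in _spawn_rngs(config.seed, n_mc):
        result = evolve(config, evaluator, rng)
        counts += result.best.genes
    return counts / n_mc
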