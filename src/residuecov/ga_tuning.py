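"""Genetic-algorithm tuning of the four segmentation parameters.

A real-coded generational GA searches (c_r, c_g, c_b, threshold) —
coefficients bounded to [-10, 10], threshold to [0, 255] — minimizing
the dissimilarity between segmented images and their binary templates:

    S(A, B) = sum_ij |A(i,j) - B(i,j)| / (n * m)

S is the normalized Hamming distance between masks: 0 for identical
images, 1 for pixel-wise complements. Over a training set the objective
is the unweighted mean of S across (image, template) pairs.

Operators: roulette-wheel parent selection on the goodness 1 - S (the
wheel needs a maximized score; S is in [0, 1] so this transform is
exact), two-point crossover at the 3 internal gene boundaries of the
4-gene chromosome, additive Gaussian mutation whose per-gene standard
deviation starts at scale * (gene range) and shrinks linearly across
generations, and elitism (the best individuals survive unchanged, so
the best fitness never worsens). The run stops when the best fitness
drops below ``fitness_stop``, when it has not improved for
``stall_generations`` generations, or at ``max_generations``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .segmentation import (
    DEFAULT_VEGETATION,
    SegmentationParams,
    VegetationParams,
    median_filter_5x5,
    segment,
    vegetation_mask,
)

__all__ = [
    "GENE_NAMES",
    "GENE_LOWER",
    "GENE_UPPER",
    "Individual",
    "GAConfig",
    "TuningResult",
    "fitness",
    "mean_fitness",
    "initialize_population",
    "roulette_select",
    "two_point_crossover",
    "gaussian_mutate",
    "evolve",
]

GENE_NAMES = ("c_r", "c_g", "c_b", "threshold")
GENE_LOWER = np.array([-10.0, -10.0, -10.0, 0.0])
GENE_UPPER = np.array([10.0, 10.0, 10.0, 255.0])
GENE_RANGE = GENE_UPPER - GENE_LOWER

#: Minimum decrease of the best fitness that counts as an improvement
#: for stall detection (floating-point-safe reading of "does not improve").
STALL_EPS = 1e-9


@dataclass
class Individual:
    """One candidate parameter quadruple and its (mean) dissimilarity."""

    genes: np.ndarray  # (c_r, c_g, c_b, threshold), always within bounds
    fitness: Optional[float] = None

    def params(self) -> SegmentationParams:
        return SegmentationParams(*map(float, self.genes))

    def copy(self) -> "Individual":
        return Individual(self.genes.copy(), self.fitness)


@dataclass
class GAConfig:
    """GA settings; defaults are the field study's published choices."""

    population_size: int = 100
    crossover_prob: float = 0.8
    mutation_scale: float = 0.5
    mutation_shrink: float = 0.5
    elite_count: int = 2
    stall_generations: int = 50
    fitness_stop: Optional[float] = 0.05
    max_generations: int = 10_000
    integer_threshold: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")


@dataclass
class TuningResult:
    best: Individual
    history: list = field(default_factory=list)  # (generation, best, mean)
    generations_run: int = 0
    stop_reason: str = ""

    def best_params(self) -> SegmentationParams:
        return self.best.params()


def fitness(A: np.ndarray, B: np.ndarray) -> float:
    """Mean absolute pixel difference between two binary masks, in [0, 1]."""
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"mask dimensions differ: {A.shape} vs {B.shape}")
    return float(np.mean(np.abs(A.astype(np.int8) - B.astype(np.int8))))


def mean_fitness(
    params: SegmentationParams,
    training: Sequence[tuple[np.ndarray, np.ndarray]],
    veg: VegetationParams = DEFAULT_VEGETATION,
) -> float:
    """Unweighted mean dissimilarity of ``segment(image, params)`` vs each template."""
    if len(training) == 0:
        raise ValueError("training set is empty")
    return float(np.mean([
        fitness(segment(img, params, veg), template) for img, template in training
    ]))


class _Evaluator:
    """Mean-fitness evaluation with per-image precomputation.

    The vegetation mask and float color planes do not depend on the
    candidate genes, so they are computed once per training image; each
    evaluation is then the gray index, the threshold, the subtraction
    and the median filter — identical arithmetic to :func:`segment`.
    """

    def __init__(self, training, veg: VegetationParams):
        if len(training) == 0:
            raise ValueError("training set is empty")
        self.items = []
        for img, template in training:
            img = np.asarray(img)
            template = np.asarray(template)
            if img.shape[:2] != template.shape:
                raise ValueError(
                    f"image {img.shape[:2]} and template {template.shape} differ")
            r = img[..., 0].astype(np.float64)
            g = img[..., 1].astype(np.float64)
            b = img[..., 2].astype(np.float64)
            keep = vegetation_mask(img, veg) == 0
            self.items.append((r, g, b, keep, template.astype(np.int8)))

    def __call__(self, genes: np.ndarray) -> float:
        c_r, c_g, c_b, thr = genes
        total = 0.0
        for r, g, b, keep, template in self.items:
            gray = c_r * r + c_g * g + c_b * b
            candidate = ((gray > thr) & keep).astype(np.uint8)
            residue = median_filter_5x5(candidate)
            total += float(np.mean(np.abs(residue.astype(np.int8) - template)))
        return total / len(self.items)


def _clamp(genes: np.ndarray, config: Optional[GAConfig] = None) -> np.ndarray:
    genes = np.clip(genes, GENE_LOWER, GENE_UPPER)
    if config is not None and config.integer_threshold:
        genes[3] = np.round(genes[3])
    return genes


def initialize_population(
    config: GAConfig, rng: Optional[np.random.Generator] = None
) -> list[Individual]:
    """Uniform random population within the gene bounds."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = rng.uniform(GENE_LOWER, GENE_UPPER,
                        size=(config.population_size, len(GENE_LOWER)))
    if config.integer_threshold:
        genes[:, 3] = np.round(genes[:, 3])
    return [Individual(g) for g in genes]


def roulette_select(pop: Sequence[Individual], rng: np.random.Generator) -> Individual:
    """Sample one parent with probability proportional to goodness 1 - S.

    S is minimized, so the wheel runs on the complementary score; if
    every individual has zero goodness the draw is uniform.
    """
    weights = np.empty(len(pop))
    for i, ind in enumerate(pop):
        if ind.fitness is None:
            raise RuntimeError("roulette_select requires an evaluated population")
        weights[i] = 1.0 - ind.fitness
    weights = np.clip(weights, 0.0, None)
    total = weights.sum()
    if total <= 0.0:
        return pop[rng.integers(len(pop))]
    return pop[rng.choice(len(pop), p=weights / total)]


def two_point_crossover(
    p1: Individual,
    p2: Individual,
    rng: np.random.Generator,
    prob: float,
) -> tuple[Individual, Individual]:
    """Swap the gene segment between two random internal cut points.

    The chromosome is real-coded, so cuts fall on the 3 internal gene
    boundaries (positions 1..3) of the 4-gene chromosome. With
    probability ``1 - prob`` the offspring are plain copies.
    """
    c1, c2 = p1.genes.copy(), p2.genes.copy()
    if rng.random() < prob:
        lo, hi = sorted(rng.choice([1, 2, 3], size=2, replace=False))
        c1[lo:hi], c2[lo:hi] = p2.genes[lo:hi].copy(), p1.genes[lo:hi].copy()
    return Individual(c1), Individual(c2)


def mutation_sigma(generation: int, config: GAConfig) -> np.ndarray:
    """Per-gene mutation standard deviation at a given generation.

    sigma_k = scale * range * (1 - shrink * k / max_generations),
    floored at 0; ``range`` is 20 for coefficients and 255 for the
    threshold.
    """
    frac = generation / config.max_generations if config.max_generations > 0 else 0.0
    decay = max(0.0, 1.0 - config.mutation_shrink * frac)
    return config.mutation_scale * GENE_RANGE * decay


def gaussian_mutate(
    ind: Individual,
    generation: int,
    config: GAConfig,
    rng: np.random.Generator,
) -> Individual:
    """Additive zero-mean Gaussian noise per gene, then clamp to bounds."""
    sigma = mutation_sigma(generation, config)
    genes = ind.genes + rng.standard_normal(len(sigma)) * sigma
    return Individual(_clamp(genes, config))


def evolve(
    training: Sequence[tuple[np.ndarray, np.ndarray]],
    veg: VegetationParams = DEFAULT_VEGETATION,
    config: Optional[GAConfig] = None,
    fixed_coefficients: Optional[Sequence[float]] = None,
    on_generation: Optional[Callable[[int, float, float], None]] = None,
) -> TuningResult:
    """Run the generational GA on a training set of (image, template) pairs.

    Parameters
    ----------
    training : sequence of (HxWx3 uint8 image, HxW {0,1} template)
    veg : VegetationParams
        Vegetation index used inside every segmentation evaluation.
    config : GAConfig
        Population size, operator rates, termination; fully reproducible
        given ``config.seed``.
    fixed_coefficients : optional (c_r, c_g, c_b)
        Freeze the color coefficients and evolve only the threshold
        (used for oracle comparisons against exhaustive threshold search).
    on_generation : optional callback(generation, best, mean)
        Invoked after each generation is evaluated (e.g. for logging).
    """
    if config is None:
        config = GAConfig()
    evaluate = _Evaluator(training, veg)
    rng = np.random.default_rng(config.seed)

    fixed = None
    if fixed_coefficients is not None:
        fixed = np.asarray(fixed_coefficients, dtype=np.float64)
        if fixed.shape != (3,):
            raise ValueError("fixed_coefficients must be (c_r, c_g, c_b)")

    def pin(ind: Individual) -> Individual:
        if fixed is not None:
            ind.genes[:3] = fixed
        return ind

    population = [pin(ind) for ind in initialize_population(config, rng)]

    history: list[tuple[int, float, float]] = []
    best_so_far: Optional[Individual] = None
    stall = 0
    generation = 0
    stop_reason = "max_generations"

    while True:
        for ind in population:
            if ind.fitness is None:
                ind.fitness = evaluate(ind.genes)
        population.sort(key=lambda ind: ind.fitness)
        gen_best = population[0]
        mean_fit = float(np.mean([ind.fitness for ind in population]))

        if best_so_far is None or best_so_far.fitness - gen_best.fitness > STALL_EPS:
            best_so_far = gen_best.copy()
            stall = 0
        else:
            stall += 1

        history.append((generation, best_so_far.fitness, mean_fit))
        if on_generation is not None:
            on_generation(generation, best_so_far.fitness, mean_fit)

        if config.fitness_stop is not None and best_so_far.fitness < config.fitness_stop:
            stop_reason = "fitness_stop"
            break
        if generation >= config.max_generations:
            stop_reason = "max_generations"
            break
        if stall >= config.stall_generations:
            stop_reason = "stall"
            break

        elites = [population[i].copy() for i in range(config.elite_count)]
        offspring: list[Individual] = []
        while len(elites) + len(offspring) < config.population_size:
            p1 = roulette_select(population, rng)
            p2 = roulette_select(population, rng)
            c1, c2 = two_point_crossover(p1, p2, rng, config.crossover_prob)
            for child in (c1, c2):
                if len(elites) + len(offspring) < config.population_size:
                    offspring.append(pin(gaussian_mutate(child, generation, config, rng)))
        population = elites + offspring
        generation += 1

    return TuningResult(
        best=best_so_far,
        history=history,
        generations_run=generation,
        stop_reason=stop_reason,
    )
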