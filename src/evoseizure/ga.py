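"""Genetic-algorithm engine: tournament selection, reproduction, elitist loop.

The configuration mirrors the study conditions: a population of 100
individuals, binary-tournament parent selection of half the population, a
recombination rate of 0.80 (80 % of reproduction events combine two parents;
otherwise the offspring starts as a copy of one selected parent), a mutation
rate of 1.00 (every offspring takes one unitary mutation step), and elitist
(1+lambda) replacement pooling parents and offspring and keeping the best.
Evolution stops when the maximum fitness is reached, when the best fitness
has stagnated for 50 generations, or after 15000 fitness evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .genotype import GeneDomains, Individual, mutate, random_individual, recombine

FitnessFn = Callable[[Individual], float]


@dataclass
class GAConfig:
    population_size: int = 100
    recombination_rate: float = 0.80
    mutation_rate: float = 1.00
    max_evaluations: int = 15000
    stagnation_generations: int = 50
    max_fitness: float = 1.0
    n_executions: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.recombination_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.population_size, self.max_evaluations, self.n_executions) <= 0:
            raise ValueError("sizes must be positive")

    @property
    def n_parents(self) -> int:
        return self.population_size // 2


@dataclass
class ReproductionEvent:
    """One offspring plus diagnostics of how it was produced."""

    offspring: Individual
    recombined: bool
    pre_mutation: Individual
    mutated: bool


@dataclass
class ExecutionResult:
    best_individual: Individual
    best_fitness: float
    generations: int
    evaluations: int
    trajectory: list[float] = field(default_factory=list)
    stop_reason: str = ""
    final_population: list[Individual] = field(default_factory=list)

    def elite(self, k: int = 10) -> list[Individual]:
        """Top-k distinct genotypes of the final population (fitness order)."""
        out, seen = [], set()
        for ind in self.final_population:
            if ind.key() not in seen:
                seen.add(ind.key())
                out.append(ind)
            if len(out) == k:
                break
        return out or [self.best_individual]


def tournament_select(population: list[Individual], rng: np.random.Generator,
                      n_parents: int | None = None) -> list[Individual]:
    """Repeated size-2 tournaments (sampling with replacement); the higher
    fitness wins each tournament.  Returns half the population by default.
    """
    if n_parents is None:
        n_parents = len(population) // 2
    n = len(population)
    first = rng.integers(n, size=n_parents)
    second = (first + 1 + rng.integers(n - 1, size=n_parents)) % n  # distinct opponent
    return [
        population[a] if population[a].fitness >= population[b].fitness else population[b]
        for a, b in zip(first, second)
    ]


def reproduction_event(parents: list[Individual], domains: GeneDomains,
                       rng: np.random.Generator, config: GAConfig) -> ReproductionEvent:
    """One reproduction: crossover with probability ``recombination_rate``
    (else a clone of one selected parent), then mutation with probability
    ``mutation_rate``.
    """
    recombined = bool(rng.random() < config.recombination_rate)
    if recombined and len(parents) >= 2:
        i, j = rng.choice(len(parents), size=2, replace=False)
        base = recombine(parents[i], parents[j], domains, rng)
    else:
        base = Individual(parents[rng.integers(len(parents))].hyper_features)
    mutated = bool(rng.random() < config.mutation_rate)
    child = mutate(base, domains, rng) if mutated else Individual(base.hyper_features)
    return ReproductionEvent(child, recombined, base, mutated)


def run_execution(config: GAConfig, fitness_fn: FitnessFn, domains: GeneDomains,
                  seed: int, log: Callable[[dict], None] | None = None) -> ExecutionResult:
    """One GA execution under the configured stopping criteria.

    Fitness values are cached by genotype within the execution; only fresh
    evaluations count against the evaluation budget.  A fitness function that
    raises assigns the sentinel minimum instead of aborting the run.
    """
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}
    evaluations = 0

    def evaluate(ind: Individual) -> None:
        nonlocal evaluations
        key = ind.key()
        if key in cache:
            ind.fitness = cache[key]
            return
        try:
            value = float(fitness_fn(ind))
        except Exception:
            value = -np.inf
        cache[key] = value
        ind.fitness = value
        evaluations += 1

    population = [random_individual(domains, rng) for _ in range(config.population_size)]
    for ind in population:
        evaluate(ind)
    population.sort(key=lambda i: i.fitness, reverse=True)

    trajectory = [population[0].fitness]
    stagnant = 0
    generations = 0
    stop_reason = ""
    while True:
        if population[0].fitness >= config.max_fitness - 1e-9:
            stop_reason = "max_fitness"
            break
        if stagnant >= config.stagnation_generations:
            stop_reason = "stagnation"
            break
        if evaluations >= config.max_evaluations:
            stop_reason = "budget"
            break
        parents = tournament_select(population, rng, config.n_parents)
        n_offspring = min(config.n_parents, config.max_evaluations - evaluations)
        offspring = []
        for _ in range(n_offspring):
            event = reproduction_event(parents, domains, rng, config)
            evaluate(event.offspring)
            offspring.append(event.offspring)
        # Offspring first: the stable sort then prefers offspring on fitness
        # ties, allowing neutral drift across plateaus (elitism is preserved
        # because a strictly better parent still outranks them).
        pool = offspring + population
        pool.sort(key=lambda i: i.fitness, reverse=True)
        population = pool[: config.population_size]
        generations += 1
        best = population[0].fitness
        stagnant = stagnant + 1 if best <= trajectory[-1] else 0
        trajectory.append(max(best, trajectory[-1]))
        if log is not None:
            finite = [i.fitness for i in population if np.isfinite(i.fitness)]
            log(
                {
                    "generation": generations,
                    "best_fitness": float(best),
                    "mean_fitness": float(np.mean(finite)) if finite else None,
                    "evaluations": evaluations,
                }
            )

    return ExecutionResult(
        best_individual=population[0],
        best_fitness=population[0].fitness,
        generations=generations,
        evaluations=evaluations,
        trajectory=trajectory,
        stop_reason=stop_reason,
        final_population=population,
    )


def run_patient(config: GAConfig, fitness_fn: FitnessFn, domains: GeneDomains,
                progress: Callable[[int, ExecutionResult], None] | None = None,
                ) -> list[ExecutionResult]:
    """The configured number of independent executions; execution ``i`` is
    seeded with ``config.seed + i`` so a rerun reproduces all results.
    """
    results = []
    for i in range(config.n_executions):
        result = run_execution(config, fitness_fn, domains, seed=config.seed + i)
        if progress is not None:
            progress(i, result)
        results.append(result)
    return results
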