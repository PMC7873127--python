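"""GA engine: selection, reproduction rates, elitist loop on a toy fitness."""

from collections import Counter

import numpy as np
import pytest

from evoseizure.ga import (
    GAConfig,
    reproduction_event,
    run_execution,
    run_patient,
    tournament_select,
)
from evoseizure.genotype import GENE_NAMES, GeneDomains, Individual, random_individual


def hidden_target_fitness(domains, rng):
    """Toy benchmark: fraction of the 35 genes matching a hidden target genotype.

    Hyper-features are compared in the same canonical (time-instant, electrode)
    order the recombination pairing uses — an individual is a *set* of
    hyper-features, so matching is order-free, exactly as in the real pipeline.
    """
    from evoseizure.genotype import _pairing_order

    target = random_individual(domains, rng)
    target_sorted = _pairing_order(target, domains)

    def fitness(ind: Individual) -> float:
        return sum(
            hf.gene(g) == t.gene(g)
            for hf, t in zip(_pairing_order(ind, domains), target_sorted)
            for g in GENE_NAMES
        ) / 35.0

    return fitness, target


# ---------------------------------------------------------------------------
# configuration


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(recombination_rate=1.2)
    with pytest.raises(ValueError):
        GAConfig(population_size=0)
    assert GAConfig().n_parents == 50


# ---------------------------------------------------------------------------
# tournament selection


def test_tournament_better_of_two_always_wins(domains, rng):
    good = random_individual(domains, rng)
    bad = random_individual(domains, rng)
    good.fitness, bad.fitness = 1.0, 0.0
    parents = tournament_select([good, bad], rng, n_parents=100)
    assert all(p is good for p in parents)


def test_tournament_parent_count_is_half_population(domains, rng):
    pop = [random_individual(domains, rng) for _ in range(100)]
    for ind in pop:
        ind.fitness = 0.5
    assert len(tournament_select(pop, rng)) == 50


def test_tournament_uniform_under_equal_fitness(domains, rng):
    pop = [random_individual(domains, rng) for _ in range(10)]
    for ind in pop:
        ind.fitness = 0.5
    counts = Counter()
    for _ in range(100):
        for parent in tournament_select(pop, rng, n_parents=100):
            counts[id(parent)] += 1
    values = np.array(list(counts.values()))
    assert len(values) == 10
    assert values.std() / values.mean() < 0.1


# ---------------------------------------------------------------------------
# reproduction rates


def test_reproduction_rates_and_unitary_mutation(domains, rng):
    config = GAConfig()
    parents = [random_individual(domains, rng) for _ in range(10)]
    for p in parents:
        p.fitness = 0.0
    n = 10_000
    recombined = mutated = 0
    for _ in range(n):
        event = reproduction_event(parents, domains, rng, config)
        recombined += event.recombined
        mutated += event.mutated
        diff = sum(
            a.gene(g) != b.gene(g)
            for a, b in zip(event.pre_mutation.hyper_features,
                            event.offspring.hyper_features)
            for g in GENE_NAMES
        )
        assert diff == 1  # every offspring mutates in exactly one gene
    assert recombined / n == pytest.approx(0.80, abs=0.02)
    assert mutated == n


# ---------------------------------------------------------------------------
# full executions


def test_toy_benchmark_reaches_optimum_with_elitist_trajectory(domains):
    fitness, _ = hidden_target_fitness(domains, np.random.default_rng(99))
    # benchmark the evaluation budget alone (no early stagnation cut-off)
    config = GAConfig(max_evaluations=15000, stagnation_generations=10**9)
    result = run_execution(config, fitness, domains, seed=0)
    assert result.best_fitness == pytest.approx(1.0)
    assert result.stop_reason == "max_fitness"
    assert result.evaluations <= 15000
    trajectory = np.asarray(result.trajectory)
    assert np.all(np.diff(trajectory) >= 0)


def test_failing_fitness_function_gets_sentinel(domains):
    def bad_fitness(ind):
        raise RuntimeError("boom")

    config = GAConfig(max_evaluations=1000, stagnation_generations=2)
    result = run_execution(config, bad_fitness, domains, seed=1)
    assert result.best_fitness == -np.inf
    assert result.stop_reason == "stagnation"


def test_evaluation_budget_respected(domains):
    rng = np.random.default_rng(5)

    def noise_fitness(ind):
        return float(rng.random())

    config = GAConfig(max_evaluations=400, stagnation_generations=10_000)
    result = run_execution(config, noise_fitness, domains, seed=2)
    assert result.evaluations <= 400
    assert result.stop_reason in ("budget", "stagnation")


def test_run_patient_is_deterministic_and_seeded_per_execution(domains):
    fitness, _ = hidden_target_fitness(domains, np.random.default_rng(7))
    config = GAConfig(max_evaluations=300, n_executions=3, seed=11,
                      stagnation_generations=5)
    first = run_patient(config, fitness, domains)
    second = run_patient(config, fitness, domains)
    assert len(first) == 3
    for a, b in zip(first, second):
        assert a.best_individual.key() == b.best_individual.key()
        assert a.best_fitness == b.best_fitness
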