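"""Genotype encoding: domains, neighbourhoods, decoding, mutation, recombination."""

from collections import Counter, deque

import numpy as np
import pytest

from evoseizure.genotype import (
    GENE_NAMES,
    GeneDomains,
    HyperFeature,
    Individual,
    decode,
    mutate,
    random_individual,
    recombine,
    shortest_path_choice,
)


def bfs_shortest_path_nodes(neighbours: dict, u, v) -> set:
    """Independent oracle: BFS distances from both endpoints; a node lies on a
    shortest u-v path iff d_u(x) + d_v(x) equals the u-v distance."""

    def distances(src):
        dist = {src: 0}
        queue = deque([src])
        while queue:
            node = queue.popleft()
            for nxt in neighbours[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + 1
                    queue.append(nxt)
        return dist

    du, dv = distances(u), distances(v)
    return {x for x in neighbours if x in du and x in dv and du[x] + dv[x] == du[v]}


def hamming(a: Individual, b: Individual) -> int:
    return sum(
        hf_a.gene(g) != hf_b.gene(g)
        for hf_a, hf_b in zip(a.hyper_features, b.hyper_features)
        for g in GENE_NAMES
    )


# ---------------------------------------------------------------------------
# random_individual


def test_random_individual_is_uniform_over_electrodes(domains, rng):
    draws = Counter()
    n = 10_000
    for _ in range(n // 5):  # 5 hyper-features per individual
        ind = random_individual(domains, rng)
        draws.update(hf.electrode for hf in ind.hyper_features)
    k = len(domains.values["electrode"])
    expected = n / k
    chi2 = sum((draws[e] - expected) ** 2 / expected for e in domains.values["electrode"])
    # chi-square with k-1=18 dof: mean 18, sd 6; 3 sigma upper bound
    assert chi2 < 18 + 3 * 6


def test_random_individual_within_domains_and_deterministic(domains):
    a = random_individual(domains, np.random.default_rng(7))
    b = random_individual(domains, np.random.default_rng(7))
    assert a.key() == b.key()
    for hf in a.hyper_features:
        for gene in GENE_NAMES:
            assert hf.gene(gene) in domains.values[gene]


# ---------------------------------------------------------------------------
# decode


def _with_instants(ind: Individual, instants) -> Individual:
    hfs = [hf.with_gene("time_instant", t) for hf, t in zip(ind.hyper_features, instants)]
    return Individual(tuple(hfs))


def test_decode_timeline_from_worked_example(domains, rng):
    # max time instant 15 on top of a 40-min minimum pre-ictal period and the
    # fixed 10-min SPH gives a 55-min pre-ictal period and a 45-min SOP.
    ind = _with_instants(random_individual(domains, rng), (0, 5, 15, 2, 0))
    ph = decode(ind, 40)
    assert ph.pre_ictal_minutes == 55
    assert ph.sop_minutes == 45
    assert ph.sph_minutes == 10


def test_decode_boundary_all_instants_zero(domains, rng):
    ind = _with_instants(random_individual(domains, rng), (0, 0, 0, 0, 0))
    ph = decode(ind, 40)
    assert ph.pre_ictal_minutes == 40
    assert ph.sop_minutes == 30


def test_decode_dominance_masks_inactive_feature_gene(domains, rng):
    ind = random_individual(domains, rng)
    hf = ind.hyper_features[0].with_gene("dominant", "band_wave")
    base = Individual((hf,) + ind.hyper_features[1:])
    # perturbing the non-expressed feature gene leaves the phenotype unchanged
    other = "average_power" if hf.non_band_wave != "average_power" else "mean_amplitude"
    perturbed = Individual(
        (hf.with_gene("non_band_wave", other),) + ind.hyper_features[1:]
    )
    assert decode(base, 40) == decode(perturbed, 40)
    assert decode(base, 40).recipes[0].feature == f"rp_{hf.band_wave}"


def test_decode_is_pure(domains, rng):
    ind = random_individual(domains, rng)
    assert decode(ind, 50) == decode(Individual(ind.hyper_features), 50)


# ---------------------------------------------------------------------------
# mutate


def test_mutation_is_unitary_neighbourhood_step(domains, rng):
    for _ in range(200):
        ind = random_individual(domains, rng)
        mutant = mutate(ind, domains, rng)
        assert hamming(ind, mutant) == 1
        for hf_old, hf_new in zip(ind.hyper_features, mutant.hyper_features):
            for gene in GENE_NAMES:
                old, new = hf_old.gene(gene), hf_new.gene(gene)
                if old != new:
                    assert new in domains.neighbours(gene, old)


def test_mutation_selects_hyper_features_uniformly(domains, rng):
    ind = random_individual(domains, rng)
    counts = Counter()
    n = 10_000
    for _ in range(n):
        mutant = mutate(ind, domains, rng)
        changed = [
            i for i, (a, b) in enumerate(zip(ind.hyper_features, mutant.hyper_features))
            if a != b
        ]
        counts[changed[0]] += 1
    for i in range(5):
        assert counts[i] == pytest.approx(n / 5, rel=0.15)


# ---------------------------------------------------------------------------
# recombine / shortest paths


def test_recombination_of_identical_parents_is_identity(domains, rng):
    ind = random_individual(domains, rng)
    child = recombine(ind, Individual(ind.hyper_features), domains, rng)
    assert Counter(child.hyper_features) == Counter(ind.hyper_features)


def test_recombination_stays_within_domains_and_on_shortest_paths(domains, rng):
    for _ in range(100):
        a, b = random_individual(domains, rng), random_individual(domains, rng)
        child = recombine(a, b, domains, rng)
        for hf in child.hyper_features:
            for gene in GENE_NAMES:
                assert hf.gene(gene) in domains.values[gene]


def test_ordinal_chain_offspring_lie_between_parents(domains, rng):
    # window_length chain 1-5-10-15-20: parents at the ends can produce any value
    a = random_individual(domains, rng)
    b = random_individual(domains, rng)
    a = Individual(tuple(h.with_gene("window_length", 1).with_gene("time_instant", 0)
                         for h in a.hyper_features))
    b = Individual(tuple(h.with_gene("window_length", 20).with_gene("time_instant", 0)
                         for h in b.hyper_features))
    seen = set()
    for _ in range(300):
        child = recombine(a, b, domains, rng)
        seen.update(h.window_length for h in child.hyper_features)
    assert seen == {1, 5, 10, 15, 20}


@pytest.mark.parametrize("gene", GENE_NAMES)
def test_shortest_path_nodes_match_bfs_oracle(domains, gene, rng):
    values = domains.values[gene]
    neighbours = {v: domains.neighbours(gene, v) for v in values}
    for _ in range(30):
        u = values[rng.integers(len(values))]
        v = values[rng.integers(len(values))]
        assert set(domains.shortest_path_nodes(gene, u, v)) == bfs_shortest_path_nodes(
            neighbours, u, v
        )


def test_shortest_path_choice_endpoints_and_uniformity(rng):
    domains = GeneDomains()
    # u = v returns u
    assert shortest_path_choice(domains, "operator", "mean", "mean", rng) == "mean"
    # chain mean-median-variance: endpoints mean/variance -> uniform over 3 nodes
    counts = Counter(
        shortest_path_choice(domains, "operator", "mean", "variance", rng)
        for _ in range(10_000)
    )
    for value in ("mean", "median", "variance"):
        assert counts[value] == pytest.approx(10_000 / 3, rel=0.12)


def test_reachability_every_gene_graph_is_connected(domains, rng):
    # closure + connectedness imply any genotype is reachable by finite mutations
    for gene, values in domains.values.items():
        start = values[0]
        seen = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nxt in domains.neighbours(gene, node):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        assert seen == set(values), gene


def test_individual_json_round_trip(domains, rng):
    ind = random_individual(domains, rng)
    assert Individual.from_json(ind.to_json()).key() == ind.key()


def test_individual_requires_five_hyper_features(domains, rng):
    ind = random_individual(domains, rng)
    with pytest.raises(ValueError):
        Individual(ind.hyper_features[:4])
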