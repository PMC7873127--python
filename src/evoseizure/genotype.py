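"""Hyper-feature genotype: gene domains, neighbourhoods, decoding, variation.

An individual is a set of exactly five *hyper-features*.  Each hyper-feature
is encoded by seven genes:

* ``dominant``       which of the two feature genes is expressed
                     (``band_wave`` or ``non_band_wave``);
* ``band_wave``      one of the 7 relative band powers;
* ``non_band_wave``  one of the 5 amplitude/spectral summary features;
* ``operator``       aggregation operator applied over the window;
* ``electrode``      10-20 scalp label the feature is read from;
* ``window_length``  aggregation window, minutes;
* ``time_instant``   placement, minutes *before* the minimum pre-ictal
                     boundary (0 = at the boundary).

Every gene carries a neighbourhood graph over its value set; mutation is a
unitary step to a neighbour, and recombination draws each offspring gene
uniformly from the nodes on the shortest paths between the two parent values.
Ordinal genes use a chain in natural order; the electrode gene uses the 10-20
scalp adjacency, so a mutation moves to a physically neighbouring electrode.

Decoding places the five hyper-features on a pre-seizure timeline: the total
pre-ictal duration is the configured minimum pre-ictal period plus the
largest ``time_instant``, and the seizure occurrence period (SOP) is that
total minus the 10-min seizure prediction horizon (SPH).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .features import BAND_NAMES, NON_BAND_FEATURES
from .montage import ELECTRODES_10_20, adjacency_graph

#: Seizure prediction horizon, minutes (fixed in training and testing).
SPH_MINUTES = 10

GENE_NAMES: tuple[str, ...] = (
    "dominant",
    "band_wave",
    "non_band_wave",
    "operator",
    "electrode",
    "window_length",
    "time_instant",
)

DOMINANT_VALUES: tuple[str, ...] = ("band_wave", "non_band_wave")
OPERATORS: tuple[str, ...] = ("mean", "median", "variance", "max", "min")
WINDOW_LENGTHS: tuple[int, ...] = (1, 5, 10, 15, 20)
TIME_INSTANTS: tuple[int, ...] = tuple(range(21))

#: Minimum pre-ictal periods explored, minutes.
MIN_PREICTAL_CHOICES: tuple[int, ...] = (40, 50, 60)


def _chain_graph(values: tuple) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(values)
    g.add_edges_from(zip(values[:-1], values[1:]))
    return g


@dataclass(frozen=True)
class HyperFeature:
    """One 7-gene hyper-feature (immutable, hashable)."""

    dominant: str
    band_wave: str
    non_band_wave: str
    operator: str
    electrode: str
    window_length: int
    time_instant: int

    def gene(self, name: str):
        return getattr(self, name)

    def with_gene(self, name: str, value) -> "HyperFeature":
        return replace(self, **{name: value})

    def to_dict(self) -> dict:
        return {name: self.gene(name) for name in GENE_NAMES}

    @classmethod
    def from_dict(cls, record: dict) -> "HyperFeature":
        return cls(**{name: record[name] for name in GENE_NAMES})


@dataclass
class Individual:
    """A set of exactly five hyper-features plus (optionally) a cached fitness."""

    hyper_features: tuple[HyperFeature, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.hyper_features = tuple(self.hyper_features)
        if len(self.hyper_features) != 5:
            raise ValueError("an individual carries exactly 5 hyper-features")

    def key(self) -> tuple:
        """Hashable genotype key (ignores cached fitness)."""
        return tuple(hf for hf in self.hyper_features)

    def to_json(self) -> str:
        return json.dumps([hf.to_dict() for hf in self.hyper_features])

    @classmethod
    def from_json(cls, text: str) -> "Individual":
        return cls(tuple(HyperFeature.from_dict(rec) for rec in json.loads(text)))


@dataclass(frozen=True)
class HyperFeatureRecipe:
    """Decoded (expressed) form of one hyper-feature."""

    feature: str
    electrode: str
    operator: str
    window_minutes: int
    offset_minutes: int


@dataclass(frozen=True)
class Phenotype:
    """Decoded individual: five time-series recipes on a pre-seizure timeline."""

    recipes: tuple[HyperFeatureRecipe, ...]
    pre_ictal_minutes: int
    sop_minutes: int
    sph_minutes: int = SPH_MINUTES


class GeneDomains:
    """Value sets and neighbourhood graphs for the seven genes.

    All domains are configurable; defaults cover the full 10-20 montage, five
    aggregation operators, window lengths of 1-20 min and time instants of
    0-20 min.  Shortest-path node unions are precomputed per gene for O(1)
    recombination draws.
    """

    def __init__(
        self,
        electrodes: tuple[str, ...] = ELECTRODES_10_20,
        operators: tuple[str, ...] = OPERATORS,
        window_lengths: tuple[int, ...] = WINDOW_LENGTHS,
        time_instants: tuple[int, ...] = TIME_INSTANTS,
        band_features: tuple[str, ...] = BAND_NAMES,
        non_band_features: tuple[str, ...] = NON_BAND_FEATURES,
        electrode_graph: nx.Graph | None = None,
    ) -> None:
        if electrode_graph is None:
            full = adjacency_graph()
            electrode_graph = full.subgraph(electrodes).copy() if set(electrodes) != set(
                full.nodes
            ) else full
        self.values: dict[str, tuple] = {
            "dominant": DOMINANT_VALUES,
            "band_wave": tuple(band_features),
            "non_band_wave": tuple(non_band_features),
            "operator": tuple(operators),
            "electrode": tuple(electrodes),
            "window_length": tuple(window_lengths),
            "time_instant": tuple(time_instants),
        }
        for gene, vals in self.values.items():
            if not vals:
                raise ValueError(f"empty domain for gene '{gene}'")
        self.graphs: dict[str, nx.Graph] = {
            gene: _chain_graph(vals) for gene, vals in self.values.items()
        }
        self.graphs["electrode"] = electrode_graph
        for gene, g in self.graphs.items():
            missing = set(self.values[gene]) - set(g.nodes)
            if missing:
                raise ValueError(f"gene '{gene}': values {missing} absent from graph")
            if not nx.is_connected(g.subgraph(self.values[gene])):
                raise ValueError(f"gene '{gene}': neighbourhood graph is not connected")
        self._neighbours: dict[str, dict] = {
            gene: {v: tuple(sorted(g.neighbors(v), key=self.values[gene].index))
                   for v in self.values[gene]}
            for gene, g in self.graphs.items()
        }
        self._sp_nodes: dict[str, dict] = {gene: {} for gene in GENE_NAMES}

    def neighbours(self, gene: str, value) -> tuple:
        return self._neighbours[gene][value]

    def shortest_path_nodes(self, gene: str, u, v) -> tuple:
        """Union of nodes on all shortest u-v paths (endpoints included), cached."""
        cache = self._sp_nodes[gene]
        key = (u, v)
        if key not in cache:
            nodes: set = set()
            for path in nx.all_shortest_paths(self.graphs[gene], u, v):
                nodes.update(path)
            ordered = tuple(sorted(nodes, key=self.values[gene].index))
            cache[key] = ordered
            cache[(v, u)] = ordered
        return cache[key]


def shortest_path_choice(domains: GeneDomains, gene: str, u, v, rng: np.random.Generator):
    """Uniform draw over the union of nodes of all shortest u-v paths."""
    nodes = domains.shortest_path_nodes(gene, u, v)
    return nodes[rng.integers(len(nodes))]


def random_hyper_feature(domains: GeneDomains, rng: np.random.Generator) -> HyperFeature:
    draw = {gene: vals[rng.integers(len(vals))] for gene, vals in domains.values.items()}
    return HyperFeature(**draw)


def random_individual(domains: GeneDomains, rng: np.random.Generator) -> Individual:
    """Every gene drawn uniformly from its domain; fitness unset."""
    return Individual(tuple(random_hyper_feature(domains, rng) for _ in range(5)))


def decode(ind: Individual, min_preictal: int) -> Phenotype:
    """Genotype -> phenotype mapping.

    The dominant gene selects the expressed feature; the pre-ictal duration is
    ``min_preictal`` plus the largest time instant, and SOP is the pre-ictal
    duration minus the 10-min SPH.
    """
    recipes = []
    for hf in ind.hyper_features:
        feature = hf.band_wave if hf.dominant == "band_wave" else hf.non_band_wave
        if hf.dominant == "band_wave":
            feature = f"rp_{feature}"
        recipes.append(
            HyperFeatureRecipe(
                feature=feature,
                electrode=hf.electrode,
                operator=hf.operator,
                window_minutes=hf.window_length,
                offset_minutes=hf.time_instant,
            )
        )
    pre_ictal = min_preictal + max(hf.time_instant for hf in ind.hyper_features)
    return Phenotype(
        recipes=tuple(recipes),
        pre_ictal_minutes=pre_ictal,
        sop_minutes=pre_ictal - SPH_MINUTES,
    )


def mutate(ind: Individual, domains: GeneDomains, rng: np.random.Generator) -> Individual:
    """Unitary mutation: one random gene of one random hyper-feature steps to a neighbour."""
    hf_idx = int(rng.integers(5))
    gene = GENE_NAMES[rng.integers(len(GENE_NAMES))]
    old = ind.hyper_features[hf_idx].gene(gene)
    options = domains.neighbours(gene, old)
    new = options[rng.integers(len(options))]
    hfs = list(ind.hyper_features)
    hfs[hf_idx] = hfs[hf_idx].with_gene(gene, new)
    return Individual(tuple(hfs))


def _pairing_order(ind: Individual, domains: GeneDomains) -> list[HyperFeature]:
    """Sort hyper-features by time instant (ties by electrode order, then stable)."""
    order = domains.values["electrode"].index
    return sorted(ind.hyper_features, key=lambda hf: (hf.time_instant, order(hf.electrode)))


def recombine(
    parent_a: Individual,
    parent_b: Individual,
    domains: GeneDomains,
    rng: np.random.Generator,
) -> Individual:
    """Shortest-path recombination of rank-paired hyper-features.

    Hyper-features are first paired by their temporal rank (sorted by time
    instant), preserving each parent's temporal sequence structure; then every
    offspring gene is drawn uniformly from the nodes on the shortest paths
    between the two parent gene values.
    """
    offspring = []
    for hf_a, hf_b in zip(_pairing_order(parent_a, domains), _pairing_order(parent_b, domains)):
        genes = {
            name: shortest_path_choice(domains, name, hf_a.gene(name), hf_b.gene(name), rng)
            for name in GENE_NAMES
        }
        offspring.append(HyperFeature(**genes))
    return Individual(tuple(offspring))


def save_individuals(individuals: list[Individual], path: str | Path) -> None:
    records = [
        {"hyper_features": [hf.to_dict() for hf in ind.hyper_features], "fitness": ind.fitness}
        for ind in individuals
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def load_individuals(path: str | Path) -> list[Individual]:
    records = json.loads(Path(path).read_text())
    return [
        Individual(
            tuple(HyperFeature.from_dict(r) for r in rec["hyper_features"]),
            fitness=rec["fitness"],
        )
        for rec in records
    ]
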