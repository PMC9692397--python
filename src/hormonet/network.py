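"""Pathway-union interaction network analysis.

Pathways (gene sets with intra-pathway interaction edges) that contain at
least one differentially expressed gene are merged into a single undirected,
unweighted network.  Nodes are annotated as crosstalk-regulated DE genes,
other DE genes, or non-DE genes.  On this network the module finds hubs
(degree >= 20 by default), extracts "chains" (connected components of the
subgraph induced on selected DE genes), computes first/second BFS
neighborhoods of seed genes, and tests neighborhood enrichment of an
annotation class by label permutation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ANNOTATIONS",
    "DEFAULT_HUB_THRESHOLD",
    "PathwayCollection",
    "InteractionNetwork",
    "ChainSet",
    "Neighborhood",
    "PermutationTestResult",
    "merge_pathways",
    "find_hubs",
    "hub_percentage",
    "extract_chains",
    "neighborhood",
    "permutation_enrichment",
]

ANNOTATIONS = ("crosstalk_DE", "other_DE", "non_DE")

DEFAULT_HUB_THRESHOLD = 20

#: Assignment counts up to which the permutation null is enumerated
#: exhaustively instead of sampled.
EXHAUSTIVE_LIMIT = 10_000


def _norm(gene: str) -> str:
    # Identifiers are matched case-insensitively (inputs are pre-mapped
    # orthologs whose capitalization varies between sources).
    return str(gene).upper()


@dataclass
class PathwayCollection:
    """Named gene sets with undirected intra-pathway edges.

    ``pathways`` maps pathway name -> (member set, edge set); edges are
    2-element frozensets over members.  Self-loops are dropped and edge
    endpoints must be members.
    """

    pathways: dict[str, tuple[frozenset[str], frozenset[frozenset[str]]]]

    @classmethod
    def from_dict(
        cls,
        members: Mapping[str, Iterable[str]],
        edges: Mapping[str, Iterable[tuple[str, str]]] | None = None,
    ) -> "PathwayCollection":
        edges = edges or {}
        pathways = {}
        for name, genes in members.items():
            gene_set = frozenset(_norm(g) for g in genes)
            edge_set = set()
            for a, b in edges.get(name, ()):
                a, b = _norm(a), _norm(b)
                if a == b:
                    continue  # self-loop
                if a not in gene_set or b not in gene_set:
                    raise ValueError(
                        f"edge ({a}, {b}) of pathway {name!r} has an "
                        "endpoint outside the member set"
                    )
                edge_set.add(frozenset((a, b)))
            pathways[name] = (gene_set, frozenset(edge_set))
        return cls(pathways=pathways)

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    def members(self, name: str) -> frozenset[str]:
        return self.pathways[name][0]

    def edges(self, name: str) -> frozenset[frozenset[str]]:
        return self.pathways[name][1]


@dataclass
class InteractionNetwork:
    """Merged pathway-union graph with per-node annotations."""

    graph: nx.Graph = field(repr=False)
    n_pathways_included: int = 0
    n_pathways_total: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def annotation(self, gene: str) -> str:
        return self.graph.nodes[gene]["annotation"]

    def nodes_with(self, annotation: str) -> set[str]:
        return {
            n for n, a in self.graph.nodes(data="annotation") if a == annotation
        }

    @property
    def de_nodes(self) -> set[str]:
        return self.nodes_with("crosstalk_DE") | self.nodes_with("other_DE")

    def degree_of(self, gene: str) -> int:
        return self.graph.degree[gene]

    def summary(self) -> dict:
        comp_sizes = sorted(
            (len(c) for c in nx.connected_components(self.graph)), reverse=True
        )
        counts = {a: len(self.nodes_with(a)) for a in ANNOTATIONS}
        giant = max(nx.connected_components(self.graph), key=len) if comp_sizes else set()
        de_in_giant = sum(
            1 for n in giant
            if self.graph.nodes[n]["annotation"] in ("crosstalk_DE", "other_DE")
        )
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_pathways_included": self.n_pathways_included,
            "n_pathways_total": self.n_pathways_total,
            "annotation_counts": counts,
            "n_components": len(comp_sizes),
            "largest_component_size": comp_sizes[0] if comp_sizes else 0,
            "de_genes_in_largest_component": de_in_giant,
        }


def merge_pathways(
    collection: PathwayCollection,
    de_genes: Iterable[str],
    crosstalk_genes: Iterable[str] = (),
) -> InteractionNetwork:
    """Union of all pathways containing at least one DE gene.

    Duplicate edges collapse; pathways with no DE member contribute
    nothing.  Nodes are annotated crosstalk_DE / other_DE / non_DE from the
    two gene sets (crosstalk genes should be a subset of DE genes).
    """
    de = {_norm(g) for g in de_genes}
    crosstalk = {_norm(g) for g in crosstalk_genes}
    graph = nx.Graph()
    included = 0
    for name in collection.names:
        members = collection.members(name)
        if not members & de:
            continue
        included += 1
        graph.add_nodes_from(members)
        graph.add_edges_from(tuple(sorted(e)) for e in collection.edges(name))
    for node in graph.nodes:
        if node in crosstalk:
            annotation = "crosstalk_DE"
        elif node in de:
            annotation = "other_DE"
        else:
            annotation = "non_DE"
        graph.nodes[node]["annotation"] = annotation
    return InteractionNetwork(
        graph=graph,
        n_pathways_included=included,
        n_pathways_total=len(collection.names),
    )


def find_hubs(
    network: InteractionNetwork, hub_threshold: int = DEFAULT_HUB_THRESHOLD
) -> set[str]:
    """Nodes with degree >= hub_threshold."""
    return {n for n, d in network.graph.degree() if d >= hub_threshold}


def hub_percentage(n_hubs: int, n_nodes: int) -> float:
    """Hubs as a percentage of network nodes."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return 100.0 * n_hubs / n_nodes


@dataclass
class ChainSet:
    """Connected components (size >= 2) of the induced DE subgraph."""

    chains: list[list[str]]
    gene_set_mode: str

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.chains]


def extract_chains(
    network: InteractionNetwork, gene_set_mode: str = "crosstalk_only"
) -> ChainSet:
    """Chains: groups of selected DE genes that are functionally connected.

    ``gene_set_mode`` selects the genes kept before taking components:
    "crosstalk_only" keeps crosstalk-regulated DE genes, "all_de" keeps
    every DE gene.  Isolated nodes are dropped; components are sorted by
    size (descending), ties broken by their lexicographically smallest
    member.
    """
    if gene_set_mode == "crosstalk_only":
        keep = network.nodes_with("crosstalk_DE")
    elif gene_set_mode == "all_de":
        keep = network.de_nodes
    else:
        raise ValueError(
            "gene_set_mode must be 'crosstalk_only' or 'all_de', "
            f"got {gene_set_mode!r}"
        )
    sub = network.graph.subgraph(keep)
    components = [
        sorted(c) for c in nx.connected_components(sub) if len(c) >= 2
    ]
    components.sort(key=lambda c: (-len(c), c[0]))
    return ChainSet(chains=components, gene_set_mode=gene_set_mode)


@dataclass
class Neighborhood:
    """First and second BFS rings around a seed gene set."""

    seeds: set[str]
    first_neighbors: set[str]
    second_neighbors: set[str]
    #: annotation -> count, per ring
    first_counts: dict[str, int]
    second_counts: dict[str, int]
    #: first neighbors adjacent to more than one seed
    common_first: set[str]


def neighborhood(network: InteractionNetwork, seeds: Iterable[str]) -> Neighborhood:
    """Nodes at shortest-path distance exactly 1 and 2 from the seed set."""
    seed_set = {_norm(s) for s in seeds}
    missing = sorted(s for s in seed_set if s not in network.graph)
    if missing:
        raise KeyError(f"seed genes not in network: {missing}")
    first: set[str] = set()
    for s in seed_set:
        first.update(network.graph.neighbors(s))
    first -= seed_set
    second: set[str] = set()
    for n in first:
        second.update(network.graph.neighbors(n))
    second -= seed_set | first
    common = {
        n for n in first
        if sum(1 for s in seed_set if network.graph.has_edge(s, n)) >= 2
    }

    def ring_counts(ring: set[str]) -> dict[str, int]:
        counts = {a: 0 for a in ANNOTATIONS}
        for n in ring:
            counts[network.annotation(n)] += 1
        return counts

    return Neighborhood(
        seeds=seed_set,
        first_neighbors=first,
        second_neighbors=second,
        first_counts=ring_counts(first),
        second_counts=ring_counts(second),
        common_first=common,
    )


@dataclass
class PermutationTestResult:
    """Enrichment of an annotation class in a seed neighborhood."""

    observed: int
    null_mean: float
    null_sd: float
    z_score: float  #: NaN when the null SD is zero (flagged degenerate)
    empirical_p: float
    n_permutations: int
    seed: int | None
    label: str
    exhaustive: bool = False
    degenerate: bool = False


def permutation_enrichment(
    network: InteractionNetwork,
    seeds: Iterable[str],
    label: str = "crosstalk_DE",
    n_permutations: int = 10_000,
    seed: int | None = 0,
    exhaustive: bool | None = None,
    null_model: str = "label_permutation",
) -> PermutationTestResult:
    """Permutation test for enrichment of ``label`` nodes near the seeds.

    The statistic is the number of labeled nodes among the first and second
    neighbors (jointly) of the seed set.  Under the default null the
    labeled set (same cardinality) is re-assigned uniformly over all
    non-seed nodes.  ``exhaustive=True`` (or automatically when the number
    of possible assignments is small) enumerates every assignment, making
    the null moments and p-value exact.  ``null_model="degree_rewire"``
    instead rewires the graph degree-preservingly each round and keeps the
    labels fixed; it is much slower and intended for sensitivity checks.

    The empirical p-value is (1 + #{null >= observed}) / (1 + B) for
    sampled nulls and #{null >= observed} / B for exhaustive enumeration.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    if label not in ANNOTATIONS:
        raise ValueError(f"unknown annotation {label!r}")
    nbhd = neighborhood(network, seeds)
    ring = nbhd.first_neighbors | nbhd.second_neighbors
    labeled = network.nodes_with(label)
    observed = len(ring & labeled)
    non_seed = sorted(set(network.graph.nodes) - nbhd.seeds)
    k = len(labeled - nbhd.seeds)

    if k == 0:
        return PermutationTestResult(
            observed=observed, null_mean=0.0, null_sd=0.0,
            z_score=float("nan"), empirical_p=1.0,
            n_permutations=0, seed=seed, label=label, degenerate=True,
        )

    if null_model == "label_permutation":
        # The statistic depends only on how many of the k labels land in
        # the ring, but nulls are realized as explicit node assignments.
        ring_non_seed = sorted(ring - nbhd.seeds)
        n_assign = math.comb(len(non_seed), k)
        do_exhaustive = exhaustive if exhaustive is not None else (
            n_assign <= EXHAUSTIVE_LIMIT
        )
        if do_exhaustive:
            ring_set = set(ring_non_seed)
            null = np.fromiter(
                (
                    sum(1 for g in combo if g in ring_set)
                    for combo in itertools.combinations(non_seed, k)
                ),
                dtype=float,
                count=n_assign,
            )
            n_used = n_assign
            p = float(np.sum(null >= observed)) / n_used
        else:
            rng = np.random.default_rng(seed)
            arr = np.array(non_seed)
            in_ring = np.isin(arr, np.array(ring_non_seed, dtype=arr.dtype))
            null = np.empty(n_permutations)
            for b in range(n_permutations):
                pick = rng.choice(len(arr), size=k, replace=False)
                null[b] = in_ring[pick].sum()
            n_used = n_permutations
            p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_used)
            do_exhaustive = False
    elif null_model == "degree_rewire":
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        n_swap = max(1, 2 * network.n_edges)
        for b in range(n_permutations):
            g = network.graph.copy()
            nx.double_edge_swap(
                g, nswap=n_swap, max_tries=20 * n_swap,
                seed=int(rng.integers(2**31 - 1)),
            )
            rewired = InteractionNetwork(graph=g)
            nb = neighborhood(rewired, nbhd.seeds)
            null[b] = len((nb.first_neighbors | nb.second_neighbors) & labeled)
        n_used = n_permutations
        p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_used)
        do_exhaustive = False
    else:
        raise ValueError(f"unknown null_model {null_model!r}")

    null_mean = float(null.mean())
    null_sd = float(null.std())
    degenerate = null_sd == 0.0
    z = (observed - null_mean) / null_sd if not degenerate else float("nan")
    return PermutationTestResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        empirical_p=p,
        n_permutations=n_used,
        seed=seed,
        label=label,
        exhaustive=bool(do_exhaustive),
        degenerate=degenerate,
    )
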