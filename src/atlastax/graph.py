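"""Phase 2: cluster reference sequences that are confused with one another.

Reference sequences that co-occur in query outlier sets are joined in a
weighted, undirected confusion graph (edge weight = number of queries whose
outlier set contains both endpoints). Low-weight edges — below the mean
minus two population standard deviations of all edge weights — are pruned
once, and Louvain modularity optimisation over the remaining graph yields
the sample-specific database partitions. Isolated nodes become singleton
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from atlastax.outliers import OutlierSet


@dataclass(frozen=True)
class PartitionSet:
    """A disjoint partition of the confusion-graph nodes.

    Partition ids are consecutive integers from 0, ordered by each
    partition's smallest member reference id, which makes the labelling
    deterministic given the communities.
    """

    partitions: tuple[frozenset[str], ...]

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[str]]) -> "PartitionSet":
        comms = [frozenset(c) for c in communities if c]
        comms.sort(key=lambda c: min(c))
        return cls(tuple(comms))

    def __len__(self) -> int:
        return len(self.partitions)

    def __getitem__(self, pid: int) -> frozenset[str]:
        return self.partitions[pid]

    def __iter__(self):
        return iter(self.partitions)

    @property
    def membership(self) -> dict[str, int]:
        """Map reference id -> partition id."""
        return {ref: pid for pid, comm in enumerate(self.partitions) for ref in comm}

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.partitions if len(c) == 1)


def build_confusion_graph(outlier_sets: Iterable[OutlierSet]) -> nx.Graph:
    """Count co-occurrences of references across outlier sets.

    Every size-m outlier set increments all C(m, 2) pairwise edge weights
    by one; size-1 sets contribute their node only. References never seen
    in any outlier set do not appear in the graph.
    """
    g = nx.Graph()
    for oset in outlier_sets:
        members = sorted(set(oset.members))
        g.add_nodes_from(members)
        for u, v in combinations(members, 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    return g


def edge_weight_threshold(graph: nx.Graph, sd_multiplier: float = 2.0) -> float:
    """The pruning threshold tau = mean(w) - sd_multiplier * sd(w).

    The standard deviation is the population one: the observed edges are
    the whole population of interest, not a sample from it.
    """
    weights = np.array([d["weight"] for _, _, d in graph.edges(data=True)], dtype=float)
    if weights.size == 0:
        return float("-inf")
    return float(weights.mean() - sd_multiplier * weights.std(ddof=0))


def filter_edges(graph: nx.Graph, sd_multiplier: float = 2.0) -> nx.Graph:
    """Remove edges strictly below the mean - 2*sd weight threshold.

    Single pass: the threshold is computed once on the unfiltered edge
    multiset. Nodes are never removed — isolated survivors later become
    singleton partitions. Returns a new graph.
    """
    out = graph.copy()
    if graph.number_of_edges() == 0:
        return out
    tau = edge_weight_threshold(graph, sd_multiplier)
    drop = [(u, v) for u, v, d in out.edges(data=True) if d["weight"] < tau]
    out.remove_edges_from(drop)
    return out


def louvain_partition(
    graph: nx.Graph, seed: int = 42, resolution: float = 1.0
) -> PartitionSet:
    """Louvain community detection on the (filtered) confusion graph.

    Nodes are fed to Louvain in sorted order before any seeded shuffling,
    so identical inputs and seed give identical partitions across
    platforms. Isolated nodes emerge as singleton partitions.
    """
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes()))
    ordered.add_weighted_edges_from(
        (u, v, d["weight"]) for u, v, d in sorted(graph.edges(data=True))
    )
    if ordered.number_of_nodes() == 0:
        return PartitionSet(())
    communities = nx.community.louvain_communities(
        ordered, weight="weight", resolution=resolution, seed=seed
    )
    return PartitionSet.from_communities(communities)


def modularity(graph: nx.Graph, partition: Iterable[Iterable[str]] | PartitionSet) -> float:
    """Weighted Newman modularity Q of a node partition.

    Q = sum_c [ w_in_c / m  -  (deg_c / (2 m))^2 ]

    with m the total edge weight, w_in_c the intra-community edge weight
    and deg_c the summed weighted degree of community c. Every graph node
    must be covered exactly once; an edgeless graph has Q = 0.
    """
    comms = [set(c) for c in partition]
    covered: set[str] = set()
    for c in comms:
        if covered & c:
            raise ValueError("partition communities overlap")
        covered |= c
    nodes = set(graph.nodes())
    if covered != nodes:
        missing = nodes - covered
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    m = graph.size(weight="weight")
    if m == 0:
        return 0.0
    degree = dict(graph.degree(weight="weight"))
    q = 0.0
    for c in comms:
        w_in = sum(
            d["weight"]
            for u, v, d in graph.edges(c, data=True)
            if u in c and v in c
        )
        deg_c = sum(degree[n] for n in c)
        q += w_in / m - (deg_c / (2.0 * m)) ** 2
    return q
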