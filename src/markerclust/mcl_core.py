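"""Markov clustering (MCL) of weighted undirected graphs.

Used twice by the detection pipeline: once on the marker graph (markers as
nodes, counts of shared alignments as edge weights) and once on the taxon
graph (counts of multiply aligned reads).  The implementation is the standard
flow simulation: add self-loops, column-normalize, then alternate expansion
(matrix power) and inflation (entrywise power + renormalization) until the
matrix stops changing, and read clusters off the attractor rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["WeightedGraph", "Clustering", "mcl"]

Node = Hashable


class WeightedGraph:
    """Undirected graph with positive edge weights.

    Edges are stored symmetrically; adding (u, v) also adds (v, u).
    """

    def __init__(self) -> None:
        self._adj: dict[Node, dict[Node, float]] = {}

    @classmethod
    def from_edges(
        cls,
        edges: Mapping[tuple[Node, Node], float] | Iterable[tuple[Node, Node, float]],
        nodes: Iterable[Node] = (),
    ) -> "WeightedGraph":
        g = cls()
        for node in nodes:
            g.add_node(node)
        items = edges.items() if isinstance(edges, Mapping) else ((e[:2], e[2]) for e in edges)
        for (u, v), w in items:
            g.add_edge(u, v, w)
        return g

    def add_node(self, node: Node) -> None:
        self._adj.setdefault(node, {})

    def add_edge(self, u: Node, v: Node, weight: float) -> None:
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight} for ({u}, {v})")
        if u == v:
            raise ValueError(f"self-loop on {u!r}; self-loops are added internally by mcl")
        existing = self._adj.get(u, {}).get(v)
        if existing is not None and existing != weight:
            raise ValueError(
                f"conflicting weights for edge ({u}, {v}): {existing} vs {weight}"
            )
        self.add_node(u)
        self.add_node(v)
        self._adj[u][v] = weight
        self._adj[v][u] = weight

    @property
    def nodes(self) -> list[Node]:
        return list(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    def weight(self, u: Node, v: Node) -> float | None:
        return self._adj.get(u, {}).get(v)

    def edges(self) -> list[tuple[Node, Node, float]]:
        out = []
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                if str(u) <= str(v):
                    out.append((u, v, w))
        return out

    def adjacency_matrix(self) -> tuple[np.ndarray, list[Node]]:
        """Dense symmetric adjacency over nodes in sorted order."""
        order = sorted(self._adj, key=str)
        index = {n: i for i, n in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                a[index[u], index[v]] = w
        return a, order


@dataclass
class Clustering:
    """A partition of graph nodes into non-empty clusters."""

    clusters: list[set[Node]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[Node] = set()
        for cluster in self.clusters:
            if not cluster:
                raise ValueError("clusters must be non-empty")
            if cluster & seen:
                raise ValueError(f"clusters overlap on {cluster & seen!r}")
            seen |= cluster
        self._membership = {n: i for i, c in enumerate(self.clusters) for n in c}

    @property
    def nodes(self) -> set[Node]:
        return set(self._membership)

    def cluster_of(self, node: Node) -> set[Node]:
        return self.clusters[self._membership[node]]

    def cluster_index(self, node: Node) -> int:
        return self._membership[node]

    def same_cluster(self, u: Node, v: Node) -> bool:
        return self._membership[u] == self._membership[v]

    def as_sets(self) -> set[frozenset]:
        return {frozenset(c) for c in self.clusters}

    def __len__(self) -> int:
        return len(self.clusters)


def _column_normalize(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl(
    graph: WeightedGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    self_loop_weight: float = 1.0,
    pruning_threshold: float = 1e-9,
) -> Clustering:
    """Cluster a weighted undirected graph with the Markov Cluster algorithm.

    Overlapping attractor systems are resolved deterministically: a node
    claimed by several clusters goes to the one with the largest attractor
    value, ties broken toward the cluster with the smallest representative.
    Non-convergence within ``max_iterations`` logs a warning and returns the
    current partition.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    if graph.n_nodes == 0:
        return Clustering([])

    a, order = graph.adjacency_matrix()
    if not np.allclose(a, a.T):
        raise ValueError("adjacency matrix is not symmetric")
    np.fill_diagonal(a, np.diag(a) + self_loop_weight)
    m = _column_normalize(a)

    converged = False
    for _ in range(max_iterations):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = _column_normalize(expanded**inflation)
        inflated[inflated < pruning_threshold] = 0.0
        inflated = _column_normalize(inflated)
        if np.abs(inflated - m).max() < tolerance:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        logger.warning(
            "MCL did not converge in %d iterations; returning current partition",
            max_iterations,
        )

    return _clusters_from_matrix(m, order)


def _clusters_from_matrix(
    m: np.ndarray, order: list[Node], eps: float = 1e-6
) -> Clustering:
    n = len(order)
    attractors = [i for i in range(n) if m[i, i] > eps]

    # Group attractor rows that flow into each other (shared members).
    parent = list(range(len(attractors)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members = [set(np.flatnonzero(m[a] > eps)) | {a} for a in attractors]
    for i in range(len(attractors)):
        for j in range(i + 1, len(attractors)):
            if members[i] & members[j]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(attractors)):
        groups.setdefault(find(i), []).append(i)

    raw_clusters: list[tuple[set[int], list[int]]] = []  # (member cols, attractor rows)
    for idxs in groups.values():
        cols: set[int] = set()
        rows = [attractors[i] for i in idxs]
        for i in idxs:
            cols |= members[i]
        raw_clusters.append((cols, rows))

    # Resolve multi-membership: best attractor value wins, ties to the
    # cluster with the smallest representative node.
    assignment: dict[int, int] = {}
    reps = [min(str(order[c]) for c in cols) for cols, _ in raw_clusters]
    for col in range(n):
        candidates = [
            (max(m[r, col] for r in rows), ci)
            for ci, (cols, rows) in enumerate(raw_clusters)
            if col in cols
        ]
        if not candidates:
            continue
        best_val = max(v for v, _ in candidates)
        best = min((ci for v, ci in candidates if v == best_val), key=lambda ci: reps[ci])
        assignment[col] = best

    final: dict[int, set[Node]] = {}
    for col, ci in assignment.items():
        final.setdefault(ci, set()).add(order[col])
    clusters = list(final.values())
    # Numerically orphaned nodes become singletons.
    for col in range(n):
        if col not in assignment:
            clusters.append({order[col]})
    clusters.sort(key=lambda c: min(str(node) for node in c))
    return Clustering(clusters)
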