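"""Spanning-tree container and reference tree topologies.

A spanning tree on ``n`` nodes is the acyclic connected graph with exactly
``m = n - 1`` edges.  Two reference topologies anchor the analysis: the
*star* (one hub adjacent to every other node, the most centralized tree)
and the *path* (a single chain, the most decentralized tree).  Random
labeled trees are drawn uniformly via random Pruefer sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpanningTree", "make_tree"]


@dataclass(frozen=True)
class SpanningTree:
    """An undirected labeled tree on nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes
        Number of nodes; must be at least 2.
    edges
        Tuple of ``(i, j)`` pairs with ``i < j``; exactly ``n_nodes - 1``
        of them, forming a connected acyclic graph.
    weights
        Optional per-edge weights (e.g. the connection strengths the tree
        was built from), aligned with ``edges``.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    weights: tuple[float, ...] | None = field(default=None, compare=False)

    def __post_init__(self):
        n = self.n_nodes
        if n < 2:
            raise ValueError(f"a spanning tree needs at least 2 nodes, got {n}")
        edges = tuple(tuple(sorted(map(int, e))) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) != n - 1:
            raise ValueError(f"expected {n - 1} edges for {n} nodes, got {len(edges)}")
        if self.weights is not None and len(self.weights) != len(edges):
            raise ValueError("weights must align with edges")
        seen = set()
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for {n} nodes")
            if i == j or (i, j) in seen:
                raise ValueError(f"invalid or duplicate edge ({i}, {j})")
            seen.add((i, j))
            a, b = find(i), find(j)
            if a == b:
                raise ValueError(f"edge ({i}, {j}) closes a cycle")
            parent[a] = b
        # n-1 cycle-free edges on n nodes imply connectivity.

    @property
    def m(self) -> int:
        """Number of edges, ``n_nodes - 1``."""
        return self.n_nodes - 1

    def degrees(self) -> np.ndarray:
        """Degree of every node."""
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency_lists(self) -> list[list[int]]:
        """Neighbor lists, sorted, one per node."""
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        for neigh in adj:
            neigh.sort()
        return adj

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.edges)


def _prufer_decode(seq: np.ndarray, n: int) -> list[tuple[int, int]]:
    """Decode a Pruefer sequence into the edge list of the labeled tree."""
    import heapq

    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(x)))
        degree[leaf] -= 1
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, int(x))
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    return edges


def make_tree(topology: str, n_nodes: int, seed: int | None = None) -> SpanningTree:
    """Build a reference tree: ``star``, ``path`` or uniform ``random``.

    The star places node 0 at the hub; the path chains nodes in index
    order.  ``random`` draws a uniform labeled tree by decoding a random
    Pruefer sequence (all ``n**(n-2)`` labeled trees equally likely).
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if topology == "star":
        edges = [(0, i) for i in range(1, n_nodes)]
    elif topology == "path":
        edges = [(i, i + 1) for i in range(n_nodes - 1)]
    elif topology == "random":
        if n_nodes == 2:
            edges = [(0, 1)]
        else:
            rng = np.random.default_rng(seed)
            seq = rng.integers(0, n_nodes, size=n_nodes - 2)
            edges = _prufer_decode(seq, n_nodes)
    else:
        raise ValueError(f"unknown topology {topology!r}; use star, path or random")
    return SpanningTree(n_nodes=n_nodes, edges=tuple(edges))
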