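"""Maximum-strength spanning tree construction and tree topology metrics.

The spanning tree of a functional-connectivity matrix is built on maximum
connection strength: Kruskal's algorithm scans edges in descending weight
order, keeping each edge unless it would close a cycle, until all n nodes
are connected by n - 1 edges.  On the strength (similarity) matrix this
maximum spanning tree plays the role the minimum spanning tree plays on a
distance matrix, and it is unique whenever the weights are distinct.

Tree metrics use hop distances (every tree edge counts 1) and the
normalizations that anchor the two reference topologies:

* ``diameter_norm``  — longest shortest path in hops / m; 1 on a path,
  2/m on a star (m = n - 1).
* ``leaf_fraction``  — number of degree-1 nodes / m; 1 on a star, 2/m on
  a path.
* ``kappa``          — degree divergence sum(k^2)/sum(k); maximal for the
  star, minimal for the path at fixed n.
* ``betweenness``    — fraction of node pairs whose unique tree path
  crosses a node, normalized by (n-1)(n-2)/2 so a leaf scores exactly 0
  and a star hub exactly 1.
* ``tree hierarchy`` — TH = leaf / (2 m BC_max), the balance between
  integration and hub overload; with the leaf *count* in the numerator a
  star scores 0.5 and a long path approaches 0.  Both the count and the
  leaf-fraction variant are computed (see ``tree_hierarchy``).
* ``eccentricity``   — per-node largest hop distance to any other node,
  unnormalized.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .connectivity import FcMatrix
from .errors import DisconnectedGraphError
from .trees import SpanningTree

__all__ = [
    "MstMetrics",
    "max_spanning_tree",
    "tree_diameter",
    "leaf_stats",
    "kappa",
    "betweenness",
    "tree_hierarchy",
    "eccentricity",
    "mst_metrics",
]


@dataclass(frozen=True)
class MstMetrics:
    """Per-subject tree metric record."""

    n_nodes: int
    m: int
    diameter_norm: float
    leaf_count: int
    leaf_fraction: float
    kappa: float
    bc: tuple[float, ...]
    bc_max: float
    th_count: float
    th_fraction: float
    ecc: tuple[int, ...]
    ecc_mean: float


def max_spanning_tree(fc) -> SpanningTree:
    """Kruskal maximum-strength spanning tree of a connectivity matrix.

    Edges are scanned by (weight descending, smaller node index, smaller
    partner index), making ties deterministic.  Zero-weight entries are
    absent edges; if they disconnect the graph, a
    :class:`DisconnectedGraphError` is raised.
    """
    w = fc.z if isinstance(fc, FcMatrix) else np.asarray(fc, dtype=float)
    n = w.shape[0]
    candidates = [
        (float(w[i, j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if w[i, j] > 0
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges, weights = [], []
    for wt, i, j in candidates:
        a, b = find(i), find(j)
        if a != b:
            parent[a] = b
            edges.append((i, j))
            weights.append(wt)
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        roots = {}
        for v in range(n):
            roots.setdefault(find(v), []).append(v)
        comps = list(roots.values())
        raise DisconnectedGraphError(
            f"graph is disconnected ({len(comps)} components): {comps}",
            components=comps,
        )
    return SpanningTree(n_nodes=n, edges=tuple(edges), weights=tuple(weights))


def _hop_distances_from(tree: SpanningTree, source: int, adj=None) -> np.ndarray:
    adj = adj if adj is not None else tree.adjacency_lists()
    dist = np.full(tree.n_nodes, -1, dtype=int)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_hop_distances(tree: SpanningTree) -> np.ndarray:
    adj = tree.adjacency_lists()
    return np.stack([_hop_distances_from(tree, s, adj) for s in range(tree.n_nodes)])


def tree_diameter(tree: SpanningTree) -> float:
    """Normalized diameter: longest shortest hop path divided by m = n - 1."""
    d = _all_hop_distances(tree)
    return float(d.max()) / tree.m


def leaf_stats(tree: SpanningTree) -> tuple[int, float]:
    """Leaf count (degree-1 nodes) and leaf fraction (count / m)."""
    deg = tree.degrees()
    leaf_count = int((deg == 1).sum())
    return leaf_count, leaf_count / tree.m


def kappa(tree: SpanningTree) -> float:
    """Degree divergence sum(k^2) / sum(k); broad (hubby) degree sequences score high."""
    deg = tree.degrees()
    return float((deg**2).sum() / deg.sum())


def betweenness(tree: SpanningTree) -> tuple[np.ndarray, float]:
    """Pair-normalized betweenness centrality of every node, and its maximum.

    ``bc_v`` counts the unordered pairs {s, t} (both different from v)
    whose unique tree path passes through v, divided by (n-1)(n-2)/2.
    Removing v splits the tree into components of sizes c_1..c_k; the pairs
    through v are exactly those straddling two different components, so
    ``bc_v = (sum_{a<b} c_a c_b) / ((n-1)(n-2)/2)``.  A leaf scores 0 and
    the hub of a star scores 1.
    """
    n = tree.n_nodes
    if n < 3:
        return np.zeros(n), 0.0
    adj = tree.adjacency_lists()
    norm = (n - 1) * (n - 2) / 2.0

    # Component sizes hanging off each node via subtree sizes in a rooted copy.
    order = []
    parent = np.full(n, -1, dtype=int)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    subtree = np.ones(n, dtype=int)
    for u in reversed(order):
        if parent[u] >= 0:
            subtree[parent[u]] += subtree[u]

    bc = np.zeros(n)
    for v in range(n):
        comp_sizes = [subtree[c] for c in adj[v] if parent[c] == v]
        if parent[v] >= 0:
            comp_sizes.append(n - subtree[v])
        comp_sizes = np.array(comp_sizes, dtype=float)
        pairs_through = (comp_sizes.sum() ** 2 - (comp_sizes**2).sum()) / 2.0
        bc[v] = pairs_through / norm
    return bc, float(bc.max())


def tree_hierarchy(tree: SpanningTree, variant: str = "count") -> float:
    """Tree hierarchy TH = leaf / (2 m BC_max).

    ``variant='count'`` uses the leaf *number* L (star TH = 0.5 for every
    n, the value the definition anchors); ``variant='fraction'`` uses the
    leaf fraction L/m instead, a 1/m-scaled variant whose magnitude matches
    toolbox outputs that normalize the numerator.  Undefined for n < 3
    (BC_max = 0).
    """
    if tree.n_nodes < 3:
        raise ValueError("tree hierarchy is undefined for fewer than 3 nodes")
    leaf_count, leaf_fraction = leaf_stats(tree)
    _, bc_max = betweenness(tree)
    if variant == "count":
        num = leaf_count
    elif variant == "fraction":
        num = leaf_fraction
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'count' or 'fraction'")
    return num / (2.0 * tree.m * bc_max)


def eccentricity(tree: SpanningTree) -> tuple[np.ndarray, float]:
    """Per-node eccentricity in hops (largest distance to any node) and its mean."""
    d = _all_hop_distances(tree)
    ecc = d.max(axis=1)
    return ecc, float(ecc.mean())


def mst_metrics(fc) -> MstMetrics:
    """Build the maximum spanning tree of ``fc`` and compute all tree metrics."""
    tree = max_spanning_tree(fc)
    leaf_count, leaf_fraction = leaf_stats(tree)
    bc, bc_max = betweenness(tree)
    ecc, ecc_mean = eccentricity(tree)
    return MstMetrics(
        n_nodes=tree.n_nodes,
        m=tree.m,
        diameter_norm=tree_diameter(tree),
        leaf_count=leaf_count,
        leaf_fraction=leaf_fraction,
        kappa=kappa(tree),
        bc=tuple(float(b) for b in bc),
        bc_max=bc_max,
        th_count=tree_hierarchy(tree, "count"),
        th_fraction=tree_hierarchy(tree, "fraction"),
        ecc=tuple(int(e) for e in ecc),
        ecc_mean=ecc_mean,
    )
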