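"""Weighted small-world metrics normalized by weight-reshuffled null networks.

A small-world network combines near-random characteristic path length with
elevated clustering: lambda = L / L_random ~ 1 and gamma = C / C_random > 1,
where the random reference values are ensemble means over null networks
obtained by randomly permuting the edge weights of the observed network over
its own edge positions.  Weight reshuffling preserves the binary topology
(and hence the degree sequence) exactly, so the normalization isolates the
weight organization.

Conventions: clustering is the geometric-mean (Onnela) weighted form with
weights scaled by the network maximum; path length uses the inverse-weight
distance 1/w on nonzero edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra

from .connectivity import FcMatrix
from .errors import DisconnectedGraphError

__all__ = [
    "SwMetrics",
    "weighted_clustering",
    "char_path_length",
    "reshuffle_weights",
    "normalize_sw",
]


@dataclass(frozen=True)
class SwMetrics:
    """Per-subject small-world record: raw C and L plus null-normalized forms."""

    C: float
    L: float
    C_random: float
    L_random: float
    gamma: float
    lambda_: float
    sigma: float  # gamma / lambda_, reported for completeness
    n_random: int
    seed: int


def _weight_matrix(fc) -> np.ndarray:
    w = fc.z if isinstance(fc, FcMatrix) else np.asarray(fc, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative; remove negative correlations first")
    return w


def weighted_clustering(fc) -> float:
    """Network-average geometric-mean weighted clustering coefficient.

    With weights scaled by the network maximum, node i's coefficient is
    the sum over neighbor pairs of the cube-root triangle intensity
    ``(w_ij w_ih w_jh)^(1/3)`` divided by ``k_i (k_i - 1)``; nodes with
    fewer than two neighbors contribute zero.  Equals 1 on an unweighted
    clique and 0 on any triangle-free graph.
    """
    w = _weight_matrix(fc)
    wmax = w.max()
    if wmax == 0:
        return 0.0
    wn = w / wmax
    k = (wn > 0).sum(axis=1)
    cbrt = np.cbrt(wn)
    tri = np.diagonal(cbrt @ cbrt @ cbrt)
    denom = k * (k - 1)
    ci = np.divide(tri, denom, out=np.zeros_like(tri, dtype=float), where=denom > 0)
    return float(ci.mean())


def _components(w: np.ndarray) -> list[list[int]]:
    n_comp, labels = connected_components((w > 0).astype(int), directed=False)
    return [list(np.flatnonzero(labels == c)) for c in range(n_comp)]


def char_path_length(fc) -> float:
    """Characteristic path length: mean shortest 1/w-distance over node pairs."""
    w = _weight_matrix(fc)
    comps = _components(w)
    if len(comps) > 1:
        raise DisconnectedGraphError(
            f"graph has {len(comps)} components: {comps}", components=comps
        )
    with np.errstate(divide="ignore"):
        dist_w = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(dist_w, 0.0)
    d = dijkstra(dist_w, directed=False)
    iu = np.triu_indices(w.shape[0], 1)
    return float(d[iu].mean())


def reshuffle_weights(fc: FcMatrix, seed) -> FcMatrix:
    """Null network: permute the nonzero edge weights over the same edges.

    The multiset of weights and the set of edge positions (hence every
    node's degree) are conserved; only the assignment of weight to edge is
    randomized.  Deterministic under ``seed``.
    """
    z = fc.z.copy()
    n = z.shape[0]
    iu = np.triu_indices(n, 1)
    vals = z[iu]
    nz = vals > 0
    rng = np.random.default_rng(seed)
    shuffled = vals.copy()
    shuffled[nz] = rng.permutation(vals[nz])
    out = np.zeros_like(z)
    out[iu] = shuffled
    out = out + out.T
    return FcMatrix(
        z=out,
        roi_names=list(fc.roi_names),
        negatives_removed=fc.negatives_removed,
        n_timepoints=fc.n_timepoints,
    )


def normalize_sw(fc: FcMatrix, n_random: int = 100, seed: int = 0) -> SwMetrics:
    """Small-world metrics normalized against a reshuffled-null ensemble.

    Ensemble member k is generated with seed ``seed + k`` so individual
    nulls can be reproduced.  gamma = C / mean(C_null); lambda = L /
    mean(L_null).  Members whose graph is disconnected are dropped with a
    warning (reshuffling preserves topology, so this can only arise from a
    disconnected input); more than 10% drops is an error.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    c_obs = weighted_clustering(fc)
    l_obs = char_path_length(fc)
    c_null, l_null = [], []
    dropped = 0
    for k in range(n_random):
        null = reshuffle_weights(fc, seed=seed + k)
        try:
            l_null.append(char_path_length(null))
        except DisconnectedGraphError:
            dropped += 1
            warnings.warn(f"dropping disconnected null network {k}", stacklevel=2)
            continue
        c_null.append(weighted_clustering(null))
    if dropped > 0.1 * n_random:
        raise DisconnectedGraphError(
            f"{dropped}/{n_random} null networks disconnected; input too sparse"
        )
    # mean centered on the observed value: free of cancellation error, and
    # exactly equal to C (resp. L) when every null matches the original, so
    # the weight-constant fixed point gives gamma = lambda = 1 exactly
    c_rand = c_obs + math.fsum(c - c_obs for c in c_null) / len(c_null)
    l_rand = l_obs + math.fsum(l - l_obs for l in l_null) / len(l_null)
    gamma = c_obs / c_rand
    lambda_ = l_obs / l_rand
    return SwMetrics(
        C=c_obs,
        L=l_obs,
        C_random=c_rand,
        L_random=l_rand,
        gamma=gamma,
        lambda_=lambda_,
        sigma=gamma / lambda_,
        n_random=n_random - dropped,
        seed=seed,
    )
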