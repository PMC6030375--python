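"""Weighted graph metrics for FA-weighted structural connectomes.

Conventions (held throughout the package):

* Edge length is the reciprocal edge weight, 1/w_ij; shortest-path
  distances L_ij are sums of reciprocals.
* The characteristic path length L^w is the harmonic mean of L_ij over
  ordered pairs: L^w = N(N-1) / sum_{i != j} 1/L_ij.  Disconnected pairs
  contribute 1/inf = 0 to the sum, so L^w and every efficiency remain
  finite on disconnected graphs.
* With that convention the global efficiency is exactly 1/L^w, and the
  mean nodal efficiency equals the global efficiency.
* Clustering is the weighted (geometric-mean) clustering coefficient
  C_i^w = 1/(k_i (k_i - 1)) * sum_{j,h} (w_ij w_ih w_jh)^{1/3} with k_i the
  binary degree; nodes with k_i < 2 get C_i^w = 0 but stay in the average.
* Betweenness B_i^w counts, over all source-target pairs (s != t != i),
  the fraction of shortest s-t paths (by 1/w length) passing through i;
  b_i^w = B_i^w / <B^w> normalizes by the network mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path
from scipy.sparse.csgraph import connected_components as _sp_connected_components

from .construction import as_weights


@dataclass(frozen=True)
class GlobalMetricSet:
    """Whole-network measures of one subject.

    gamma, lam, sigma (normalized clustering, normalized path length, and
    small-worldness sigma = gamma/lam) require a matched random-network
    ensemble and are None when no ensemble was computed.
    """

    clustering_cw: float
    path_length_lw: float
    strength_sw: float
    e_global: float
    e_local: float
    gamma: Optional[float] = None
    lam: Optional[float] = None
    sigma: Optional[float] = None


@dataclass(frozen=True)
class NodalMetricSet:
    """Per-node measures of one subject (arrays of length n_nodes)."""

    strength: np.ndarray           # k_i^w, sum of incident weights
    efficiency: np.ndarray         # e_i^w
    betweenness_raw: np.ndarray    # B_i^w
    betweenness: np.ndarray        # b_i^w = B_i^w / <B^w>
    clustering: np.ndarray         # C_i^w
    degree: np.ndarray             # binary degree k_i


def degree(W) -> np.ndarray:
    """Binary degree: number of nonzero off-diagonal entries per row."""
    A = as_weights(W)
    return np.count_nonzero(A > 0, axis=1).astype(int)


def strength(W) -> tuple[np.ndarray, float]:
    """Nodal strength k_i^w (row sums) and their mean S^w."""
    A = as_weights(W)
    k = A.sum(axis=1)
    return k, float(k.mean())


def shortest_path_lengths(W) -> np.ndarray:
    """All-pairs shortest-path distances over edge lengths 1/w_ij.

    Returns a symmetric matrix with zero diagonal; +inf marks pairs with
    no connecting path.
    """
    A = as_weights(W)
    n = A.shape[0]
    rows, cols = np.nonzero(np.triu(A, k=1))
    lengths = 1.0 / A[rows, cols]
    graph = csr_matrix((lengths, (rows, cols)), shape=(n, n))
    D = _sp_shortest_path(graph, method="D", directed=False)
    return D


def _inverse_distances(D: np.ndarray) -> np.ndarray:
    """1/L_ij with the 1/inf = 0 convention and a zero diagonal."""
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def characteristic_path_length(D: np.ndarray) -> float:
    """Harmonic-mean shortest path length L^w = N(N-1) / sum 1/L_ij."""
    n = D.shape[0]
    total = _inverse_distances(D).sum()
    if total == 0.0:
        raise ValueError("no finite off-diagonal distance: L^w undefined")
    return n * (n - 1) / total


def global_efficiency(D: np.ndarray) -> float:
    """E_global = mean of 1/L_ij over ordered pairs (0 for edgeless graphs)."""
    n = D.shape[0]
    if n < 2:
        return 0.0
    return float(_inverse_distances(D).sum() / (n * (n - 1)))


def nodal_efficiency(D: np.ndarray) -> np.ndarray:
    """e_i^w = mean of 1/L_ij over the other N-1 nodes; mean equals E_global."""
    n = D.shape[0]
    return _inverse_distances(D).sum(axis=1) / (n - 1)


def single_node_efficiency(W, node: int) -> float:
    """Nodal efficiency of one node via a single-source Dijkstra pass.

    ``node`` is a 0-based matrix index.  Cheaper than the all-pairs route
    when only one region is of interest (e.g. severity correlation at the
    left precuneus).
    """
    A = as_weights(W)
    n = A.shape[0]
    rows, cols = np.nonzero(np.triu(A, k=1))
    graph = csr_matrix((1.0 / A[rows, cols], (rows, cols)), shape=(n, n))
    d = _sp_shortest_path(graph, method="D", directed=False, indices=node)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    inv[node] = 0.0
    return float(inv.sum() / (n - 1))


def weighted_clustering(W) -> tuple[np.ndarray, float]:
    """Weighted clustering C_i^w per node and the network mean C^w.

    Uses the geometric-mean triangle intensity: the numerator
    sum_{j,h} (w_ij w_ih w_jh)^{1/3} over ordered neighbor pairs is the
    diagonal of the cubed matrix of cube-rooted weights; the ordered-pair
    double counting cancels against k_i (k_i - 1).
    """
    A = as_weights(W)
    k = np.count_nonzero(A > 0, axis=1)
    C13 = np.cbrt(A)
    cycles = np.diagonal(C13 @ C13 @ C13)
    denom = k * (k - 1)
    ci = np.zeros(A.shape[0])
    ok = denom > 0
    ci[ok] = cycles[ok] / denom[ok]
    return ci, float(ci.mean())


def local_efficiency(W) -> float:
    """E_local = mean over nodes of E_global of the neighbor-induced subgraph.

    The subgraph G_i keeps the original weights among the neighbors of i
    (i itself excluded); nodes with fewer than 2 neighbors contribute 0.
    """
    A = as_weights(W)
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(A[i] > 0)
        if nbrs.size < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        total += global_efficiency(shortest_path_lengths(sub))
    return total / n


def betweenness(W) -> tuple[np.ndarray, np.ndarray]:
    """Betweenness B_i^w (pair-fraction counts) and b_i^w = B_i^w / <B^w>.

    Shortest paths use 1/w edge lengths (Brandes' algorithm).  Each
    unordered source-target pair contributes once.  If every B_i^w is 0
    (e.g. a complete triangle has no intermediate vertices), all b_i^w
    are defined as 0.
    """
    import networkx as nx

    A = as_weights(W)
    n = A.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    rows, cols = np.nonzero(np.triu(A, k=1))
    G.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / A[i, j]) for i, j in zip(rows, cols)),
        weight="length",
    )
    bc = nx.betweenness_centrality(G, normalized=False, weight="length")
    B = np.array([bc[i] for i in range(n)])
    mean_b = B.mean()
    b = B / mean_b if mean_b > 0 else np.zeros(n)
    return B, b


def is_connected(W) -> bool:
    A = as_weights(W)
    n = A.shape[0]
    rows, cols = np.nonzero(np.triu(A, k=1))
    graph = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    n_comp, _ = _sp_connected_components(graph, directed=False)
    return n_comp == 1


def global_metrics(W, gamma: Optional[float] = None, lam: Optional[float] = None) -> GlobalMetricSet:
    """All whole-network measures of one subject.

    gamma/lam come from :func:`fanet.nullmodels.small_world_indices`; when
    given, sigma = gamma/lam is filled in.
    """
    D = shortest_path_lengths(W)
    _, cw = weighted_clustering(W)
    _, sw = strength(W)
    sigma = (gamma / lam) if (gamma is not None and lam is not None) else None
    return GlobalMetricSet(
        clustering_cw=cw,
        path_length_lw=characteristic_path_length(D),
        strength_sw=sw,
        e_global=global_efficiency(D),
        e_local=local_efficiency(W),
        gamma=gamma,
        lam=lam,
        sigma=sigma,
    )


def nodal_metrics(W) -> NodalMetricSet:
    """All per-node measures of one subject."""
    D = shortest_path_lengths(W)
    ci, _ = weighted_clustering(W)
    k, _ = strength(W)
    B, b = betweenness(W)
    return NodalMetricSet(
        strength=k,
        efficiency=nodal_efficiency(D),
        betweenness_raw=B,
        betweenness=b,
        clustering=ci,
        degree=degree(W),
    )
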