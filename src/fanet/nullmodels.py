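"""Matched random networks and normalized small-world indices.

"Matched" means: identical node count, edge count, binary degree sequence
(degree-preserving double-edge swaps), and identical multiset of edge
weights (the original weights are shuffled onto the rewired topology).
The normalized indices are gamma = C^w / <C^w_random>,
lam = L^w / <L^w_random>, sigma = gamma / lam; sigma > 1 with lam near 1
is the small-world signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .construction import ConnectivityMatrix, as_weights
from .metrics import (
    characteristic_path_length,
    is_connected,
    shortest_path_lengths,
    weighted_clustering,
)

_MAX_CONNECT_RETRIES = 5


@dataclass(frozen=True)
class NullEnsemble:
    """Summary of a matched random-network ensemble for one subject."""

    n_random: int
    c_random_mean: float
    l_random_mean: float
    seed: int


def _edge_list(A: np.ndarray) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(np.triu(A, k=1))
    return list(zip(rows.tolist(), cols.tolist()))


def _double_edge_swaps(edges: list[tuple[int, int]], n_swaps: int,
                       rng: np.random.Generator) -> int:
    """In-place degree-preserving double-edge swaps; returns successes.

    A swap picks edges (u,v), (x,y) and proposes (u,x), (v,y) (with a
    random orientation of the second edge).  It is rejected when the four
    endpoints are not distinct or either proposed edge already exists —
    both degree sequence and edge count are therefore invariant.
    """
    m = len(edges)
    if m < 2:
        return 0
    edge_set = set(edges)
    successes = 0
    tries = 0
    max_tries = 20 * n_swaps + 100
    block = 512
    while successes < n_swaps and tries < max_tries:
        pick = rng.integers(0, m, size=(block, 2))
        coin = rng.random(block) < 0.5
        for (e1, e2), flip in zip(pick, coin):
            tries += 1
            if successes >= n_swaps or tries >= max_tries:
                break
            if e1 == e2:
                continue
            u, v = edges[e1]
            x, y = edges[e2]
            if flip:
                x, y = y, x
            if u == x or u == y or v == x or v == y:
                continue
            new1 = (u, x) if u < x else (x, u)
            new2 = (v, y) if v < y else (y, v)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.remove(edges[e1])
            edge_set.remove(edges[e2])
            edges[e1] = new1
            edges[e2] = new2
            edge_set.add(new1)
            edge_set.add(new2)
            successes += 1
    return successes


def randomize_network(W, swaps_per_edge: int = 10,
                      seed: int | None = None,
                      require_connected: bool = True) -> ConnectivityMatrix:
    """Degree- and weight-multiset-preserving randomization of a network.

    The binary topology is rewired by double-edge swaps (``swaps_per_edge``
    successful swaps per edge on average) and the original edge weights
    are randomly reassigned to the rewired edges.  Graphs admitting no
    legal swap (e.g. complete graphs) come back as a weight-shuffled copy
    with a warning.  Disconnected realizations are resampled a bounded
    number of times, then accepted with a warning (distances to unreachable
    nodes follow the 1/inf = 0 convention downstream).
    """
    A = as_weights(W)
    orig_edges = _edge_list(A)
    m = len(orig_edges)
    if m < 2:
        raise ValueError("randomization needs at least 2 edges")
    weights = A[tuple(np.array(orig_edges).T)]
    rng = np.random.default_rng(seed)

    for attempt in range(_MAX_CONNECT_RETRIES + 1):
        edges = list(orig_edges)
        done = _double_edge_swaps(edges, swaps_per_edge * m, rng)
        if done == 0:
            warnings.warn(
                "no legal degree-preserving swap exists; "
                "returning a weight-shuffled copy", stacklevel=2)
        new_w = weights[rng.permutation(m)]
        n = A.shape[0]
        R = np.zeros_like(A)
        idx = np.array(edges)
        R[idx[:, 0], idx[:, 1]] = new_w
        R = R + R.T
        if not require_connected or done == 0 or is_connected(R):
            break
        if attempt == _MAX_CONNECT_RETRIES:
            warnings.warn(
                "rewired network disconnected after retries; accepting it "
                "(disconnected pairs contribute zero efficiency)", stacklevel=2)
    sid = W.subject_id if isinstance(W, ConnectivityMatrix) else ""
    labels = W.labels if isinstance(W, ConnectivityMatrix) else None
    return ConnectivityMatrix(R, labels=labels, subject_id=sid)


def small_world_indices(W, n_random: int = 100, swaps_per_edge: int = 10,
                        seed: int | None = None) -> tuple[float, float, float, NullEnsemble]:
    """Normalized small-world indices against a matched random ensemble.

    Returns (gamma, lam, sigma, ensemble) where gamma = C^w/<C^w_random>,
    lam = L^w/<L^w_random> and sigma = gamma/lam.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    _, cw = weighted_clustering(W)
    lw = characteristic_path_length(shortest_path_lengths(W))
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for r in range(n_random):
        R = randomize_network(W, swaps_per_edge=swaps_per_edge,
                              seed=int(rng.integers(2**31 - 1)))
        _, c_rand[r] = weighted_clustering(R)
        l_rand[r] = characteristic_path_length(shortest_path_lengths(R))
    c_mean = float(c_rand.mean())
    l_mean = float(l_rand.mean())
    if c_mean == 0 or l_mean == 0:
        raise ValueError("degenerate random ensemble (zero mean C^w or L^w)")
    gamma = cw / c_mean
    lam = lw / l_mean
    ens = NullEnsemble(n_random=n_random, c_random_mean=c_mean,
                       l_random_mean=l_mean,
                       seed=-1 if seed is None else int(seed))
    return gamma, lam, gamma / lam, ens
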