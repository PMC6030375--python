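"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use different algorithms from the package
(Floyd-Warshall triple loop vs Dijkstra, explicit triple loops vs matrix
powers, path-count dynamic programming vs Brandes accumulation) so that
agreement is a genuine cross-check.
"""

import numpy as np
import pytest

from fanet import CohortConfig, generate_cohort
from fanet.metrics import (
    characteristic_path_length,
    global_efficiency,
    local_efficiency,
    shortest_path_lengths,
)


# ---------------------------------------------------------------------------
# small canonical graphs


@pytest.fixture
def chain3():
    """a-b and b-c with weight 0.5 each (edge length 2)."""
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[1, 2] = W[2, 1] = 0.5
    return W


@pytest.fixture
def triangle():
    """Complete 3-node graph, all weights 0.5."""
    W = np.full((3, 3), 0.5)
    np.fill_diagonal(W, 0.0)
    return W


@pytest.fixture
def star5():
    """5-node star: center 0 connected to 4 leaves with weight 0.6."""
    W = np.zeros((5, 5))
    W[0, 1:] = W[1:, 0] = 0.6
    return W


def random_weighted_graph(rng, n_max=10, p_edge=0.45):
    """Random symmetric weighted graph with weights in (0.1, 1)."""
    n = int(rng.integers(4, n_max + 1))
    A = rng.random((n, n)) < p_edge
    W = np.where(A, rng.uniform(0.1, 1.0, (n, n)), 0.0)
    W = np.triu(W, k=1)
    return W + W.T


# ---------------------------------------------------------------------------
# brute-force oracles


def floyd_warshall_oracle(W):
    """All-pairs shortest paths over 1/w lengths by explicit relaxation."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def clustering_oracle(W):
    """Weighted clustering by explicit loops over ordered neighbor pairs."""
    n = W.shape[0]
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and W[j, h] > 0:
                    total += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
        C[i] = total / (k * (k - 1))
    return C


def local_efficiency_oracle(W):
    """Recompute each neighbor subgraph independently via the FW oracle."""
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = floyd_warshall_oracle(sub)
        m = len(nbrs)
        inv = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and np.isfinite(D[a, b]):
                    inv += 1.0 / D[a, b]
        total += inv / (m * (m - 1))
    return total / n


def betweenness_oracle(W, rel_tol=1e-10):
    """Pair-fraction betweenness by shortest-path counting on FW distances.

    Counts each unordered source-target pair once; sigma[s, t] (number of
    shortest s-t paths) comes from a dynamic program over the distance
    matrix, and the through-i count is sigma[s,i]*sigma[i,t] when i lies
    on a shortest path.
    """
    n = W.shape[0]
    D = floyd_warshall_oracle(W)

    def n_paths(s, t):
        if s == t:
            return 1
        if not np.isfinite(D[s, t]):
            return 0
        total = 0
        for u in range(n):
            if W[u, t] > 0 and u != t:
                if abs(D[s, u] + 1.0 / W[u, t] - D[s, t]) <= rel_tol * max(1.0, D[s, t]):
                    total += n_paths(s, u)
        return total

    B = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]):
                continue
            sigma_st = n_paths(s, t)
            if sigma_st == 0:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                on_path = abs(D[s, i] + D[i, t] - D[s, t]) \
                    <= rel_tol * max(1.0, D[s, t])
                if on_path:
                    B[i] += n_paths(s, i) * n_paths(i, t) / sigma_st
    return B


# ---------------------------------------------------------------------------
# the packaged default cohort, computed once per session


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def default_global_metrics(default_cohort):
    """Per-subject L^w, E_global, E_local of the packaged cohort."""
    matrices, metas = default_cohort
    rows = []
    for mat, meta in zip(matrices, metas):
        D = shortest_path_lengths(mat)
        rows.append({
            "subject_id": meta.subject_id,
            "group": meta.group,
            "lw": characteristic_path_length(D),
            "eg": global_efficiency(D),
            "el": local_efficiency(mat),
        })
    return rows
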