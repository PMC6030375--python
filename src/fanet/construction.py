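"""FA-weighted connectivity-matrix construction from fiber records.

A structural connectome edge exists between two parcellation regions as
soon as at least one tractography streamline (fiber) connects them; the
edge weight is the arithmetic mean of the per-fiber mean fractional
anisotropy (FA) over all fibers linking the pair.  Region labels are
1-based AAL indices at the API boundary and 0-based rows/columns inside
the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .aal import AAL90_LABELS

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class FiberRecord:
    """One tracked fiber: its region-pair endpoints and per-fiber mean FA."""

    subject_id: str
    region_a: int          # 1-based node label
    region_b: int          # 1-based node label
    fa: float              # fractional anisotropy, in (0, 1]

    def __post_init__(self):
        if int(self.region_a) == int(self.region_b):
            raise ValueError(
                f"self-loop fiber rejected: region {self.region_a} "
                f"(subject {self.subject_id!r})"
            )
        if not (0.0 < self.fa <= 1.0):
            raise ValueError(f"FA must lie in (0, 1], got {self.fa}")

    def canonical_pair(self) -> tuple[int, int]:
        """Orderless (low, high) region pair; (a, b) and (b, a) pool together."""
        a, b = int(self.region_a), int(self.region_b)
        return (a, b) if a < b else (b, a)


class ConnectivityMatrix:
    """Per-subject symmetric nonnegative weight matrix with region labels.

    Invariants enforced on construction: square, symmetric (within 1e-9),
    zero diagonal, entries in [0, 1].
    """

    def __init__(self, weights: np.ndarray, labels: Optional[Sequence[str]] = None,
                 subject_id: str = ""):
        W = np.asarray(weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        n = W.shape[0]
        asym = np.abs(W - W.T)
        if asym.max(initial=0.0) > _SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), W.shape)
            raise ValueError(
                f"asymmetric weights: w[{i},{j}]={W[i, j]!r} vs w[{j},{i}]={W[j, i]!r}"
            )
        W = (W + W.T) / 2.0
        if np.any(np.diag(W) != 0):
            i = int(np.flatnonzero(np.diag(W))[0])
            raise ValueError(f"nonzero diagonal entry at node {i + 1}")
        if np.any(W < 0) or np.any(W > 1):
            i, j = np.unravel_index(int(np.argmin((W >= 0) & (W <= 1))), W.shape)
            raise ValueError(f"entry outside [0, 1] at ({i + 1},{j + 1}): {W[i, j]}")
        if labels is None:
            labels = (AAL90_LABELS if n == len(AAL90_LABELS)
                      else tuple(f"node_{i + 1}" for i in range(n)))
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} nodes")
        self.weights = W
        self.labels = labels
        self.subject_id = str(subject_id)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.weights, dtype=dtype)

    def __repr__(self):
        return (f"ConnectivityMatrix(subject_id={self.subject_id!r}, "
                f"n_nodes={self.n_nodes}, n_edges={self.n_edges})")


def as_weights(W) -> np.ndarray:
    """Accept a ConnectivityMatrix or a plain array and return the array."""
    if isinstance(W, ConnectivityMatrix):
        return W.weights
    return np.asarray(W, dtype=float)


def build_connectivity(fibers: Iterable[FiberRecord], n_nodes: int,
                       min_fibers: int = 1,
                       subject_id: Optional[str] = None) -> ConnectivityMatrix:
    """Aggregate fiber records of one subject into a connectivity matrix.

    weight(a, b) = mean FA over all fibers between a and b (orderless);
    pairs connected by fewer than ``min_fibers`` fibers (default 1, i.e.
    "at least one fiber") get weight 0.
    """
    fibers = list(fibers)
    if subject_id is None:
        subject_id = fibers[0].subject_id if fibers else ""
    total = np.zeros((n_nodes, n_nodes))
    count = np.zeros((n_nodes, n_nodes), dtype=int)
    for rec in fibers:
        if rec.subject_id != subject_id:
            raise ValueError(
                f"fiber of subject {rec.subject_id!r} mixed into "
                f"subject {subject_id!r}"
            )
        a, b = rec.canonical_pair()
        if not (1 <= a <= n_nodes and 1 <= b <= n_nodes):
            raise ValueError(
                f"region label outside 1..{n_nodes} in record "
                f"({rec.region_a}, {rec.region_b}, fa={rec.fa})"
            )
        total[a - 1, b - 1] += rec.fa
        count[a - 1, b - 1] += 1
    if not fibers:
        warnings.warn("no fiber records: returning an all-zero matrix",
                      stacklevel=2)
    keep = count >= max(1, int(min_fibers))
    W = np.zeros_like(total)
    W[keep] = total[keep] / count[keep]
    W = W + W.T
    return ConnectivityMatrix(W, subject_id=subject_id)


# ---------------------------------------------------------------------------
# plain-text IO


def write_matrix(W: ConnectivityMatrix, path) -> None:
    """Write a connectivity matrix as TSV with a header row of region labels."""
    df = pd.DataFrame(W.weights, columns=W.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_matrix(path, subject_id: str = "") -> ConnectivityMatrix:
    """Read a TSV adjacency matrix, validating the container invariants."""
    df = pd.read_csv(path, sep="\t")
    W = df.to_numpy(dtype=float)
    try:
        return ConnectivityMatrix(W, labels=tuple(df.columns), subject_id=subject_id)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def write_fibers(fibers: Iterable[FiberRecord], path) -> None:
    """Write fiber records as CSV (subject_id, region_a, region_b, fa)."""
    df = pd.DataFrame(
        [(f.subject_id, f.region_a, f.region_b, f.fa) for f in fibers],
        columns=["subject_id", "region_a", "region_b", "fa"],
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_fibers(path) -> list[FiberRecord]:
    """Read a fiber CSV (possibly multi-subject) into records."""
    df = pd.read_csv(path)
    required = {"subject_id", "region_a", "region_b", "fa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing fiber columns {sorted(missing)}")
    return [
        FiberRecord(str(r.subject_id), int(r.region_a), int(r.region_b), float(r.fa))
        for r in df.itertuples(index=False)
    ]


def to_graphml(W: ConnectivityMatrix, path) -> None:
    """Export one subject's network as GraphML with a 'weight' edge attribute."""
    import networkx as nx

    G = nx.Graph()
    for i, lab in enumerate(W.labels):
        G.add_node(lab, aal_index=i + 1)
    rows, cols = np.nonzero(np.triu(W.weights, k=1))
    for i, j in zip(rows, cols):
        G.add_edge(W.labels[i], W.labels[j], weight=float(W.weights[i, j]))
    nx.write_graphml(G, path)
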