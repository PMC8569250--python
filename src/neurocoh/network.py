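"""Weighted undirected brain networks: thresholding, shortest paths,
global efficiency and its area under the threshold curve.

Graphs are built from a symmetric nonnegative connectivity matrix (Fisher-z
coherence).  Because there is no principled single threshold, metrics are
computed over a sparsity sweep (default 0.10 to 0.40 in steps of 0.05: the
proportion of strongest edges retained) and summarized by the trapezoidal
area under the metric-vs-threshold curve (AUC).  Global efficiency of a
graph G with N nodes is

    E_global(G) = 1 / (N (N - 1)) * sum_{i != j} 1 / D(i, j)

where D(i, j) is the weighted shortest-path length between nodes i and j
(edge length = 1 / weight by default) and 1/inf := 0 for disconnected
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "WeightedGraph",
    "NetworkMetrics",
    "DEFAULT_THRESHOLDS",
    "threshold_graph",
    "shortest_paths",
    "global_efficiency",
    "efficiency_auc",
    "efficiency_curve",
]

#: Sparsity sweep: 0.10, 0.15, ..., 0.40.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.401, 0.05), 2))


@dataclass
class WeightedGraph:
    """Thresholded weighted undirected graph.

    ``weights`` is the full symmetric matrix; ``mask`` marks retained edges
    (symmetric, no self-loops).  Retained edges keep their original weights.
    """

    weights: np.ndarray
    mask: np.ndarray
    labels: tuple[str, ...] | None = None
    sparsity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def adjacency(self) -> np.ndarray:
        """Weights with non-retained edges zeroed."""
        return np.where(self.mask, self.weights, 0.0)


def _check_square_symmetric(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    if np.any(w < -1e-12):
        raise ValueError("edge weights must be nonnegative")
    return np.maximum((w + w.T) / 2.0, 0.0)


def threshold_graph(
    z_matrix: np.ndarray,
    sparsity: float,
    labels: tuple[str, ...] | None = None,
    mode: str = "sparsity",
) -> WeightedGraph:
    """Retain the strongest edges of a weighted network.

    ``mode="sparsity"`` (default) keeps the ``ceil(sparsity * N(N-1)/2)``
    largest-weight edges; ties at the cut are broken deterministically by
    node-index lexicographic order, so equal borderline weights always
    resolve the same way.  ``mode="absolute"`` instead keeps every edge with
    weight >= sparsity.
    """
    w = _check_square_symmetric(z_matrix)
    n = w.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    if mode == "sparsity":
        if not 0 < sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        n_edges = len(iu)
        k = int(np.ceil(sparsity * n_edges))
        order = sorted(range(n_edges), key=lambda e: (-w[iu[e], ju[e]], iu[e], ju[e]))
        keep = order[:k]
        mask[iu[keep], ju[keep]] = True
    elif mode == "absolute":
        sel = w[iu, ju] >= sparsity
        mask[iu[sel], ju[sel]] = True
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    mask |= mask.T
    return WeightedGraph(weights=w, mask=mask, labels=labels, sparsity=float(sparsity))


def shortest_paths(g: WeightedGraph, length: str = "reciprocal") -> np.ndarray:
    """All-pairs weighted shortest path lengths (Dijkstra).

    Edge length is ``1/weight`` (default) or ``1 - weight`` when
    ``length="inverse_complement"``.  The result is symmetric with zero
    diagonal; unreachable pairs are ``inf``.
    """
    adj = g.adjacency()
    n = g.n_nodes
    lengths = np.zeros((n, n))
    edge = g.mask & (adj > 0)
    if length == "reciprocal":
        lengths[edge] = 1.0 / adj[edge]
    elif length == "inverse_complement":
        lengths[edge] = 1.0 - adj[edge]
        if np.any(lengths[edge] < 0):
            raise ValueError("1-weight lengths require weights <= 1")
    else:
        raise ValueError(f"unknown length convention {length!r}")
    # zero-weight retained edges contribute no path; drop them from the graph
    D = _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def global_efficiency(D: np.ndarray, n_nodes: int | None = None) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    D = np.asarray(D, dtype=float)
    n = n_nodes if n_nodes is not None else D.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    off = ~np.eye(D.shape[0], dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def efficiency_auc(thresholds, values) -> float:
    """Trapezoidal AUC of a metric over a threshold grid (sorted internally)."""
    t = np.asarray(thresholds, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.size < 2:
        raise ValueError("need >= 2 matching (threshold, value) points")
    order = np.argsort(t)
    return float(np.trapezoid(v[order], t[order]))


@dataclass
class NetworkMetrics:
    """Global efficiency across a threshold sweep plus its AUC."""

    thresholds: tuple[float, ...]
    eglobal: tuple[float, ...]
    auc: float
    band: str = ""

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.eglobal):
            raise ValueError("thresholds and eglobal lengths differ")


def efficiency_curve(
    z_matrix: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
    labels: tuple[str, ...] | None = None,
    mode: str = "sparsity",
    length: str = "reciprocal",
    band: str = "",
) -> NetworkMetrics:
    """Threshold sweep: global efficiency at each sparsity plus the AUC."""
    eff = []
    for t in thresholds:
        g = threshold_graph(z_matrix, t, labels=labels, mode=mode)
        D = shortest_paths(g, length=length)
        eff.append(global_efficiency(D))
    return NetworkMetrics(
        thresholds=tuple(float(t) for t in thresholds),
        eglobal=tuple(eff),
        auc=efficiency_auc(thresholds, eff),
        band=band,
    )
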