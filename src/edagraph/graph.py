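"""Time-series-to-graph transform for electrodermal activity.

An EDA window is quantized to discrete conductance levels (step Q, default
0.05 μS); the unique levels become graph nodes. Consecutive samples that
land on distinct levels register their level pair as a candidate edge
(temporal co-occurrence). Each node then keeps its k nearest co-occurring
neighbors ranked by absolute conductance difference D_ij, and the undirected
union of the selections forms the edge set with weights w_ij = 1/D_ij. The
adjacency matrix A is therefore symmetric with zero diagonal, and spectral
features can be read from A and the combinatorial Laplacian L = D - A.

Nodes are identified by their integer level index (value / Q), which makes
node identity exact in floating point; the physical value of node i is
``i * Q`` microsiemens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .preprocess import TimeSeries

__all__ = [
    "DEFAULT_Q",
    "QuantizedSignal",
    "EdaGraph",
    "quantize",
    "candidate_pairs",
    "build_graph",
    "laplacian",
    "graph_from_window",
]

#: Default quantization step in microsiemens.
DEFAULT_Q = 0.05


@dataclass(frozen=True)
class QuantizedSignal:
    """A signal snapped to integer multiples of the quantization step Q.

    ``level_indices`` holds the integer multiples; ``levels`` the physical
    values ``level_indices * Q``.
    """

    level_indices: np.ndarray
    Q: float
    source_fs: float

    @property
    def levels(self) -> np.ndarray:
        return self.level_indices * self.Q

    @property
    def unique_indices(self) -> np.ndarray:
        return np.unique(self.level_indices)


@dataclass
class EdaGraph:
    """Undirected weighted graph over quantized EDA levels.

    ``graph`` is a networkx ``Graph`` whose node keys are integer level
    indices with a ``value`` attribute (μS); edge weights are 1/D_ij with
    D_ij the absolute value difference. ``A``, ``D`` and ``L`` are dense
    matrices in ascending node-value order.
    """

    graph: nx.Graph
    Q: float
    k: int
    node_order: np.ndarray  # sorted level indices

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_values(self) -> np.ndarray:
        return self.node_order * self.Q

    @property
    def A(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=list(self.node_order), weight="weight")

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.A.sum(axis=1))

    @property
    def L(self) -> np.ndarray:
        a = self.A
        return np.diag(a.sum(axis=1)) - a

    def to_edgelist(self, path: str | Path) -> None:
        """Dump edges as ``value_i value_j weight`` text, nodes ascending."""
        lines = []
        for i, j in sorted((min(u, v), max(u, v)) for u, v in self.graph.edges):
            w = self.graph[i][j]["weight"]
            lines.append(f"{i * self.Q:.6f}\t{j * self.Q:.6f}\t{w:.9g}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def quantize(sig: TimeSeries | np.ndarray, Q: float = DEFAULT_Q,
             fs: float | None = None) -> QuantizedSignal:
    """Snap each sample to the nearest multiple of Q.

    Half-step ties round away from zero (0.125 with Q = 0.05 maps to 0.15),
    avoiding platform-dependent bankers' rounding. A small relative epsilon
    guards exact half-way values against binary representation error.
    """
    if Q <= 0:
        raise ValueError("Q must be positive")
    if isinstance(sig, TimeSeries):
        values, fs = sig.values, sig.fs
    else:
        values = np.asarray(sig, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    ratio = np.abs(values) / Q
    idx = np.floor(ratio + 0.5 + 1e-9).astype(np.int64)
    idx = np.sign(values).astype(np.int64) * idx
    return QuantizedSignal(level_indices=idx, Q=float(Q), source_fs=float(fs))


def candidate_pairs(qsig: QuantizedSignal) -> set[tuple[int, int]]:
    """Unordered level-index pairs that co-occur consecutively in time.

    Consecutive samples on the same level produce no pair (a revisit of the
    same node, not a self-loop); repeats of the same pair collapse to one.
    """
    idx = qsig.level_indices
    if idx.size < 2:
        return set()
    a, b = idx[:-1], idx[1:]
    mask = a != b
    lo = np.minimum(a[mask], b[mask])
    hi = np.maximum(a[mask], b[mask])
    return set(zip(lo.tolist(), hi.tolist()))


def build_graph(qsig: QuantizedSignal, k: int | None = None) -> EdaGraph:
    """Assemble the kNN co-occurrence graph from a quantized signal.

    For each node its co-occurring partners are ranked by distance
    D_ij = |x_i - x_j| ascending and the closest k kept; partners tied with
    the k-th distance are all kept, which makes the selection deterministic
    and independent of input ordering. The edge set is the undirected union
    of all per-node selections; a single-level signal yields a valid one-node
    graph with no edges.

    ``k`` defaults to ``round(source_fs)``, matching the convention of one
    neighbor per sample of one second of signal.
    """
    if k is None:
        k = int(round(qsig.source_fs))
    if k < 1:
        raise ValueError("k must be >= 1")
    g = nx.Graph()
    for level in qsig.unique_indices:
        g.add_node(int(level), value=float(level * qsig.Q))
    pairs = candidate_pairs(qsig)
    neighbors: dict[int, list[int]] = {int(n): [] for n in qsig.unique_indices}
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)
    selected: set[tuple[int, int]] = set()
    for node, cands in neighbors.items():
        if not cands:
            continue
        dists = sorted(abs(c - node) for c in cands)
        cutoff = dists[min(k, len(dists)) - 1]  # ties with k-th rank kept
        for c in cands:
            if abs(c - node) <= cutoff:
                selected.add((min(node, c), max(node, c)))
    Q = qsig.Q
    for i, j in selected:
        d = abs(i - j) * Q
        g.add_edge(i, j, weight=1.0 / d, distance=d)
    order = np.sort(qsig.unique_indices)
    return EdaGraph(graph=g, Q=Q, k=k, node_order=order)


def laplacian(g: EdaGraph) -> np.ndarray:
    """Combinatorial Laplacian L = D - A (weighted, symmetric PSD)."""
    return g.L


def graph_from_window(eda: TimeSeries, Q: float = DEFAULT_Q,
                      k: int | None = None) -> EdaGraph:
    """Quantize an EDA window and build its graph in one step."""
    return build_graph(quantize(eda, Q=Q), k=k)
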