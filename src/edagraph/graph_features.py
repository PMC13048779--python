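"""Topological and spectral feature battery for EDA-graphs.

Features are organized in three hierarchical levels. Graph-level features
summarize global structure: connectivity counts (triangles, transitivity,
maximal cliques), weighted distance metrics (diameter, radius, periphery),
clustering, and spectral statistics of the adjacency matrix and of the
combinatorial Laplacian (graph energy is the sum of absolute adjacency
eigenvalues). Node-level features summarize per-node centralities (degree,
closeness, betweenness, eigenvector, harmonic) and eccentricities by their
max / min / median, plus the total eigenvector centrality. Edge-level
features capture flow: current-flow (random-walk) betweenness of nodes and
edges, current-flow closeness, degree assortativity, degree-strength
correlation, and edge-weight statistics.

Conventions (recorded per-feature in the manifest):

* counting metrics use the unweighted skeleton;
* distance metrics use the value difference D_ij = 1/w_ij as edge length;
* spectral and flow metrics use the weighted adjacency (weight = affinity);
* on disconnected graphs, distance/flow/eigenvector metrics are computed on
  the largest connected component;
* degenerate graphs (single node, no edges) emit documented zero sentinels
  instead of raising, so every window maps to a full-length vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import stats

from .graph import EdaGraph

__all__ = [
    "FeatureSpec",
    "MANIFEST",
    "GRAPH_FEATURE_NAMES",
    "graph_level_features",
    "spectrum_stats",
    "node_level_features",
    "edge_level_features",
    "wl_signature",
    "edagraph_feature_vector",
    "manifest_json",
]


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str        # graph | node | edge
    weighted: bool       # whether edge weights/lengths enter the computation
    sentinel: float = 0.0


def _specs(category: str, weighted: bool, names: Iterable[str]) -> list[FeatureSpec]:
    return [FeatureSpec(n, category, weighted) for n in names]


#: Frozen 66-feature manifest: the single source of truth for roster order.
MANIFEST: tuple[FeatureSpec, ...] = tuple(
    _specs("graph", False, [
        "n_nodes", "n_edges", "density", "n_components",
        "total_triangle_number", "transitivity", "maximal_clique_count",
        "average_clustering",
    ])
    + _specs("graph", True, [
        "diameter", "radius", "periphery_size",
        "graph_energy",
        "graph_spectrum_max", "graph_spectrum_min", "graph_spectrum_mean",
        "graph_spectrum_std", "graph_spectrum_skewness",
        "graph_spectrum_kurtosis", "graph_spectrum_gap",
        "laplacian_spectrum_max", "laplacian_spectrum_min",
        "laplacian_spectrum_mean", "laplacian_spectrum_std",
        "laplacian_spectrum_skewness", "laplacian_spectrum_kurtosis",
        "laplacian_energy", "algebraic_connectivity",
    ])
    + _specs("graph", False, ["wl_signature"])
    + _specs("node", False, [
        "degree_centrality_max", "degree_centrality_min", "degree_centrality_median",
    ])
    + _specs("node", True, [
        "closeness_centrality_max", "closeness_centrality_min", "closeness_centrality_median",
        "betweenness_centrality_max", "betweenness_centrality_min", "betweenness_centrality_median",
        "eigenvector_centrality_max", "eigenvector_centrality_min", "eigenvector_centrality_median",
        "total_eigenvector_centrality",
        "harmonic_centrality_max", "harmonic_centrality_min", "harmonic_centrality_median",
        "component_eccentricity", "eccentricity_min", "eccentricity_median",
    ])
    + _specs("edge", True, [
        "flow_centrality_max", "flow_centrality_min", "flow_centrality_mean",
        "flow_centrality_median", "flow_centrality_std",
        "total_log_flow_centrality",
        "edge_flow_centrality_max", "edge_flow_centrality_min", "edge_flow_centrality_median",
        "flow_closeness_max", "flow_closeness_min", "flow_closeness_median",
    ])
    + _specs("edge", False, ["degree_assortativity", "degree_strength_correlation"])
    + _specs("edge", True, [
        "edge_weight_max", "edge_weight_min", "edge_weight_mean",
        "edge_weight_std", "edge_weight_sum",
    ])
)

GRAPH_FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in MANIFEST)
assert len(GRAPH_FEATURE_NAMES) == 66 and len(set(GRAPH_FEATURE_NAMES)) == 66

_CATEGORY_NAMES = {
    cat: tuple(s.name for s in MANIFEST if s.category == cat)
    for cat in ("graph", "node", "edge")
}


def manifest_json(indent: int = 1) -> str:
    """The manifest serialized as JSON (ordered names + metadata)."""
    return json.dumps(
        [
            {"name": s.name, "category": s.category, "weighted": s.weighted,
             "sentinel": s.sentinel}
            for s in MANIFEST
        ],
        indent=indent,
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _largest_component(g: nx.Graph) -> nx.Graph:
    if g.number_of_nodes() == 0:
        return g
    # deterministic tie-break: largest size, then smallest minimum node key
    comp = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    return g.subgraph(comp)


def _stat_block(values: Iterable[float], prefix: str,
                which: tuple[str, ...] = ("max", "min", "median")) -> dict[str, float]:
    arr = np.asarray(list(values), dtype=float)
    out = {}
    fns = {"max": np.max, "min": np.min, "median": np.median,
           "mean": np.mean, "std": np.std}
    for w in which:
        out[f"{prefix}_{w}"] = float(fns[w](arr)) if arr.size else 0.0
    return out


def _finite(x: float) -> float:
    return float(x) if np.isfinite(x) else 0.0


# ---------------------------------------------------------------------------
# feature groups
# ---------------------------------------------------------------------------

def spectrum_stats(matrix: np.ndarray, prefix: str, gap_mode: str = "top") -> dict[str, float]:
    """Summary statistics of the eigenvalue spectrum of a symmetric matrix.

    Emits max, min, mean, std, skewness, kurtosis, energy (sum of absolute
    eigenvalues), and a spectral gap: the difference between the two largest
    eigenvalues (``gap_mode="top"``, adjacency convention) or the
    second-smallest eigenvalue (``gap_mode="fiedler"``, Laplacian algebraic
    connectivity).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        lam = np.array([0.0])
    else:
        lam = np.linalg.eigvalsh(matrix)
    lam = np.sort(lam)
    out = {
        f"{prefix}_max": float(lam[-1]),
        f"{prefix}_min": float(lam[0]),
        f"{prefix}_mean": float(np.mean(lam)),
        f"{prefix}_std": float(np.std(lam)),
        f"{prefix}_skewness": _finite(stats.skew(lam)) if lam.size > 1 else 0.0,
        f"{prefix}_kurtosis": _finite(stats.kurtosis(lam)) if lam.size > 1 else 0.0,
        f"{prefix}_energy": float(np.sum(np.abs(lam))),
    }
    if gap_mode == "top":
        out[f"{prefix}_gap"] = float(lam[-1] - lam[-2]) if lam.size > 1 else 0.0
    elif gap_mode == "fiedler":
        out[f"{prefix}_gap"] = float(lam[1]) if lam.size > 1 else 0.0
    else:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    return out


def graph_level_features(g: EdaGraph) -> dict[str, float]:
    """Global structure summaries; distance metrics on the largest component."""
    G = g.graph
    n = G.number_of_nodes()
    out: dict[str, float] = {
        "n_nodes": float(n),
        "n_edges": float(G.number_of_edges()),
        "density": float(nx.density(G)) if n > 1 else 0.0,
        "n_components": float(nx.number_connected_components(G)) if n else 0.0,
    }
    tri = nx.triangles(G)
    out["total_triangle_number"] = float(sum(tri.values()) // 3)
    out["transitivity"] = float(nx.transitivity(G))
    out["maximal_clique_count"] = float(sum(1 for _ in nx.find_cliques(G))) if n else 0.0
    out["average_clustering"] = float(nx.average_clustering(G)) if n else 0.0

    lcc = _largest_component(G)
    if lcc.number_of_nodes() > 1:
        ecc = nx.eccentricity(lcc, weight="distance")
        vals = np.array(list(ecc.values()))
        out["diameter"] = float(vals.max())
        out["radius"] = float(vals.min())
        out["periphery_size"] = float(np.sum(np.isclose(vals, vals.max())))
    else:
        out["diameter"] = out["radius"] = 0.0
        out["periphery_size"] = float(min(1, lcc.number_of_nodes()))

    adj = spectrum_stats(g.A, "graph_spectrum", gap_mode="top")
    out["graph_energy"] = adj.pop("graph_spectrum_energy")
    out.update(adj)
    lap = spectrum_stats(g.L, "laplacian_spectrum", gap_mode="fiedler")
    out["laplacian_energy"] = lap.pop("laplacian_spectrum_energy")
    out["algebraic_connectivity"] = lap.pop("laplacian_spectrum_gap")
    out.update(lap)
    out["wl_signature"] = wl_signature(g)
    return {k: out[k] for k in _CATEGORY_NAMES["graph"]}


def node_level_features(g: EdaGraph) -> dict[str, float]:
    """Centrality summaries (max / min / median over nodes)."""
    G = g.graph
    n = G.number_of_nodes()
    out: dict[str, float] = {}
    if n <= 1:
        # single-node sentinel: no pairwise structure, all centralities 0
        return {name: 0.0 for name in _CATEGORY_NAMES["node"]}
    out.update(_stat_block(nx.degree_centrality(G).values(), "degree_centrality"))
    out.update(_stat_block(
        nx.closeness_centrality(G, distance="distance").values(), "closeness_centrality"))
    out.update(_stat_block(
        nx.betweenness_centrality(G, weight="distance", normalized=True).values(),
        "betweenness_centrality"))

    lcc = _largest_component(G)
    eig = {v: 0.0 for v in G.nodes}
    if lcc.number_of_nodes() > 1:
        # dense symmetric eigendecomposition of the weighted adjacency of
        # the largest component; Perron vector is simple on a connected
        # graph, reported with unit L2 norm and non-negative entries
        sub_nodes = sorted(lcc.nodes)
        S = nx.to_numpy_array(lcc, nodelist=sub_nodes, weight="weight")
        _, vecs = np.linalg.eigh(S)
        principal = np.abs(vecs[:, -1])
        eig.update(dict(zip(sub_nodes, principal)))
    out.update(_stat_block(eig.values(), "eigenvector_centrality"))
    out["total_eigenvector_centrality"] = float(sum(eig.values()))

    out.update(_stat_block(
        nx.harmonic_centrality(G, distance="distance").values(), "harmonic_centrality"))

    if lcc.number_of_nodes() > 1:
        ecc = np.array(list(nx.eccentricity(lcc, weight="distance").values()))
        out["component_eccentricity"] = float(ecc.max())
        out["eccentricity_min"] = float(ecc.min())
        out["eccentricity_median"] = float(np.median(ecc))
    else:
        out["component_eccentricity"] = out["eccentricity_min"] = out["eccentricity_median"] = 0.0
    return {k: out[k] for k in _CATEGORY_NAMES["node"]}


def edge_level_features(g: EdaGraph) -> dict[str, float]:
    """Flow centralities, assortativity, and edge-weight statistics.

    Current-flow metrics require a connected graph and are computed on the
    largest component with edge weights acting as conductances.
    """
    G = g.graph
    out: dict[str, float] = {}
    lcc = _largest_component(G)
    flow_stats = ("max", "min", "mean", "median", "std")
    if lcc.number_of_nodes() > 1:
        # normalization constant (n-1)(n-2) vanishes for 2-node components;
        # fall back to unnormalized values there (node flow is 0 regardless)
        norm = lcc.number_of_nodes() > 2
        flow = nx.current_flow_betweenness_centrality(lcc, weight="weight", normalized=norm)
        out.update(_stat_block(flow.values(), "flow_centrality", flow_stats))
        out["total_log_flow_centrality"] = float(
            np.sum(np.log1p(np.asarray(list(flow.values())))))
        eflow = nx.edge_current_flow_betweenness_centrality(
            lcc, weight="weight", normalized=norm)
        out.update(_stat_block(eflow.values(), "edge_flow_centrality"))
        fclose = nx.current_flow_closeness_centrality(lcc, weight="weight")
        out.update(_stat_block(fclose.values(), "flow_closeness"))
    else:
        out.update(_stat_block([], "flow_centrality", flow_stats))
        out["total_log_flow_centrality"] = 0.0
        out.update(_stat_block([], "edge_flow_centrality"))
        out.update(_stat_block([], "flow_closeness"))

    if G.number_of_edges() > 0:
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = nx.degree_assortativity_coefficient(G)
        except (ValueError, ZeroDivisionError):
            r = np.nan
        out["degree_assortativity"] = _finite(r)
        deg = np.array([d for _, d in G.degree()], dtype=float)
        strength = np.array([d for _, d in G.degree(weight="weight")], dtype=float)
        if deg.size > 1 and np.std(deg) > 0 and np.std(strength) > 0:
            out["degree_strength_correlation"] = float(np.corrcoef(deg, strength)[0, 1])
        else:
            out["degree_strength_correlation"] = 0.0
        w = np.array([d["weight"] for _, _, d in G.edges(data=True)])
        out["edge_weight_max"] = float(w.max())
        out["edge_weight_min"] = float(w.min())
        out["edge_weight_mean"] = float(w.mean())
        out["edge_weight_std"] = float(w.std())
        out["edge_weight_sum"] = float(w.sum())
    else:
        out["degree_assortativity"] = 0.0
        out["degree_strength_correlation"] = 0.0
        for s in ("max", "min", "mean", "std", "sum"):
            out[f"edge_weight_{s}"] = 0.0
    return {k: out[k] for k in _CATEGORY_NAMES["edge"]}


def wl_signature(g: EdaGraph, iterations: int = 2) -> float:
    """Structural-diversity scalar from Weisfeiler-Lehman label refinement.

    Nodes start with degree labels; each iteration rehashes a node's label
    together with the sorted multiset of its neighbors' labels. The
    signature is the number of distinct labels after the final iteration
    divided by the node count: 1/n for vertex-transitive graphs, approaching
    1 as structure diversifies. A single-node graph scores 1.
    """
    G = g.graph
    n = G.number_of_nodes()
    if n == 0:
        return 0.0
    labels = {v: str(d) for v, d in G.degree()}
    for _ in range(iterations):
        new = {}
        for v in G.nodes:
            neigh = sorted(labels[u] for u in G.neighbors(v))
            new[v] = labels[v] + "|" + ",".join(neigh)
        canon = {lab: str(i) for i, lab in enumerate(sorted(set(new.values())))}
        labels = {v: canon[lab] for v, lab in new.items()}
    return len(set(labels.values())) / n


def edagraph_feature_vector(g: EdaGraph) -> dict[str, float]:
    """All 66 features in manifest order; a pure function of the graph."""
    out: dict[str, float] = {}
    out.update(graph_level_features(g))
    out.update(node_level_features(g))
    out.update(edge_level_features(g))
    assert tuple(out) == GRAPH_FEATURE_NAMES
    return out
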