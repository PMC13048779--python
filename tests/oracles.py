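"""Independent brute-force reference implementations for small graphs.

Everything here works from the dense weighted adjacency matrix using direct
definitions: Floyd-Warshall distances, exhaustive simple-path enumeration
for betweenness, power iteration for eigenvector centrality, subset
enumeration for cliques, and Laplacian-pseudoinverse electrical flows.
Intended for graphs of at most ~8 nodes, where exhaustive enumeration is
cheap. These deliberately avoid the library code paths they are used to
check.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


def distance_matrix(A: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by Floyd-Warshall; ``lengths[i, j]``
    is the edge length where ``A[i, j] > 0``."""
    n = A.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if A[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def components(A: np.ndarray) -> list[set[int]]:
    n = A.shape[0]
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(j for j in range(n) if A[v, j] > 0 and j not in comp)
        comps.append(comp)
        seen |= comp
    return comps


def degree_centrality(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    deg = (A > 0).sum(axis=1)
    return deg / (n - 1) if n > 1 else np.zeros(n)


def closeness_centrality(A: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Wasserman-Faust-scaled closeness over reachable nodes (the networkx
    default convention)."""
    n = A.shape[0]
    d = distance_matrix(A, lengths)
    out = np.zeros(n)
    for v in range(n):
        reach = [u for u in range(n) if u != v and d[v, u] < INF]
        if not reach:
            continue
        total = sum(d[v, u] for u in reach)
        r = len(reach)
        out[v] = (r / total) * (r / (n - 1)) if total > 0 else 0.0
    return out


def harmonic_centrality(A: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    d = distance_matrix(A, lengths)
    return np.array([
        sum(1.0 / d[v, u] for u in range(n) if u != v and 0 < d[v, u] < INF)
        for v in range(n)
    ])


def _all_simple_paths(A: np.ndarray, s: int, t: int) -> list[list[int]]:
    n = A.shape[0]
    paths: list[list[int]] = []

    def dfs(v: int, path: list[int]) -> None:
        if v == t:
            paths.append(path[:])
            return
        for u in range(n):
            if A[v, u] > 0 and u not in path:
                path.append(u)
                dfs(u, path)
                path.pop()

    dfs(s, [s])
    return paths


def betweenness_centrality(A: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Normalized shortest-path betweenness by exhaustive path enumeration.

    Edge lengths must be dyadic rationals so that path-length sums are exact
    in binary floating point and tie detection is order-independent.
    """
    n = A.shape[0]
    raw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_simple_paths(A, s, t)
        if not paths:
            continue
        plens = [sum(lengths[u, v] for u, v in zip(p[:-1], p[1:])) for p in paths]
        dmin = min(plens)
        shortest = [p for p, pl in zip(paths, plens) if pl == dmin]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                raw[v] += 1.0 / sigma
    if n > 2:
        raw *= 2.0 / ((n - 1) * (n - 2))
    return raw


def eigenvector_centrality(A: np.ndarray, iters: int = 20_000, tol: float = 1e-14) -> np.ndarray:
    """Power iteration on the shifted weighted adjacency A + cI (same
    eigenvectors; the shift makes the Perron root strictly dominant even on
    bipartite graphs), L2-normalized, absolute scores. Assumes a connected
    graph with at least one edge."""
    n = A.shape[0]
    M = A + (A.sum(axis=1).max() + 1.0) * np.eye(n)
    x = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        y = M @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return np.zeros(n)
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    return np.abs(x)


def spectrum(M: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric matrix via the general (non-symmetric)
    solver — an independent numerical route from ``eigvalsh``."""
    return np.sort(np.linalg.eig(M).eigenvalues.real)


def triangle_count(A: np.ndarray) -> int:
    n = A.shape[0]
    return sum(
        1
        for i, j, k in itertools.combinations(range(n), 3)
        if A[i, j] > 0 and A[j, k] > 0 and A[i, k] > 0
    )


def transitivity(A: np.ndarray) -> float:
    """3 * triangles / open-plus-closed triads (paths of length two)."""
    n = A.shape[0]
    triads = 0
    for v in range(n):
        deg = int((A[v] > 0).sum())
        triads += deg * (deg - 1) // 2
    return 3.0 * triangle_count(A) / triads if triads else 0.0


def maximal_clique_count(A: np.ndarray) -> int:
    n = A.shape[0]
    cliques = []
    for r in range(1, n + 1):
        for sub in itertools.combinations(range(n), r):
            if all(A[i, j] > 0 for i, j in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return sum(
        1 for c in cliques
        if not any(c < other for other in cliques)
    )


def degree_assortativity(A: np.ndarray) -> float:
    """Pearson correlation over directed edge-end degree pairs."""
    deg = (A > 0).sum(axis=1)
    xs, ys = [], []
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if A[i, j] > 0:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs or np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def graph_energy(A: np.ndarray) -> float:
    return float(np.sum(np.abs(spectrum(A))))


def current_flow_betweenness(A: np.ndarray) -> np.ndarray:
    """Electrical (random-walk) node betweenness from the Laplacian
    pseudoinverse, normalized as 2/((n-1)(n-2)) over interior throughflow;
    for n = 2 the unnormalized interior value (zero) is returned."""
    n = A.shape[0]
    L = np.diag(A.sum(1)) - A
    Lp = np.linalg.pinv(L)
    raw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        b = np.zeros(n)
        b[s], b[t] = 1.0, -1.0
        V = Lp @ b
        for i in range(n):
            if i not in (s, t):
                raw[i] += 0.5 * sum(A[i, j] * abs(V[i] - V[j]) for j in range(n))
    if n > 2:
        raw *= 2.0 / ((n - 1) * (n - 2))
    return raw


def current_flow_closeness(A: np.ndarray) -> np.ndarray:
    """Reciprocal of total effective resistance to all other nodes."""
    n = A.shape[0]
    L = np.diag(A.sum(1)) - A
    Lp = np.linalg.pinv(L)
    out = np.zeros(n)
    for v in range(n):
        er = sum(Lp[v, v] + Lp[t, t] - 2 * Lp[v, t] for t in range(n) if t != v)
        out[v] = 1.0 / er if er > 0 else 0.0
    return out
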