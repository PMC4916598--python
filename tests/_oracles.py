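"""Independent brute-force oracles used to validate library implementations.

Deliberately naive: triangle enumeration, Floyd-Warshall shortest paths,
subdivision-based planarity on <= 6 nodes, and parametric segment
intersection. None of them share code with the package.
"""

import itertools

import numpy as np


def brute_clustering(adj: np.ndarray) -> float:
    """Mean local clustering by explicit triangle counting."""
    a = (np.asarray(adj) > 0).astype(int)
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        d = len(nbrs)
        if d < 2:
            continue
        tri = 0
        for i in range(d):
            for j in range(i + 1, d):
                tri += a[nbrs[i], nbrs[j]]
        total += tri / (d * (d - 1) / 2)
    return total / n


def brute_path_length(adj: np.ndarray) -> tuple[float, float]:
    """(L, coverage) on the largest component via Floyd-Warshall."""
    a = (np.asarray(adj) > 0)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    # largest component by reachability
    comps = []
    seen = set()
    for v in range(n):
        if v in seen:
            continue
        comp = set(np.flatnonzero(np.isfinite(dist[v])))
        comps.append(sorted(comp))
        seen |= comp
    comp = max(comps, key=len)
    idx = np.asarray(comp)
    sub = dist[np.ix_(idx, idx)]
    m = len(idx)
    total = sub[~np.eye(m, dtype=bool)].sum()
    return total / (m * (m - 1)), m / n


def _k33_subgraph(a: np.ndarray) -> bool:
    n = a.shape[0]
    if n < 6:
        return False
    for six in itertools.combinations(range(n), 6):
        for left in itertools.combinations(six, 3):
            right = tuple(v for v in six if v not in left)
            if all(a[u, v] for u in left for v in right):
                return True
    return False


def _k5_subdivision(a: np.ndarray) -> bool:
    n = a.shape[0]
    for five in itertools.combinations(range(n), 5):
        pairs = list(itertools.combinations(five, 2))
        missing = [p for p in pairs if not a[p]]
        if not missing:
            return True
        if len(missing) == 1 and n >= 6:
            u, v = missing[0]
            for w in range(n):
                if w not in five and a[u, w] and a[v, w]:
                    return True
    return False


def brute_planar(adj: np.ndarray) -> bool:
    """Planarity for graphs on <= 6 nodes via Kuratowski subdivisions.

    On <= 6 vertices a graph is non-planar iff it contains a K3,3 subgraph
    or a K5 subdivision (which, with at most one spare vertex, is K5 itself
    or K5 with exactly one edge subdivided).
    """
    a = (np.asarray(adj) > 0)
    a = (a | a.T)
    if a.shape[0] > 6:
        raise ValueError("oracle limited to <= 6 nodes")
    return not (_k33_subgraph(a) or _k5_subdivision(a))


def segment_crossings(segments: list[tuple[np.ndarray, np.ndarray]],
                      tol: float = 1e-9) -> list[np.ndarray]:
    """Pairwise interior intersection points of straight segments."""
    pts = []
    for (p0, p1), (q0, q1) in itertools.combinations(segments, 2):
        r, s = p1 - p0, q1 - q0
        denom = r[0] * s[1] - r[1] * s[0]
        if abs(denom) < 1e-12:
            continue
        d = q0 - p0
        t = (d[0] * s[1] - d[1] * s[0]) / denom
        u = (d[0] * r[1] - d[1] * r[0]) / denom
        if tol < t < 1 - tol and tol < u < 1 - tol:
            pts.append(p0 + t * r)
    return pts
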