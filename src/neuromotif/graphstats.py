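"""Small-world graph statistics with explicit null-model ensembles.

For an undirected functional network the module reports the degree
distribution, raw clustering coefficient C and characteristic path length
L, and their null-normalized forms

    sigma = C / <C_rand>,   lambda = L / <L_rand>,   small_world = sigma/lambda,

where the null averages come from an ensemble of either degree-preserving
rewirings (Maslov-Sneppen double-edge swaps, the default, appropriate for
heavy-tailed degree sequences) or Erdős-Rényi graphs with the same node
and edge counts.  small_world > 1 indicates simultaneous high clustering
and short paths.  Disconnected graphs are handled by computing L on the
largest connected component and reporting the component coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from neuromotif._errors import ValidationError

__all__ = [
    "GraphMetrics", "degree_distribution", "clustering_coefficient",
    "characteristic_path_length", "small_world_metrics",
]


@dataclass
class GraphMetrics:
    """Raw and null-normalized network statistics."""

    n_nodes: int
    n_edges: int
    degree_histogram: dict[int, int]
    degree_loglog_slope: float
    clustering: float
    path_length: float
    component_coverage: float
    c_rand_mean: float
    c_rand_sd: float
    l_rand_mean: float
    l_rand_sd: float
    sigma: float
    lam: float
    small_world: float
    n_null: int
    null_method: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degree_histogram"] = {int(k): int(v)
                                 for k, v in d["degree_histogram"].items()}
        return d


def _as_graph(adjacency) -> nx.Graph:
    if isinstance(adjacency, nx.Graph):
        return nx.Graph(adjacency)
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValidationError(
            "adjacency must be symmetric; symmetrize explicitly upstream")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    return nx.from_numpy_array((a > 0).astype(int))


def degree_distribution(adjacency) -> tuple[dict[int, int], float]:
    """Undirected degree histogram plus a descriptive log-log slope.

    Returns ``(histogram, slope)`` where histogram maps degree → node
    count and slope is the least-squares slope of log(count) vs
    log(degree) over nonzero bins with degree ≥ 1 (NaN with fewer than two
    such bins).  The slope is a descriptive scale-free check, not a fitted
    power-law exponent.
    """
    g = _as_graph(adjacency)
    degrees = [d for _, d in g.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    pts = [(d, c) for d, c in sorted(hist.items()) if d >= 1 and c > 0]
    if len(pts) >= 2:
        logs = np.log(np.asarray(pts, dtype=float))
        slope = float(np.polyfit(logs[:, 0], logs[:, 1], 1)[0])
    else:
        slope = float("nan")
    return hist, slope


def clustering_coefficient(adjacency) -> float:
    """Mean local clustering coefficient.

    Per node: triangles through the node divided by pairs of neighbours;
    nodes of degree < 2 contribute 0.  Empty graphs return 0 with a
    warning.
    """
    g = _as_graph(adjacency)
    if g.number_of_nodes() == 0:
        warnings.warn("empty graph: clustering is 0", stacklevel=2)
        return 0.0
    return float(nx.average_clustering(g, count_zeros=True))


def characteristic_path_length(adjacency) -> tuple[float, float]:
    """Mean shortest-path length on the largest connected component.

    Returns ``(L, coverage)`` where coverage is the fraction of nodes in
    the largest component.  An edgeless graph has no defined L and raises
    a validation error.
    """
    g = _as_graph(adjacency)
    if g.number_of_edges() == 0:
        raise ValidationError("path length undefined on an edgeless graph")
    comp = max(nx.connected_components(g), key=len)
    coverage = len(comp) / g.number_of_nodes()
    sub = g.subgraph(comp)
    return float(nx.average_shortest_path_length(sub)), float(coverage)


def _double_edge_swap_null(g: nx.Graph, rng: np.random.Generator,
                           n_swaps: int) -> nx.Graph:
    """Degree-preserving null by Maslov-Sneppen double-edge swaps.

    Attempts up to 100× the target number of successful swaps; graphs where
    fewer swaps are possible (e.g. complete graphs admit none) are returned
    with as many as could be performed, which still preserves every degree.
    """
    h = nx.Graph(g)
    edges = list(h.edges())
    if len(edges) < 2:
        return h
    successes = 0
    attempts = 0
    max_attempts = 100 * max(n_swaps, 1)
    while successes < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(len(edges)), rng.integers(len(edges))
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if len({a, b, c, d}) < 4:
            continue
        # swap to (a, d), (c, b)
        if h.has_edge(a, d) or h.has_edge(c, b):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(a, d)
        h.add_edge(c, b)
        edges[i], edges[j] = (a, d), (c, b)
        successes += 1
    return h


def small_world_metrics(adjacency,
                        n_null: int = 20,
                        null_method: str = "degree_preserving_rewire",
                        seed: int = 0) -> GraphMetrics:
    """Null-normalized clustering, path length and small-world index.

    ``null_method`` is ``"degree_preserving_rewire"`` (Maslov-Sneppen,
    10×|E| successful swaps per sample) or ``"erdos_renyi"`` (same node and
    edge count).  sigma = C/<C_rand>, lambda = L/<L_rand>,
    small_world = sigma/lambda.  sigma is undefined (NaN, with a warning)
    when the null ensemble has no triangles.
    """
    if n_null < 10:
        raise ValidationError("n_null must be >= 10")
    if null_method not in ("degree_preserving_rewire", "erdos_renyi"):
        raise ValidationError(f"unknown null method {null_method!r}")
    g = _as_graph(adjacency)
    if g.number_of_edges() < 1:
        raise ValidationError("small_world_metrics needs >= 1 edge")

    hist, slope = degree_distribution(nx.to_numpy_array(g).astype(int))
    c_raw = clustering_coefficient(nx.to_numpy_array(g).astype(int))
    l_raw, coverage = characteristic_path_length(
        nx.to_numpy_array(g).astype(int))

    rng = np.random.default_rng(seed)
    n, m = g.number_of_nodes(), g.number_of_edges()
    c_null, l_null = [], []
    for _ in range(n_null):
        if null_method == "degree_preserving_rewire":
            h = _double_edge_swap_null(g, rng, n_swaps=10 * m)
        else:
            h = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        c_null.append(nx.average_clustering(h, count_zeros=True))
        if h.number_of_edges():
            comp = max(nx.connected_components(h), key=len)
            if len(comp) > 1:
                l_null.append(
                    nx.average_shortest_path_length(h.subgraph(comp)))

    c_mean = float(np.mean(c_null))
    c_sd = float(np.std(c_null))
    l_mean = float(np.mean(l_null)) if l_null else float("nan")
    l_sd = float(np.std(l_null)) if l_null else float("nan")
    if c_mean == 0:
        warnings.warn("null ensemble has no triangles: sigma undefined",
                      stacklevel=2)
        sigma = float("nan")
    else:
        sigma = c_raw / c_mean
    lam = l_raw / l_mean if l_mean and not np.isnan(l_mean) else float("nan")
    sw = sigma / lam if lam and not np.isnan(sigma) and not np.isnan(lam) \
        else float("nan")
    return GraphMetrics(
        n_nodes=n, n_edges=m, degree_histogram=hist,
        degree_loglog_slope=slope, clustering=c_raw, path_length=l_raw,
        component_coverage=coverage, c_rand_mean=c_mean, c_rand_sd=c_sd,
        l_rand_mean=l_mean, l_rand_sd=l_sd, sigma=sigma, lam=lam,
        small_world=sw, n_null=n_null, null_method=null_method)
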