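"""Population-level structural networks with geometry.

A structural network describes which neuronal populations (the nodes of a
motif, each one a reservoir of somas on a chip) project neurites to which
others.  Nodes carry fixed 2D coordinates; each directed edge carries a
polyline realizing the neurite channel in the plane.  The module provides

* a catalogue of small "basic brain motif" topologies (3-4 nodes),
* the bridge-device adjacency matrices with and without the guiding field,
* geometric crossing detection and decomposition of concurrent crossings
  into pairwise ones,
* graph planarity with Kuratowski witnesses, and
* comparison of structural and functional population adjacency.

Adjacency convention: ``adjacency[i, j] == 1`` means population *i*
projects neurites to population *j* (row = source).  A bidirectional
connection sets both entries.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from neuromotif._errors import CatalogueError, ValidationError

__all__ = [
    "StructuralLayout", "MotifSpec", "CrossingReport",
    "StructureFunctionAgreement", "MOTIF_IDS", "get_motif",
    "bridge_adjacency", "compute_crossings", "is_planar",
    "decompose_crossings", "compare_structure_function",
    "layout_to_json", "layout_from_json", "layout_to_graphml",
    "layout_to_edgelist_csv",
]

DEFAULT_TOLERANCE_UM = 1e-6


# ---------------------------------------------------------------------------
# types


@dataclass
class StructuralLayout:
    """Populations as nodes with 2D coordinates plus directed adjacency.

    Parameters
    ----------
    population_labels
        Text label per population.
    positions
        ``(n, 2)`` array of node coordinates in μm.
    adjacency
        ``(n, n)`` 0/1 matrix, ``adjacency[i, j] == 1`` meaning population
        ``i`` projects neurites to population ``j``.  Zero diagonal.
    edge_geometry
        Mapping ``(i, j) -> (m, 2)`` polyline for every directed edge.
        Defaults to the straight segment between the node positions.
    """

    population_labels: list[str]
    positions: np.ndarray
    adjacency: np.ndarray
    edge_geometry: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        n = len(self.population_labels)
        if self.positions.shape != (n, 2):
            raise ValidationError(
                f"positions must be ({n}, 2), got {self.positions.shape}")
        if self.adjacency.shape != (n, n):
            raise ValidationError(
                f"adjacency must be ({n}, {n}), got {self.adjacency.shape}")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        # fill in default straight-segment geometry and check endpoints
        for i, j in zip(*np.nonzero(self.adjacency)):
            key = (int(i), int(j))
            if key not in self.edge_geometry:
                self.edge_geometry[key] = np.array(
                    [self.positions[i], self.positions[j]])
            poly = np.asarray(self.edge_geometry[key], dtype=float)
            if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
                raise ValidationError(f"edge {key}: polyline must be (m>=2, 2)")
            if (np.linalg.norm(poly[0] - self.positions[i]) > 1e-9
                    or np.linalg.norm(poly[-1] - self.positions[j]) > 1e-9):
                raise ValidationError(
                    f"edge {key}: polyline endpoints must equal node positions")
            self.edge_geometry[key] = poly

    @property
    def n_populations(self) -> int:
        return len(self.population_labels)

    def directed_edges(self) -> list[tuple[int, int]]:
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(self.adjacency))]

    def undirected_edges(self) -> list[tuple[int, int]]:
        """Unordered node pairs with at least one directed edge, i < j."""
        sym = self.adjacency | self.adjacency.T
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(sym, 1)))]

    def undirected_edge_geometry(self, i: int, j: int) -> np.ndarray:
        """Polyline of the undirected edge {i, j} (the i->j one if both exist)."""
        if (i, j) in self.edge_geometry:
            return self.edge_geometry[(i, j)]
        return self.edge_geometry[(j, i)]

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for k, label in enumerate(self.population_labels):
            g.add_node(k, label=label,
                       x_um=float(self.positions[k, 0]),
                       y_um=float(self.positions[k, 1]))
        g.add_edges_from(self.directed_edges())
        return g


@dataclass(frozen=True)
class MotifSpec:
    """Catalogue entry for a basic brain motif.

    ``edges`` lists ``(source, target, directionality)`` with
    directionality in {"unidirectional", "bidirectional"}.
    """

    motif_id: str
    n_nodes: int
    edges: tuple[tuple[int, int, str], ...]
    has_crossing: bool


@dataclass
class CrossingReport:
    """Geometric crossings of edge polylines.

    ``crossing_points`` holds ``(xy, edges)`` pairs: a crossing coordinate
    and the set of directed edges whose geometry passes through it.
    """

    crossing_points: list[tuple[np.ndarray, frozenset[tuple[int, int]]]]

    @property
    def n_crossings(self) -> int:
        return len(self.crossing_points)

    @property
    def max_multiplicity(self) -> int:
        if not self.crossing_points:
            return 0
        return max(self._undirected_multiplicity(edges)
                   for _, edges in self.crossing_points)

    @staticmethod
    def _undirected_multiplicity(edges: frozenset[tuple[int, int]]) -> int:
        return len({frozenset(e) for e in edges})

    def multiplicities(self) -> list[int]:
        return [self._undirected_multiplicity(edges)
                for _, edges in self.crossing_points]


@dataclass
class StructureFunctionAgreement:
    """Partition of undirected population edges into shared / exclusive sets."""

    structural_edges: set[frozenset[int]]
    functional_edges: set[frozenset[int]]
    shared: set[frozenset[int]]
    functional_only: set[frozenset[int]]
    structural_only: set[frozenset[int]]
    jaccard: float


# ---------------------------------------------------------------------------
# motif catalogue
#
# The catalogue encodes the directionality classes of the published motif
# gallery: three-node motifs are fully bidirectional; four-node motifs are
# unidirectional (A2, A4), bidirectional (A3, B2, A5, B4, B3) or
# intersecting (B5).  Exact arrow-by-arrow assignments within a class are
# not recoverable from the available material; the shipped edge lists below
# are documented defaults under a fixed node numbering (counter-clockwise
# from the lower-left corner for squares) and can be overridden from JSON.

_BI = "bidirectional"
_UNI = "unidirectional"

_CATALOGUE: dict[str, MotifSpec] = {
    # three-node motifs: all connections bidirectional
    "A1": MotifSpec("A1", 3, ((0, 1, _BI), (1, 2, _BI), (0, 2, _BI)), False),
    "B1": MotifSpec("B1", 3, ((0, 1, _BI), (1, 2, _BI)), False),
    # four-node, unidirectional (neurite diodes)
    "A2": MotifSpec("A2", 4, ((0, 1, _UNI), (1, 2, _UNI), (2, 3, _UNI),
                              (3, 0, _UNI)), False),
    "A4": MotifSpec("A4", 4, ((0, 1, _UNI), (1, 2, _UNI), (2, 3, _UNI)), False),
    # four-node, bidirectional
    "A3": MotifSpec("A3", 4, ((0, 1, _BI), (1, 2, _BI), (2, 3, _BI),
                              (3, 0, _BI)), False),
    "B2": MotifSpec("B2", 4, ((0, 1, _BI), (1, 2, _BI), (2, 3, _BI)), False),
    "A5": MotifSpec("A5", 4, ((0, 1, _BI), (0, 2, _BI), (0, 3, _BI)), False),
    "B3": MotifSpec("B3", 4, ((0, 1, _BI), (1, 2, _BI), (1, 3, _BI)), False),
    "B4": MotifSpec("B4", 4, ((0, 1, _BI), (1, 2, _BI), (2, 3, _BI),
                              (3, 0, _BI), (0, 2, _BI)), False),
    # four-node, intersecting: the two diagonals of the square cross and are
    # realized physically as a neurite bridge
    "B5": MotifSpec("B5", 4, ((0, 2, _BI), (1, 3, _BI)), True),
}

MOTIF_IDS: tuple[str, ...] = tuple(_CATALOGUE)

_SIDE_UM = 1000.0


def _default_positions(n_nodes: int) -> np.ndarray:
    """Equilateral triangle (3 nodes) or square (4 nodes), side 1000 μm."""
    if n_nodes == 3:
        h = _SIDE_UM * math.sqrt(3.0) / 2.0
        return np.array([[0.0, 0.0], [_SIDE_UM, 0.0], [_SIDE_UM / 2.0, h]])
    if n_nodes == 4:
        return np.array([[0.0, 0.0], [_SIDE_UM, 0.0],
                         [_SIDE_UM, _SIDE_UM], [0.0, _SIDE_UM]])
    raise ValidationError(f"unsupported motif size {n_nodes}")


def motif_spec(motif_id: str) -> MotifSpec:
    """Catalogue entry for ``motif_id``; raises CatalogueError if unknown."""
    try:
        return _CATALOGUE[motif_id]
    except KeyError:
        raise CatalogueError(
            f"unknown motif {motif_id!r}; valid ids: {', '.join(MOTIF_IDS)}"
        ) from None


def get_motif(motif_id: str) -> StructuralLayout:
    """Build the default geometric layout of a catalogue motif.

    Three-node motifs sit on an equilateral triangle of side 1000 μm,
    four-node ones on a square of side 1000 μm.  Bidirectional edges set
    both directed adjacency entries.
    """
    spec = motif_spec(motif_id)
    pos = _default_positions(spec.n_nodes)
    adj = np.zeros((spec.n_nodes, spec.n_nodes), dtype=int)
    for s, t, kind in spec.edges:
        adj[s, t] = 1
        if kind == _BI:
            adj[t, s] = 1
    labels = [f"P{k}" for k in range(spec.n_nodes)]
    return StructuralLayout(labels, pos, adj)


def bridge_adjacency(field_on: bool) -> StructuralLayout:
    """Adjacency of the four-population neurite-bridge device.

    With the guiding field off, neurites sprout into every channel and all
    four populations interconnect (12 directed edges).  With the field on,
    the neurite beams are focused and bridged, leaving exactly the two
    bidirectional diagonal pairs (4 directed edges) whose geometries cross
    once at the center.
    """
    pos = _default_positions(4)
    labels = ["P0", "P1", "P2", "P3"]
    adj = np.zeros((4, 4), dtype=int)
    if field_on:
        for i, j in ((0, 2), (1, 3)):
            adj[i, j] = adj[j, i] = 1
    else:
        adj[:] = 1
        np.fill_diagonal(adj, 0)
    return StructuralLayout(labels, pos, adj)


# ---------------------------------------------------------------------------
# geometric crossings


def _segment_intersection(p0, p1, q0, q1, tol):
    """Intersection point of segments [p0,p1], [q0,q1], or None.

    Parallel / collinear segments return None (overlaps are not discrete
    crossings).  Endpoint touches within tol count as intersections here;
    filtering of shared node endpoints happens in the caller.
    """
    r = p1 - p0
    s = q1 - q0
    denom = r[0] * s[1] - r[1] * s[0]
    scale = max(np.linalg.norm(r), np.linalg.norm(s), 1.0)
    if abs(denom) <= 1e-12 * scale * scale:
        return None
    d = q0 - p0
    t = (d[0] * s[1] - d[1] * s[0]) / denom
    u = (d[0] * r[1] - d[1] * r[0]) / denom
    # tolerance in parameter space relative to each segment's length
    tt = tol / max(np.linalg.norm(r), tol)
    tu = tol / max(np.linalg.norm(s), tol)
    if -tt <= t <= 1 + tt and -tu <= u <= 1 + tu:
        return p0 + t * r
    return None


def compute_crossings(layout: StructuralLayout,
                      tolerance: float = DEFAULT_TOLERANCE_UM) -> CrossingReport:
    """Find points where two or more distinct edge geometries cross.

    A crossing is a point interior to the polylines of at least two distinct
    undirected edges; shared terminal endpoints (node positions) are not
    crossings.  Points closer than ``tolerance`` are merged, accumulating
    multiplicity.

    Raises
    ------
    ValidationError
        If any edge polyline has a zero-length segment span.
    """
    # one representative polyline per undirected edge
    edges: dict[frozenset[int], tuple[tuple[int, int], np.ndarray]] = {}
    for (i, j), poly in layout.edge_geometry.items():
        if np.linalg.norm(poly[-1] - poly[0]) <= tolerance and len(poly) == 2:
            raise ValidationError(f"edge {(i, j)} has zero-length geometry")
        edges.setdefault(frozenset((i, j)), ((i, j), poly))

    hits: list[tuple[np.ndarray, tuple[int, int]]] = []
    keys = list(edges)
    for ka, kb in itertools.combinations(keys, 2):
        (ea, pa), (eb, pb) = edges[ka], edges[kb]
        ends_a = (pa[0], pa[-1])
        ends_b = (pb[0], pb[-1])
        for a0, a1 in zip(pa[:-1], pa[1:]):
            for b0, b1 in zip(pb[:-1], pb[1:]):
                pt = _segment_intersection(a0, a1, b0, b1, tolerance)
                if pt is None:
                    continue
                # exclude terminal endpoints of either polyline
                if any(np.linalg.norm(pt - e) <= tolerance
                       for e in (*ends_a, *ends_b)):
                    continue
                hits.append((pt, ea))
                hits.append((pt, eb))

    # merge coincident points
    clusters: list[tuple[np.ndarray, set[tuple[int, int]]]] = []
    for pt, edge in hits:
        for cpt, cedges in clusters:
            if np.linalg.norm(pt - cpt) <= max(tolerance, 1e-9):
                cedges.add(edge)
                break
        else:
            clusters.append((pt, {edge}))

    points = [(pt, frozenset(ed)) for pt, ed in clusters if len(ed) >= 2]
    return CrossingReport(points)


def decompose_crossings(layout: StructuralLayout,
                        tolerance: float = DEFAULT_TOLERANCE_UM
                        ) -> StructuralLayout:
    """Replace k-fold concurrent crossings by C(k, 2) pairwise ones.

    Any point where k > 2 edges concur is resolved by deterministically
    bending all but one of the participating edges around the point
    (perturbation radius 10 × tolerance, perpendicular to each edge's local
    direction), so each pair of edges crosses at its own point.  Adjacency
    and node positions are unchanged; layouts already at multiplicity ≤ 2
    are returned unchanged.
    """
    report = compute_crossings(layout, tolerance)
    multi = [(pt, edges) for pt, edges in report.crossing_points
             if CrossingReport._undirected_multiplicity(edges) > 2]
    if not multi:
        return layout

    delta = 10.0 * max(tolerance, 1e-9)
    geometry = {k: v.copy() for k, v in layout.edge_geometry.items()}
    near = 10 * max(tolerance, 1e-9)

    def locate(poly: np.ndarray, pt: np.ndarray):
        """Segment index and unit normal of the polyline segment through pt."""
        for k in range(len(poly) - 1):
            a, b = poly[k], poly[k + 1]
            seg = b - a
            ln = np.linalg.norm(seg)
            t = np.dot(pt - a, seg) / (ln * ln)
            if -1e-12 <= t <= 1 + 1e-12:
                proj = a + t * seg
                if np.linalg.norm(proj - pt) <= near:
                    return k, np.array([-seg[1], seg[0]]) / ln
        return None, None

    def insert(poly: np.ndarray, pt: np.ndarray, new_pt: np.ndarray
               ) -> np.ndarray:
        k, _ = locate(poly, pt)
        if k is None:
            return poly
        return np.vstack([poly[:k + 1], new_pt, poly[k + 1:]])

    for pt, edge_set in multi:
        # deterministic order; the first edge keeps its geometry
        undirected = sorted({tuple(sorted(e)) for e in edge_set})
        for m, (i, j) in enumerate(undirected[1:], start=1):
            rep = (i, j) if (i, j) in geometry else (j, i)
            _, normal = locate(geometry[rep], pt)
            if normal is None:
                continue
            new_pt = pt + m * delta * normal
            for key in ((i, j), (j, i)):
                if key in geometry:
                    geometry[key] = insert(geometry[key], pt, new_pt)

    return StructuralLayout(list(layout.population_labels),
                            layout.positions.copy(),
                            layout.adjacency.copy(),
                            geometry)


# ---------------------------------------------------------------------------
# planarity


def _classify_kuratowski(g: nx.Graph) -> str:
    """Classify a Kuratowski subgraph as a K5 or K3,3 subdivision."""
    branch = [v for v, d in g.degree() if d >= 3]
    degs = sorted(g.degree(v) for v in branch)
    if degs == [4] * 5:
        return "K5"
    if degs == [3] * 6:
        return "K3,3"
    # should not happen for a genuine Kuratowski subgraph
    return "unknown"


def is_planar(adjacency: np.ndarray,
              return_witness: bool = False):
    """Planarity of the symmetrized 0/1 adjacency matrix.

    Returns ``planar`` (bool), or ``(planar, witness, kind)`` when
    ``return_witness`` is true: ``witness`` is a subgraph homeomorphic to K5
    or K3,3 (``None`` when planar) and ``kind`` is ``"K5"`` / ``"K3,3"``.
    """
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValidationError("adjacency must be a square matrix")
    g = nx.from_numpy_array(((adjacency + adjacency.T) > 0).astype(int))
    planar, cert = nx.check_planarity(g, counterexample=True)
    if not return_witness:
        return planar
    if planar:
        return True, None, None
    return False, cert, _classify_kuratowski(cert)


# ---------------------------------------------------------------------------
# structure vs function


def _undirected_edge_set(mat: np.ndarray) -> set[frozenset[int]]:
    sym = (np.asarray(mat) + np.asarray(mat).T) > 0
    return {frozenset((int(i), int(j)))
            for i, j in zip(*np.nonzero(np.triu(sym, 1)))}


def compare_structure_function(structural: np.ndarray,
                               functional: np.ndarray
                               ) -> StructureFunctionAgreement:
    """Compare structural and functional population adjacency.

    Both matrices are symmetrized (functional connectivity is undirected);
    returns the edge-set partition and the Jaccard index (1.0 by convention
    when both edge sets are empty).
    """
    structural = np.asarray(structural)
    functional = np.asarray(functional)
    if structural.shape != functional.shape:
        raise ValidationError(
            f"shape mismatch: {structural.shape} vs {functional.shape}")
    s = _undirected_edge_set(structural)
    f = _undirected_edge_set(functional)
    shared = s & f
    union = s | f
    jaccard = 1.0 if not union else len(shared) / len(union)
    return StructureFunctionAgreement(
        structural_edges=s, functional_edges=f, shared=shared,
        functional_only=f - s, structural_only=s - f, jaccard=jaccard)


# ---------------------------------------------------------------------------
# I/O


def layout_to_json(layout: StructuralLayout) -> str:
    """Serialize a layout to the JSON interchange format."""
    obj = {
        "populations": [
            {"label": lab, "x_um": float(x), "y_um": float(y)}
            for lab, (x, y) in zip(layout.population_labels, layout.positions)
        ],
        "edges": [
            {"source": layout.population_labels[i],
             "target": layout.population_labels[j],
             "directed": True}
            for i, j in layout.directed_edges()
        ],
        "edge_geometry": {
            f"{layout.population_labels[i]}->{layout.population_labels[j]}":
                np.asarray(poly).tolist()
            for (i, j), poly in layout.edge_geometry.items()
        },
    }
    return json.dumps(obj, indent=2)


def layout_from_json(text: str) -> StructuralLayout:
    """Parse a layout from the JSON interchange format."""
    obj = json.loads(text)
    labels = [p["label"] for p in obj["populations"]]
    index = {lab: k for k, lab in enumerate(labels)}
    pos = np.array([[p["x_um"], p["y_um"]] for p in obj["populations"]],
                   dtype=float)
    adj = np.zeros((len(labels), len(labels)), dtype=int)
    for e in obj["edges"]:
        i, j = index[e["source"]], index[e["target"]]
        adj[i, j] = 1
        if not e.get("directed", True):
            adj[j, i] = 1
    geometry: dict[tuple[int, int], np.ndarray] = {}
    for key, poly in obj.get("edge_geometry", {}).items():
        src, tgt = key.split("->")
        geometry[(index[src], index[tgt])] = np.asarray(poly, dtype=float)
    return StructuralLayout(labels, pos, adj, geometry)


def layout_to_graphml(layout: StructuralLayout, path) -> None:
    nx.write_graphml(layout.to_graph(), path)


def layout_to_edgelist_csv(layout: StructuralLayout, path) -> None:
    import pandas as pd

    rows = [{"source": layout.population_labels[i],
             "target": layout.population_labels[j]}
            for i, j in layout.directed_edges()]
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, index=False)
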