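"""Structural layouts: catalogue, crossings, planarity, comparison, I/O."""

import itertools

import networkx as nx
import numpy as np
import pytest

from _oracles import brute_planar, segment_crossings
from neuromotif import (
    CatalogueError, StructuralLayout, ValidationError, bridge_adjacency,
    compare_structure_function, compute_crossings, decompose_crossings,
    get_motif, is_planar, layout_from_json, layout_to_edgelist_csv,
    layout_to_graphml, layout_to_json,
)
from neuromotif.structure import MOTIF_IDS, motif_spec


# ---------------------------------------------------------------------------
# catalogue


def test_a1_is_fully_bidirectional_triangle():
    lay = get_motif("A1")
    assert lay.n_populations == 3
    off = ~np.eye(3, dtype=bool)
    assert (lay.adjacency[off] == 1).all()


def test_b5_has_crossing_flag_and_four_nodes():
    spec = motif_spec("B5")
    assert spec.n_nodes == 4
    assert spec.has_crossing
    lay = get_motif("B5")
    assert lay.n_populations == 4


def test_unknown_motif_raises_catalogue_error_naming_valid_ids():
    with pytest.raises(CatalogueError) as exc:
        get_motif("Z9")
    assert "B5" in str(exc.value)


def test_three_node_motifs_bidirectional_and_crossing_only_b5():
    for mid in MOTIF_IDS:
        spec = motif_spec(mid)
        if spec.n_nodes == 3:
            assert all(kind == "bidirectional" for _, _, kind in spec.edges)
        assert spec.has_crossing == (mid == "B5")
        lay = get_motif(mid)
        # bidirectional edges set both adjacency entries
        for s, t, kind in spec.edges:
            assert lay.adjacency[s, t] == 1
            if kind == "bidirectional":
                assert lay.adjacency[t, s] == 1


def test_catalogue_motifs_planar_but_b5_layout_crosses():
    for mid in MOTIF_IDS:
        lay = get_motif(mid)
        assert is_planar(lay.adjacency)
    report = compute_crossings(get_motif("B5"))
    assert report.n_crossings == 1
    assert report.max_multiplicity == 2
    pt, _ = report.crossing_points[0]
    assert np.allclose(pt, [500.0, 500.0])


# ---------------------------------------------------------------------------
# bridge adjacencies


def test_bridge_field_off_is_complete_with_12_directed_edges():
    lay = bridge_adjacency(field_on=False)
    assert lay.adjacency.sum() == 12
    assert (np.diag(lay.adjacency) == 0).all()


def test_bridge_field_on_has_two_bidirectional_pairs_crossing_once():
    lay = bridge_adjacency(field_on=True)
    assert lay.adjacency.sum() == 4
    assert lay.adjacency[0, 2] == lay.adjacency[2, 0] == 1
    assert lay.adjacency[1, 3] == lay.adjacency[3, 1] == 1
    assert compute_crossings(lay).n_crossings == 1


# ---------------------------------------------------------------------------
# layout validation


def test_layout_rejects_nonzero_diagonal_and_bad_entries():
    pos = np.array([[0.0, 0.0], [1.0, 0.0]])
    with pytest.raises(ValidationError):
        StructuralLayout(["a", "b"], pos, np.array([[1, 0], [0, 0]]))
    with pytest.raises(ValidationError):
        StructuralLayout(["a", "b"], pos, np.array([[0, 2], [0, 0]]))


def test_layout_rejects_geometry_with_wrong_endpoints():
    pos = np.array([[0.0, 0.0], [1.0, 0.0]])
    geom = {(0, 1): np.array([[0.0, 0.5], [1.0, 0.0]])}
    with pytest.raises(ValidationError):
        StructuralLayout(["a", "b"], pos, np.array([[0, 1], [0, 0]]), geom)


# ---------------------------------------------------------------------------
# crossings


def _segment_layout(positions, pairs):
    n = len(positions)
    adj = np.zeros((n, n), dtype=int)
    for i, j in pairs:
        adj[i, j] = 1
    return StructuralLayout([f"n{k}" for k in range(n)],
                            np.asarray(positions, float), adj)


def test_square_diagonals_cross_once():
    lay = _segment_layout(
        [[0, 0], [1, 0], [1, 1], [0, 1]], [(0, 2), (1, 3)])
    report = compute_crossings(lay)
    assert report.n_crossings == 1
    assert report.multiplicities() == [2]


def test_triangle_sides_do_not_cross():
    lay = _segment_layout(
        [[0, 0], [1, 0], [0.5, 1]], [(0, 1), (1, 2), (0, 2)])
    assert compute_crossings(lay).n_crossings == 0


def test_three_concurrent_segments_single_multiplicity_3_crossing():
    lay = _segment_layout(
        [[-1, 0], [1, 0], [0, -1], [0, 1], [-1, -1], [1, 1]],
        [(0, 1), (2, 3), (4, 5)])
    report = compute_crossings(lay)
    assert report.n_crossings == 1
    assert report.max_multiplicity == 3
    # oracle: three segments pairwise intersect at the same point
    segs = [(lay.positions[i], lay.positions[j])
            for i, j in [(0, 1), (2, 3), (4, 5)]]
    pts = segment_crossings(segs)
    assert len(pts) == 3
    assert all(np.allclose(p, [0, 0], atol=1e-9) for p in pts)


def test_zero_length_edge_raises():
    pos = np.array([[0.0, 0.0], [0.0, 0.0]])
    lay = StructuralLayout(["a", "b"], pos, np.array([[0, 1], [0, 0]]))
    with pytest.raises(ValidationError):
        compute_crossings(lay)


# ---------------------------------------------------------------------------
# decomposition


def test_two_fold_crossing_layout_returned_unchanged():
    lay = _segment_layout(
        [[0, 0], [1, 0], [1, 1], [0, 1]], [(0, 2), (1, 3)])
    out = decompose_crossings(lay)
    assert out is lay


def test_three_fold_crossing_decomposes_into_three_pairwise():
    lay = _segment_layout(
        [[-1, 0], [1, 0], [0, -1], [0, 1], [-1, -1], [1, 1]],
        [(0, 1), (2, 3), (4, 5)])
    out = decompose_crossings(lay)
    assert np.array_equal(out.adjacency, lay.adjacency)
    assert np.array_equal(out.positions, lay.positions)
    report = compute_crossings(out)
    assert report.n_crossings == 3
    assert report.multiplicities() == [2, 2, 2]
    # oracle on the decomposed polylines: each pair of edges crosses at
    # exactly one (merged) point; crossings may sit on a bend vertex
    def pair_points(pa, pb):
        pts = []
        for k in range(len(pa) - 1):
            for m in range(len(pb) - 1):
                p0, p1, q0, q1 = pa[k], pa[k + 1], pb[m], pb[m + 1]
                r, s = p1 - p0, q1 - q0
                denom = r[0] * s[1] - r[1] * s[0]
                if abs(denom) < 1e-15:
                    continue
                d = q0 - p0
                t = (d[0] * s[1] - d[1] * s[0]) / denom
                u = (d[0] * r[1] - d[1] * r[0]) / denom
                if -1e-7 <= t <= 1 + 1e-7 and -1e-7 <= u <= 1 + 1e-7:
                    pts.append(p0 + t * r)
        merged: list[np.ndarray] = []
        for p in pts:
            if not any(np.linalg.norm(p - q) < 1e-7 for q in merged):
                merged.append(p)
        return merged

    polys = [out.edge_geometry[e] for e in [(0, 1), (2, 3), (4, 5)]]
    all_pts = []
    for pa, pb in itertools.combinations(polys, 2):
        pts = pair_points(pa, pb)
        assert len(pts) == 1
        all_pts.extend(pts)
    # and the three pairwise crossing points are distinct
    for a, b in itertools.combinations(all_pts, 2):
        assert np.linalg.norm(a - b) > 1e-7


def test_decompose_preserves_adjacency_and_bounds_multiplicity_random():
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(3, 7))
        pos = rng.uniform(-100, 100, size=(n, 2))
        adj = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < 0.4:
                    adj[i, j] = 1
        lay = StructuralLayout([f"n{k}" for k in range(n)], pos, adj)
        out = decompose_crossings(lay)
        assert np.array_equal(out.adjacency, adj)
        assert compute_crossings(out).max_multiplicity <= 2


# ---------------------------------------------------------------------------
# planarity


def test_k4_planar_k5_and_k33_witnessed():
    k4 = nx.to_numpy_array(nx.complete_graph(4))
    assert is_planar(k4) is True
    planar, witness, kind = is_planar(
        nx.to_numpy_array(nx.complete_graph(5)), return_witness=True)
    assert not planar and kind == "K5"
    assert witness.number_of_nodes() >= 5
    planar, witness, kind = is_planar(
        nx.to_numpy_array(nx.complete_bipartite_graph(3, 3)),
        return_witness=True)
    assert not planar and kind == "K3,3"


def test_is_planar_rejects_non_square():
    with pytest.raises(ValidationError):
        is_planar(np.zeros((2, 3)))


def test_is_planar_matches_brute_force_exhaustively_up_to_6_nodes():
    # every labelled graph on exactly 6 nodes (and implicitly all smaller
    # graphs as their padded versions)
    pairs = list(itertools.combinations(range(6), 2))
    mismatches = 0
    for bits in range(1 << 15):
        adj = np.zeros((6, 6), dtype=int)
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                adj[i, j] = adj[j, i] = 1
        if is_planar(adj) != brute_planar(adj):
            mismatches += 1
    assert mismatches == 0


# ---------------------------------------------------------------------------
# structure vs function


def test_identical_matrices_full_agreement():
    a = get_motif("B5").adjacency
    agree = compare_structure_function(a, a)
    assert agree.jaccard == 1.0
    assert not agree.functional_only and not agree.structural_only


def test_c2_vs_complete_jaccard_two_sixths():
    c2 = bridge_adjacency(field_on=True).adjacency
    complete = bridge_adjacency(field_on=False).adjacency
    agree = compare_structure_function(c2, complete)
    assert len(agree.functional_only) == 4
    assert len(agree.shared) == 2
    assert agree.jaccard == pytest.approx(2 / 6)


def test_both_empty_jaccard_one_by_convention():
    z = np.zeros((3, 3), dtype=int)
    assert compare_structure_function(z, z).jaccard == 1.0


def test_shape_mismatch_raises():
    with pytest.raises(ValidationError):
        compare_structure_function(np.zeros((3, 3)), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# I/O


def test_layout_json_round_trip():
    lay = get_motif("B5")
    back = layout_from_json(layout_to_json(lay))
    assert back.population_labels == lay.population_labels
    assert np.allclose(back.positions, lay.positions)
    assert np.array_equal(back.adjacency, lay.adjacency)
    for key, poly in lay.edge_geometry.items():
        assert np.allclose(back.edge_geometry[key], poly)


def test_graphml_and_edgelist_exports(tmp_path):
    lay = get_motif("A2")
    layout_to_graphml(lay, tmp_path / "g.graphml")
    g = nx.read_graphml(tmp_path / "g.graphml")
    assert g.number_of_edges() == len(lay.directed_edges())
    layout_to_edgelist_csv(lay, tmp_path / "e.csv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "e.csv")
    assert len(df) == len(lay.directed_edges())
    assert list(df.columns) == ["source", "target"]
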