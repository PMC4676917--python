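"""Residue interaction networks: selection, distances, persistence, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coldfold import (
    ChargeSelection,
    TrajectoryDistances,
    build_network,
    cluster_report,
    compute_pair_distances,
    persistence_matrix,
    read_network,
    select_charged_columns,
    write_network,
)
from coldfold.synthetic import (
    TrajectorySpec,
    generate_alignment,
    generate_trajectory,
    write_trajectory_pdb,
)


def write_fasta(path, records):
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in records))


# ---------------------------------------------------------------- selection

class TestChargeSelection:
    def test_column_charged_in_single_orthologue_selected(self, tmp_path):
        # column 5 is E/T/S: one orthologue carries the charge, so the
        # reference position is kept (the cross-species correspondence rule)
        path = tmp_path / "aln.fasta"
        write_fasta(path, [("REF", "AAAATAAAAA"), ("ORT1", "AAAAEAAAAA"),
                           ("ORT2", "AAAASAAAAA")])
        sel = select_charged_columns(path, "REF")
        assert sel.positions == [5]
        assert sel.charge_class[5] == "acidic"
        assert sel.provenance[5] == ["ORT1"]

    def test_uncharged_column_not_selected(self, tmp_path):
        path = tmp_path / "aln.fasta"
        write_fasta(path, [("REF", "GGG"), ("ORT1", "GGG"), ("ORT2", "GGG")])
        assert select_charged_columns(path, "REF").positions == []

    def test_reference_gap_columns_skipped_and_numbering_mapped(self, tmp_path):
        path = tmp_path / "aln.fasta"
        # alignment column 2 is a reference gap; the charged column 4 maps
        # to reference position 3
        write_fasta(path, [("REF", "A-AEA"), ("ORT1", "AKAAA")])
        sel = select_charged_columns(path, "REF")
        assert sel.positions == [3]
        assert sel.charge_class[3] == "acidic"

    def test_missing_reference_raises(self, tmp_path):
        path = tmp_path / "aln.fasta"
        write_fasta(path, [("A", "AAA"), ("B", "AAA")])
        with pytest.raises(KeyError):
            select_charged_columns(path, "NOPE")

    def test_ragged_alignment_raises(self, tmp_path):
        path = tmp_path / "aln.fasta"
        write_fasta(path, [("REF", "AAAA"), ("B", "AA")])
        with pytest.raises(ValueError, match="ragged"):
            select_charged_columns(path, "REF")

    def test_histidine_not_charged(self, tmp_path):
        path = tmp_path / "aln.fasta"
        write_fasta(path, [("REF", "AHA"), ("ORT1", "AHA")])
        assert select_charged_columns(path, "REF").positions == []

    def test_planted_alignment_recovered(self, tmp_path):
        fasta, truth = generate_alignment(3, 120, {5: "E", 20: "K", 77: "D"}, seed=9)
        path = tmp_path / "aln.fasta"
        path.write_text(fasta)
        sel = select_charged_columns(path, "REF")
        assert sel.positions == truth["planted_columns"]
        for col in truth["planted_columns"]:
            assert sel.charge_class[col] == truth["columns"][str(col)]["charge_class"]


# ---------------------------------------------------------------- distances

TOY_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       9.000   5.000   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       7.000   4.000   0.000  1.00  0.00           C
ATOM      6  CB  ALA A   2       6.000   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""


def toy_selection(positions):
    return ChargeSelection(list(positions), {p: "acidic" for p in positions})


class TestPairDistances:
    def test_hand_computed_single_frame(self, tmp_path):
        # closest side-chain atoms (CB at x=2 and x=6 angstrom) are 4 A apart
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        dist = compute_pair_distances(path, toy_selection([1, 2]))
        assert dist.pairs == [(1, 2)]
        assert dist.distances[0, 0] == pytest.approx(0.40, abs=1e-6)

    def test_constant_coordinates_give_constant_series(self, tmp_path):
        frames = [np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.0, 0]])] * 5
        path = tmp_path / "const.pdb"
        write_trajectory_pdb(frames, path)
        dist = compute_pair_distances(path, toy_selection([1, 2, 3]))
        assert dist.n_frames == 5
        for col in range(dist.distances.shape[1]):
            assert np.ptp(dist.distances[:, col]) == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_oracle(self, tmp_path):
        spec = TrajectorySpec(n_residues=5, n_frames=10,
                              planted_edges=((1, 2, 0.5), (3, 5, 1.0)), seed=2)
        frames, _ = generate_trajectory(spec)
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb(frames, path)
        sel = toy_selection([1, 2, 3, 4, 5])
        dist = compute_pair_distances(path, sel)

        # independent naive parse of the PDB text + all-pair minimum
        oracle = _parse_pdb_sidechain_min(path.read_text())
        for f in range(10):
            for p, (i, j) in enumerate(dist.pairs):
                assert dist.distances[f, p] == pytest.approx(oracle[f][(i, j)], abs=1e-6)


def _parse_pdb_sidechain_min(text):
    """Naive reference: fixed-column PDB parse, min over CB atoms, nm."""
    frames, current = [], {}
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current = {}
        elif line.startswith("ATOM"):
            name = line[12:16].strip()
            resid = int(line[22:26])
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            current.setdefault(resid, {})[name] = xyz
        elif line.startswith("ENDMDL"):
            frames.append(current)
    out = []
    for fr in frames:
        resids = sorted(fr)
        d = {}
        for a_i, i in enumerate(resids):
            for j in resids[a_i + 1:]:
                side_i = [v for k, v in fr[i].items() if k == "CB"] or [fr[i]["CA"]]
                side_j = [v for k, v in fr[j].items() if k == "CB"] or [fr[j]["CA"]]
                d[(i, j)] = min(np.linalg.norm(a - b) for a in side_i for b in side_j) / 10.0
        out.append(d)
    return out


# -------------------------------------------------------------- persistence

class TestPersistence:
    def test_always_close_pair(self):
        dist = TrajectoryDistances([(1, 2)], np.full((100, 1), 0.5))
        assert persistence_matrix(dist)[(1, 2)] == 1.0

    def test_exact_count_semantics(self):
        d = np.full((1000, 1), 0.9)
        d[:30, 0] = 0.3
        dist = TrajectoryDistances([(1, 2)], d)
        assert persistence_matrix(dist)[(1, 2)] == 0.030

    def test_boundary_distance_is_not_an_approach(self):
        dist = TrajectoryDistances([(1, 2)], np.full((10, 1), 0.6))
        assert persistence_matrix(dist)[(1, 2)] == 0.0

    def test_invariant_under_frame_permutation(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.2, 1.0, size=(200, 3))
        dist = TrajectoryDistances([(1, 2), (1, 3), (2, 3)], d)
        perm = TrajectoryDistances([(1, 2), (1, 3), (2, 3)], d[rng.permutation(200)])
        assert persistence_matrix(dist) == persistence_matrix(perm)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.0, 1.2, size=(50, 4))
        pairs = [(1, 2), (1, 3), (2, 4), (3, 4)]
        dist = TrajectoryDistances(pairs, d)
        lo = persistence_matrix(dist, threshold=0.4)
        hi = persistence_matrix(dist, threshold=0.8)
        assert all(hi[p] >= lo[p] for p in pairs)


# -------------------------------------------------------------- network

class TestBuildNetwork:
    def make_dist(self, n_close, n_frames=1000):
        d = np.full((n_frames, 1), 0.9)
        d[:n_close, 0] = 0.3
        return TrajectoryDistances([(1, 2)], d)

    def test_edge_absent_more_than_99pct_filtered(self):
        net = build_network(self.make_dist(5), toy_selection([1, 2]))
        assert net.graph.number_of_edges() == 0
        assert net.isolated_nodes() == [1, 2]

    def test_exactly_99pct_boundary_retained(self):
        net = build_network(self.make_dist(10), toy_selection([1, 2]))
        assert net.graph.has_edge(1, 2)
        assert net.graph[1][2]["persistence"] == 0.010

    def test_planted_network_recovered_exactly(self, tmp_path):
        planted = ((1, 3, 1.0), (2, 5, 0.4), (4, 6, 0.011), (1, 6, 0.005))
        spec = TrajectorySpec(n_residues=6, n_frames=1000, planted_edges=planted, seed=5)
        frames, truth = generate_trajectory(spec)
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb(frames, path)
        sel = toy_selection(range(1, 7))
        dist = compute_pair_distances(path, sel)
        net = build_network(dist, sel)
        expected = {(i, j): p for (i, j, p) in planted if round(p * 1000) / 1000 >= 0.01}
        got = {tuple(sorted(e)): d["persistence"] for *e, d in net.graph.edges(data=True)}
        assert got == {k: pytest.approx(truth["expected_persistence"][f"{k[0]}-{k[1]}"])
                       for k in expected}

    def test_raising_min_persistence_never_adds_edges(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.3, 1.0, size=(100, 3))
        dist = TrajectoryDistances([(1, 2), (1, 3), (2, 3)], d)
        sel = toy_selection([1, 2, 3])
        loose = build_network(dist, sel, min_persistence=0.01)
        tight = build_network(dist, sel, min_persistence=0.5)
        assert set(tight.graph.edges) <= set(loose.graph.edges)

    def test_empty_selection_raises(self):
        dist = TrajectoryDistances([(1, 2)], np.full((10, 1), 0.5))
        with pytest.raises(ValueError, match="empty"):
            build_network(dist, ChargeSelection([], {}))

    def test_full_pipeline_matches_naive_reimplementation(self):
        # independent nested-loop re-implementation of persistence + filter
        rng = np.random.default_rng(17)
        pairs = [(i, j) for i in range(1, 11) for j in range(i + 1, 11)]
        d = rng.uniform(0.3, 1.0, size=(50, len(pairs)))
        dist = TrajectoryDistances(pairs, d)
        sel = toy_selection(range(1, 11))
        net = build_network(dist, sel)
        naive_edges = {}
        for p, (i, j) in enumerate(pairs):
            count = sum(1 for f in range(50) if d[f, p] < 0.6)
            far_frac = (50 - count) / 50
            if not far_frac > 0.99:
                naive_edges[(i, j)] = count / 50
        got = {tuple(sorted(e)): data["persistence"]
               for *e, data in net.graph.edges(data=True)}
        assert got == naive_edges


# -------------------------------------------------------------- serialization

class TestSerialization:
    def make_net(self):
        d = np.array([[0.3, 0.5, 0.9]] * 10)
        dist = TrajectoryDistances([(1, 2), (1, 3), (2, 3)], d)
        sel = ChargeSelection([1, 2, 3], {1: "acidic", 2: "acidic", 3: "basic"})
        return build_network(dist, sel)

    def test_graphml_counts_and_attributes(self, tmp_path):
        net = self.make_net()
        path = tmp_path / "net.graphml"
        write_network(net, path, format="graphml")
        text = path.read_text()
        assert text.count("<node") == 3 and text.count("<edge") == 2
        assert 'acidic' in text

    def test_graphml_roundtrip(self, tmp_path):
        net = self.make_net()
        path = tmp_path / "net.graphml"
        write_network(net, path, format="graphml")
        back = read_network(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(tuple, back.graph.edges)) == set(map(tuple, net.graph.edges))
        for i, j, d in net.graph.edges(data=True):
            assert back.graph[i][j]["persistence"] == pytest.approx(d["persistence"])
        for n, d in net.graph.nodes(data=True):
            assert back.graph.nodes[n]["charge_class"] == d["charge_class"]

    def test_edgelist_and_dot(self, tmp_path):
        net = self.make_net()
        write_network(net, tmp_path / "net.csv", format="edgelist-csv")
        lines = (tmp_path / "net.csv").read_text().splitlines()
        assert lines[0] == "res_i,res_j,persistence" and len(lines) == 3
        write_network(net, tmp_path / "net.dot", format="dot")
        assert "1 -- 2" in (tmp_path / "net.dot").read_text()

    def test_unknown_format_raises(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            write_network(self.make_net(), tmp_path / "x", format="gexf")


# -------------------------------------------------------------- clusters

class TestClusterReport:
    def net_from_edges(self, charge, edges):
        import networkx as nx
        from coldfold.rin import PersistenceNetwork
        g = nx.Graph()
        for n, c in charge.items():
            g.add_node(n, label=f"res{n}", charge_class=c)
        for i, j, p in edges:
            g.add_edge(i, j, persistence=p)
        return PersistenceNetwork(g, 0.6, 0.01)

    def test_acidic_triangle_single_cluster(self):
        net = self.net_from_edges(
            {1: "acidic", 2: "acidic", 3: "acidic", 4: "basic"},
            [(1, 2, 0.5), (2, 3, 0.5), (1, 3, 0.5), (3, 4, 0.9)])
        clusters = cluster_report(net)
        assert len(clusters) == 1
        assert clusters[0]["members"] == [1, 2, 3]

    def test_no_acidic_nodes_empty(self):
        net = self.net_from_edges({1: "basic", 2: "basic"}, [(1, 2, 1.0)])
        assert cluster_report(net) == []

    def test_two_disjoint_acidic_pairs(self):
        net = self.net_from_edges(
            {1: "acidic", 2: "acidic", 5: "acidic", 6: "acidic"},
            [(1, 2, 0.3), (5, 6, 0.8)])
        clusters = cluster_report(net)
        assert [c["size"] for c in clusters] == [2, 2]
        assert clusters[0]["members"] == [5, 6]  # higher summed persistence first

    def test_secondary_structure_span_annotation(self):
        net = self.net_from_edges(
            {1: "acidic", 2: "acidic", 3: "acidic"},
            [(1, 2, 0.5), (2, 3, 0.5)])
        ss = {1: "beta1", 2: "beta2", 3: "beta2"}
        clusters = cluster_report(net, secondary_structure=ss)
        assert clusters[0]["spans_multiple_elements"] is True
        assert clusters[0]["elements"] == ["beta1", "beta2"]
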