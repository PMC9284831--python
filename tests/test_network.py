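import numpy as np
import pytest

from chemnet import network as net
from chemnet.errors import (
    ClusterLookupError,
    ConfigurationError,
    FormatError,
    InputError,
)


def _write_tables(tmp_path, cp_rows, pp_rows):
    cp = tmp_path / "cp.tsv"
    pp = tmp_path / "pp.tsv"
    cp.write_text(
        "chemical\tprotein\tcombined_score\n"
        + "".join(f"{c}\t{p}\t{s}\n" for c, p, s in cp_rows)
    )
    pp.write_text(
        "protein1\tprotein2\tcombined_score\n"
        + "".join(f"{a}\t{b}\t{s}\n" for a, b, s in pp_rows)
    )
    return cp, pp


class TestReadInteractions:
    def test_threshold_filter(self, tmp_path):
        cp, pp = _write_tables(
            tmp_path, [("c1", "p1", 900), ("c1", "p2", 300)], [("p1", "p2", 500)]
        )
        graph = net.read_interactions(cp, pp, quality_cutoff=400)
        assert len(graph.chem_protein) == 1
        assert graph.chem_protein[("c1", "p1")] == 900

    def test_duplicate_collapses_to_max(self, tmp_path):
        cp, pp = _write_tables(
            tmp_path,
            [("c1", "p1", 500), ("c1", "p1", 800)],
            [("p1", "p2", 300), ("p2", "p1", 700)],
        )
        graph = net.read_interactions(cp, pp, quality_cutoff=0)
        assert graph.chem_protein == {("c1", "p1"): 800}
        assert graph.protein_protein == {("p1", "p2"): 700}

    def test_missing_column_raises(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("chemical\tscore\nc1\t100\n")
        _, pp = _write_tables(tmp_path, [], [])
        with pytest.raises(FormatError):
            net.read_interactions(bad, pp)

    def test_non_integer_score_raises(self, tmp_path):
        cp = tmp_path / "cp.tsv"
        cp.write_text("chemical\tprotein\tcombined_score\nc1\tp1\thigh\n")
        _, pp = _write_tables(tmp_path, [], [])
        with pytest.raises(FormatError):
            net.read_interactions(cp, pp)

    def test_round_trip_identity(self, tmp_path, default_fixture):
        _, graph, _, _ = default_fixture
        cp = tmp_path / "cp.tsv"
        pp = tmp_path / "pp.tsv"
        net.write_interactions(graph, cp, pp)
        again = net.read_interactions(cp, pp, quality_cutoff=0)
        assert again.chem_protein == graph.chem_protein
        assert again.protein_protein == graph.protein_protein


class TestBuildProfiles:
    def test_single_edge_unit_vector(self):
        graph = net.InteractionGraph()
        graph.add_chem_protein("c1", "p1", 1000)
        (profile,) = net.build_profiles(graph, propagation_weight=0.0)
        assert profile.weights == {"p1": 1.0}

    def test_identical_edge_sets_identical_profiles(self):
        graph = net.InteractionGraph()
        for chem in ("c1", "c2"):
            graph.add_chem_protein(chem, "p1", 800)
            graph.add_chem_protein(chem, "p2", 400)
        graph.add_protein_protein("p1", "p3", 600)
        p1, p2 = net.build_profiles(graph, propagation_weight=0.5)
        assert p1.weights == p2.weights

    def test_hand_computed_propagation(self):
        # direct: P1=1000, P2=500; PPI: P1-P3 800; w=0.5
        # raw weights: P1=1.0, P2=0.5, P3=0.5*1000*800/1e6=0.4
        graph = net.InteractionGraph()
        graph.add_chem_protein("c1", "P1", 1000)
        graph.add_chem_protein("c1", "P2", 500)
        graph.add_protein_protein("P1", "P3", 800)
        (profile,) = net.build_profiles(graph, propagation_weight=0.5)
        norm = np.sqrt(1.0**2 + 0.5**2 + 0.4**2)
        assert profile.weights["P1"] == pytest.approx(1.0 / norm)
        assert profile.weights["P2"] == pytest.approx(0.5 / norm)
        assert profile.weights["P3"] == pytest.approx(0.4 / norm)

    def test_l2_normalized(self, default_fixture):
        _, graph, _, _ = default_fixture
        for profile in net.build_profiles(graph):
            assert sum(v * v for v in profile.weights.values()) == pytest.approx(1.0)


class TestDistanceMatrix:
    def test_identical_profiles_distance_zero(self):
        a = net.ChemicalProfile("a", {"p1": 0.6, "p2": 0.8})
        b = net.ChemicalProfile("b", {"p1": 0.6, "p2": 0.8})
        dist = net.compute_distance_matrix([a, b])
        assert dist.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_distance_one(self):
        a = net.ChemicalProfile("a", {"p1": 1.0})
        b = net.ChemicalProfile("b", {"p2": 1.0})
        dist = net.compute_distance_matrix([a, b])
        assert dist.matrix[0, 1] == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        proteins = [f"p{i}" for i in range(8)]
        profiles = []
        for i in range(10):
            raw = {p: float(rng.random()) for p in rng.choice(proteins, 4, replace=False)}
            norm = np.sqrt(sum(v * v for v in raw.values()))
            profiles.append(
                net.ChemicalProfile(f"c{i}", {p: v / norm for p, v in raw.items()})
            )
        dist = net.compute_distance_matrix(profiles)
        # O(n^2) loop over explicit cosine formula
        for i, a in enumerate(sorted(profiles, key=lambda p: p.chemical)):
            for j, b in enumerate(sorted(profiles, key=lambda p: p.chemical)):
                dot = sum(a.weights.get(p, 0) * b.weights.get(p, 0) for p in proteins)
                na = np.sqrt(sum(v * v for v in a.weights.values()))
                nb = np.sqrt(sum(v * v for v in b.weights.values()))
                expected = 0.0 if i == j else 1 - dot / (na * nb)
                assert dist.matrix[i, j] == pytest.approx(expected, abs=1e-9)

    def test_symmetry_zero_diagonal(self, default_fixture):
        _, graph, _, _ = default_fixture
        dist = net.compute_distance_matrix(net.build_profiles(graph))
        assert np.allclose(dist.matrix, dist.matrix.T)
        assert np.all(np.diag(dist.matrix) == 0)
        assert dist.matrix.min() >= 0 and dist.matrix.max() <= 1

    def test_fewer_than_two_profiles_raises(self):
        with pytest.raises(InputError):
            net.compute_distance_matrix([net.ChemicalProfile("a", {"p": 1.0})])


def _block_matrix():
    """4 points: two tight blocks 0.9 apart, 0.001 within."""
    m = np.full((4, 4), 0.9)
    m[0, 1] = m[1, 0] = 0.001
    m[2, 3] = m[3, 2] = 0.001
    np.fill_diagonal(m, 0.0)
    return net.DistanceMatrix(["a", "b", "c", "d"], m)


class TestHierarchicalCluster:
    def test_two_blocks(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 0.005)
        assert len(clustering.cluster_ids) == 2
        assert clustering.assignment["a"] == clustering.assignment["b"]
        assert clustering.assignment["c"] == clustering.assignment["d"]

    def test_threshold_above_max_single_cluster(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 2.0)
        assert len(clustering.cluster_ids) == 1

    def test_threshold_below_min_all_singletons(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 0.0005)
        assert len(clustering.cluster_ids) == 4

    def test_invalid_linkage_raises(self):
        with pytest.raises(ConfigurationError):
            net.hierarchical_cluster(_block_matrix(), 0.1, "ward")

    def test_cluster_ids_stable_by_smallest_member(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 0.005)
        assert clustering.assignment["a"] == 0  # smallest member id first
        assert clustering.assignment["c"] == 1

    def test_threshold_monotonicity_standard_range(self, default_fixture):
        _, graph, _, _ = default_fixture
        dist = net.compute_distance_matrix(net.build_profiles(graph))
        counts = [
            len(net.hierarchical_cluster(dist, t).cluster_ids)
            for t in (0.001, 0.005, 0.01, 0.05, 0.1)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFilterBySupport:
    def _make_clustering(self, sizes):
        assignment = {}
        counter = 0
        for cid, n in enumerate(sizes):
            for _ in range(n):
                assignment[f"x{counter:04d}"] = cid
                counter += 1
        return net.Clustering(
            threshold=0.005,
            assignment=assignment,
            linkage_matrix=np.zeros((0, 4)),
            leaves=sorted(assignment),
        )

    def test_exactly_at_support_discarded(self):
        clustering = self._make_clustering([100])
        filtered = net.filter_by_support(clustering, 100)
        assert filtered.assignment == {}
        assert len(filtered.discarded) == 100

    def test_all_below_threshold(self):
        clustering = self._make_clustering([5, 8])
        filtered = net.filter_by_support(clustering, 100)
        assert filtered.assignment == {}
        assert len(filtered.discarded) == 13

    def test_mixed_sizes(self):
        clustering = self._make_clustering([150, 99, 101])
        filtered = net.filter_by_support(clustering, 100)
        assert len(set(filtered.assignment.values())) == 2
        assert len(filtered.discarded) == 99
        assert len(filtered.assignment) == 251


class TestAnnotateCluster:
    def _single_chem_graph(self):
        graph = net.InteractionGraph()
        graph.add_chem_protein("c1", "P1", 900)
        graph.add_chem_protein("c1", "P2", 300)
        return graph

    def _clustering_for(self, chems):
        return net.Clustering(
            threshold=0.01,
            assignment={c: 0 for c in chems},
            linkage_matrix=np.zeros((0, 4)),
            leaves=sorted(chems),
        )

    def test_high_cutoff(self):
        annot = net.annotate_cluster(
            self._clustering_for(["c1"]), self._single_chem_graph(), 700
        )
        assert annot.proteins[0] == frozenset({"P1"})

    def test_low_cutoff_superset(self):
        graph = self._single_chem_graph()
        clustering = self._clustering_for(["c1"])
        high = net.annotate_cluster(clustering, graph, 700)
        low = net.annotate_cluster(clustering, graph, 150)
        assert low.proteins[0] == frozenset({"P1", "P2"})
        assert low.proteins[0] >= high.proteins[0]

    def test_union_oracle_on_fixture(self, default_fixture):
        _, graph, _, _ = default_fixture
        chems = sorted(graph.chemicals)[:5]
        clustering = self._clustering_for(chems)
        annot = net.annotate_cluster(clustering, graph, 700)
        expected = set()
        for chem in chems:
            expected |= {
                p for p, s in graph.chemical_edges(chem).items() if s >= 700
            }
        assert annot.proteins[0] == frozenset(expected)

    def test_annotation_monotonicity_all_clusters(self, default_fixture):
        _, graph, truth, _ = default_fixture
        clustering = net.Clustering(
            threshold=0.01,
            assignment=dict(truth.chemical_cluster),
            linkage_matrix=np.zeros((0, 4)),
            leaves=sorted(truth.chemical_cluster),
        )
        low = net.annotate_cluster(clustering, graph, 400)
        high = net.annotate_cluster(clustering, graph, 700)
        for cid in low.proteins:
            assert low.proteins[cid] >= high.proteins[cid]


class TestClusterDistance:
    def test_same_cluster_zero(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 0.005)
        assert net.cluster_distance(clustering, 0, 0) == 0.0

    def test_between_block_merge_height(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 0.005)
        # average linkage joins the two blocks at their mean distance 0.9
        assert net.cluster_distance(clustering, 0, 1) == pytest.approx(0.9)

    def test_symmetry(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 0.005)
        assert net.cluster_distance(clustering, 0, 1) == net.cluster_distance(
            clustering, 1, 0
        )

    def test_unknown_cluster_raises(self):
        clustering = net.hierarchical_cluster(_block_matrix(), 0.005)
        with pytest.raises(ClusterLookupError):
            net.cluster_distance(clustering, 0, 99)
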