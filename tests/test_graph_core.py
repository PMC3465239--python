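import math

import networkx as nx
import numpy as np
import pytest

from spokenet import (
    assortativity,
    ck_spectrum,
    count_triangles,
    degree_histogram,
    hierarchical_model,
    mean_clustering,
    node_clustering,
    read_edgelist,
    write_edgelist,
)

from _oracles import (
    assortativity_brute,
    node_clustering_brute,
    random_test_graphs,
    triangles_brute,
)


class TestEdgelistIO:
    def test_parses_simple_tsv(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("a b\nb\tc\n")
        g = read_edgelist(p)
        assert set(g.nodes) == {"a", "b", "c"}
        assert g.number_of_edges() == 2

    def test_drops_self_loops_and_duplicates(self, tmp_path, caplog):
        p = tmp_path / "g.tsv"
        p.write_text("a a\na b\na b\n")
        with caplog.at_level("WARNING"):
            g = read_edgelist(p)
        assert set(g.nodes) == {"a", "b"}
        assert g.number_of_edges() == 1
        msgs = [r.getMessage() for r in caplog.records]
        assert sum(m.startswith("dropping self-loop") for m in msgs) == 1
        assert sum(m.startswith("collapsing duplicate") for m in msgs) == 1

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("# header\n\na b\n")
        assert read_edgelist(p).number_of_edges() == 1

    def test_round_trip(self, tmp_path):
        g = nx.relabel_nodes(nx.gnp_random_graph(20, 0.2, seed=3), str)
        p = tmp_path / "g.tsv"
        write_edgelist(g, p)
        h = read_edgelist(p)
        assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in h.edges}

    def test_empty_graph_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("# nothing\n")
        with pytest.raises(ValueError, match="empty"):
            read_edgelist(p)

    def test_single_column_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("lonely\n")
        with pytest.raises(ValueError, match="columns"):
            read_edgelist(p)


class TestNodeClustering:
    def test_triangle_node(self, k5):
        assert node_clustering(k5, "0") == 1.0

    def test_star_center(self, star5):
        assert node_clustering(star5, "0") == 0.0

    def test_low_degree_rejected(self, star5):
        with pytest.raises(ValueError, match="undefined"):
            node_clustering(star5, "1")

    def test_hierarchical_root(self):
        # degree-20 root of the 25-node module: 30 neighbour links -> 60/380
        g = hierarchical_model(2)
        assert g.degree("0") == 20
        assert node_clustering(g, "0") == pytest.approx(60 / 380)
        assert node_clustering(g, "0") == pytest.approx(node_clustering_brute(g, "0"))


class TestTriangleCounts:
    def test_k5(self, k5):
        assert count_triangles(k5) == 10  # C(5,3)

    def test_tree_has_none(self):
        g = nx.relabel_nodes(nx.random_labeled_tree(30, seed=1), str)
        assert count_triangles(g) == 0

    def test_hierarchical_matches_brute_force(self):
        g = hierarchical_model(2)
        assert count_triangles(g) == triangles_brute(g)


class TestCkSpectrum:
    def test_k5(self, k5):
        spec = ck_spectrum(k5)
        assert spec.entries == {4: (1.0, 5)}

    def test_star_leaves_excluded(self, star5):
        spec = ck_spectrum(star5)
        assert spec.entries == {5: (0.0, 1)}

    def test_matches_per_node_oracle(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(50, 0.15, seed=7), str)
        spec = ck_spectrum(g)
        by_k = {}
        for v in g.nodes:
            if g.degree(v) >= 2:
                by_k.setdefault(g.degree(v), []).append(node_clustering_brute(g, v))
        for k, (mean_c, n) in spec.entries.items():
            assert n == len(by_k[k])
            assert mean_c == pytest.approx(np.mean(by_k[k]))

    def test_isomorphism_invariance(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(40, 0.2, seed=9), str)
        h = nx.relabel_nodes(g, {v: f"x{v}" for v in g.nodes})
        assert ck_spectrum(g).entries == ck_spectrum(h).entries

    def test_means_within_unit_interval(self):
        for g in random_test_graphs(12, seed=5):
            try:
                spec = ck_spectrum(g)
            except ValueError:
                continue
            for k, (c, n) in spec.entries.items():
                assert 0.0 <= c <= 1.0 and n > 0 and k >= 2


class TestMeanClustering:
    def test_k5(self, k5):
        assert mean_clustering(k5) == 1.0

    def test_tree(self):
        g = nx.relabel_nodes(nx.random_labeled_tree(20, seed=2), str)
        assert mean_clustering(g) == 0.0

    def test_matches_brute_force(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(40, 0.2, seed=11), str)
        expected = np.mean([
            node_clustering_brute(g, v) for v in g.nodes if g.degree(v) >= 2
        ])
        assert mean_clustering(g) == pytest.approx(expected)


class TestAssortativity:
    def test_star_is_perfectly_disassortative(self, star5):
        assert assortativity(star5) == pytest.approx(-1.0)

    def test_union_of_cliques_matches_pearson_oracle(self):
        g = nx.relabel_nodes(nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(4)), str)
        assert assortativity(g) == pytest.approx(assortativity_brute(g))

    def test_relabeling_invariance(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(30, 0.2, seed=13), str)
        h = nx.relabel_nodes(g, {v: f"y{v}" for v in g.nodes})
        assert assortativity(g) == pytest.approx(assortativity(h))

    def test_regular_graph_rejected(self, k5):
        with pytest.raises(ValueError, match="undefined"):
            assortativity(k5)

    def test_too_few_edges_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            assortativity(g)


class TestDegreeHistogram:
    def test_stub_sum_is_twice_edges(self):
        for g in random_test_graphs(8, seed=21):
            hist = degree_histogram(g)
            assert sum(k * c for k, c in hist.counts.items()) == 2 * g.number_of_edges()
            assert hist.n_nodes == g.number_of_nodes()
            assert hist.n_edges == g.number_of_edges()

    def test_mean_degree(self, k5):
        assert degree_histogram(k5).mean_degree == 4.0

    def test_tsv_round_trip(self, tmp_path, k5):
        import pandas as pd

        p = tmp_path / "h.tsv"
        degree_histogram(k5).to_tsv(p)
        df = pd.read_csv(p, sep="\t")
        assert df.loc[0, "k"] == 4 and df.loc[0, "count"] == 5


class TestLogBinnedSpectrum:
    def test_binned_means_are_node_weighted(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(60, 0.2, seed=17), str)
        spec = ck_spectrum(g)
        binned = spec.log_binned()
        assert binned["n_nodes"].sum() == sum(n for _, n in spec.entries.values())
        # weighted mean over one bin reproduces the bin value
        row = binned.iloc[0]
        lo = 2 ** math.floor(math.log2(row["k"]))
        ks = [k for k in spec.entries if lo <= k < 2 * lo]
        w = np.array([spec.entries[k][1] for k in ks], dtype=float)
        c = np.array([spec.entries[k][0] for k in ks])
        assert row["mean_clustering"] == pytest.approx(np.average(c, weights=w))
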