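"""Network thresholding and tripartite triangle enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from microtriad.motifs import (
    build_network,
    enumerate_tripartite_triangles,
    motif_table,
    summarize_motifs,
    write_network,
)


def _edges(rows):
    return pd.DataFrame(
        rows,
        columns=["node_a", "node_b", "modality_a", "modality_b", "log10_bf", "rho"],
    )


class TestBuildNetwork:
    def test_threshold_is_inclusive(self):
        edges = _edges([
            ("t1", "m1", "T", "M", 0.5, 0.4),
            ("t1", "m2", "T", "M", 0.499, 0.4),
        ])
        net = build_network(edges, 0.5)
        assert net.graph.has_edge("t1", "m1")
        assert not net.graph.has_edge("t1", "m2")

    def test_isolated_nodes_retained(self):
        edges = _edges([("t1", "m1", "T", "M", 0.2, 0.1)])
        net = build_network(edges, 0.5, nodes=[("t1", "T"), ("m1", "M"), ("p1", "PP")])
        assert set(net.nodes) == {"t1", "m1", "p1"}
        assert net.graph.number_of_edges() == 0

    def test_minus_infinity_threshold_keeps_all(self):
        rng = np.random.default_rng(0)
        rows = [(f"t{i}", f"m{i}", "T", "M", rng.normal(), 0.0) for i in range(10)]
        net = build_network(_edges(rows), -np.inf)
        assert net.graph.number_of_edges() == 10

    def test_duplicate_pairs_rejected(self):
        edges = _edges([
            ("t1", "m1", "T", "M", 0.6, 0.4),
            ("m1", "t1", "M", "T", 0.7, 0.4),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            build_network(edges, 0.5)


def _random_tripartite(n_t, n_m, n_p, prob, seed):
    rng = np.random.default_rng(seed)
    nodes = (
        [(f"t{i}", "T") for i in range(n_t)]
        + [(f"m{i}", "M") for i in range(n_m)]
        + [(f"p{i}", "PP") for i in range(n_p)]
    )
    rows = []
    for (a, ma), (b, mb) in itertools.combinations(nodes, 2):
        bf = 1.0 if rng.random() < prob else 0.0
        rows.append((a, b, ma, mb, bf, rng.normal()))
    return nodes, _edges(rows)


class TestTriangleEnumeration:
    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(20):
            nodes, edges = _random_tripartite(12, 15, 2, 0.3, seed)
            net = build_network(edges, 0.5, nodes=nodes)
            g = net.graph
            for pp in ("p0", "p1"):
                found = enumerate_tripartite_triangles(net, pp)
                brute = [
                    (t, m)
                    for t, _ in nodes if _ == "T"
                    for m, mm in nodes if mm == "M"
                    if g.has_edge(t, m) and g.has_edge(t, pp) and g.has_edge(m, pp)
                ]
                assert [(x.taxon_node, x.module_node) for x in found] == sorted(brute)

    def test_deterministic_sorted_order_and_no_duplicates(self):
        nodes, edges = _random_tripartite(10, 10, 1, 0.6, 7)
        net = build_network(edges, 0.5, nodes=nodes)
        found = enumerate_tripartite_triangles(net, "p0")
        keys = [(m.taxon_node, m.module_node) for m in found]
        assert keys == sorted(keys)
        assert len(keys) == len(set(keys))

    def test_no_pp_edges_means_no_motifs(self):
        edges = _edges([("t1", "m1", "T", "M", 2.0, 0.5)])
        net = build_network(edges, 0.5, nodes=[("t1", "T"), ("m1", "M"), ("p1", "PP")])
        assert enumerate_tripartite_triangles(net, "p1") == []

    def test_unknown_pp_node_raises(self):
        edges = _edges([("t1", "m1", "T", "M", 2.0, 0.5)])
        net = build_network(edges, 0.5)
        with pytest.raises(KeyError):
            enumerate_tripartite_triangles(net, "nope")

    def test_non_pp_node_rejected(self):
        edges = _edges([("t1", "m1", "T", "M", 2.0, 0.5)])
        net = build_network(edges, 0.5)
        with pytest.raises(ValueError, match="modality"):
            enumerate_tripartite_triangles(net, "t1")

    def test_raising_threshold_never_adds_motifs(self):
        nodes, edges = _random_tripartite(10, 12, 2, 0.5, 3)
        edges["log10_bf"] = np.random.default_rng(3).uniform(0, 3, len(edges))
        counts = []
        for threshold in (0.2, 0.5, 1.0, 2.0):
            net = build_network(edges, threshold, nodes=nodes)
            counts.append(sum(
                len(enumerate_tripartite_triangles(net, p)) for p in ("p0", "p1")
            ))
        assert counts == sorted(counts, reverse=True)

    def test_every_motif_edge_satisfies_threshold(self):
        nodes, edges = _random_tripartite(8, 8, 2, 0.7, 5)
        edges["log10_bf"] = np.random.default_rng(5).uniform(0, 1.5, len(edges))
        net = build_network(edges, 0.5, nodes=nodes)
        for pp in ("p0", "p1"):
            for motif in enumerate_tripartite_triangles(net, pp):
                assert all(e["log10_bf"] >= 0.5 for e in motif.edges)


class TestEstimator:
    def test_fit_reproduces_pipeline_stage(self):
        import pandas as pd

        from microtriad.bayes import joint_edge_matrix
        from microtriad.motifs import TripartiteMotifAnalysis

        rng = np.random.default_rng(4)
        index = [f"s{i}" for i in range(40)]
        blocks = [
            (pd.DataFrame(rng.normal(size=(40, 5)), index=index,
                          columns=[f"t{i}" for i in range(5)]), "T"),
            (pd.DataFrame(rng.normal(size=(40, 6)), index=index,
                          columns=[f"m{i}" for i in range(6)]), "M"),
            (pd.DataFrame(rng.normal(size=(40, 1)), index=index,
                          columns=["p0"]), "PP"),
        ]
        est = TripartiteMotifAnalysis(threshold=0.3).fit(blocks)
        pd.testing.assert_frame_equal(est.edges_, joint_edge_matrix(blocks))
        assert set(est.motifs_) == {"p0"}
        assert est.summaries_["p0"] == summarize_motifs(est.motifs_["p0"])
        # isolated nodes retained
        assert set(est.network_.nodes) == {f"t{i}" for i in range(5)} \
            | {f"m{i}" for i in range(6)} | {"p0"}

    def test_get_set_params(self):
        from microtriad.motifs import TripartiteMotifAnalysis

        est = TripartiteMotifAnalysis()
        assert est.get_params() == {
            "threshold": 0.5, "rscale": 0.354, "method": "regression",
        }
        est.set_params(threshold=1.0)
        assert est.threshold == 1.0
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


class TestReports:
    @pytest.fixture
    def motifs(self):
        nodes, edges = _random_tripartite(6, 6, 1, 0.8, 9)
        net = build_network(edges, 0.5, nodes=nodes)
        return enumerate_tripartite_triangles(net, "p0")

    def test_three_rows_per_motif(self, motifs):
        table = motif_table(motifs)
        assert len(table) == 3 * len(motifs)
        assert list(table.columns) == ["motif", "node_a", "node_b", "log10_bf", "rho"]

    def test_direction_pattern_records_signs(self, motifs):
        motif = motifs[0]
        expected = tuple(int(np.sign(e["rho"])) for e in motif.edges)
        assert motif.direction_pattern == expected

    def test_summaries_are_set_cardinalities(self, motifs):
        summary = summarize_motifs(motifs)
        assert summary["n_motifs"] == len(motifs)
        assert summary["n_taxa"] == len({m.taxon_node for m in motifs})
        assert summary["n_modules"] == len({m.module_node for m in motifs})
        assert summarize_motifs([]) == {"n_motifs": 0, "n_taxa": 0, "n_modules": 0}

    def test_network_export_formats(self, tmp_path, motifs):
        import networkx as nx

        nodes, edges = _random_tripartite(6, 6, 1, 0.8, 9)
        net = build_network(edges, 0.5, nodes=nodes)
        write_network(net, tmp_path / "net.graphml", fmt="graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_edges() == net.graph.number_of_edges()
        write_network(net, tmp_path / "net.tsv", fmt="tsv")
        exported = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(exported) == net.graph.number_of_edges()
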