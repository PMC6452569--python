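"""Graph loading, node-cost schemes, constrained shortest paths (against an
exhaustive simple-path oracle), retention, union assembly, and export."""

import itertools

import networkx as nx
import numpy as np
import pytest

from laborsig import netbuild, simulate, svd
from laborsig.netbuild import (
    NetworkValidationError,
    SignalingGraph,
    assign_node_costs,
    build_parturition_network,
    constrained_shortest_path,
    export_network,
    load_signaling_network,
    select_sink_genes,
)


def graph_from(edges, tf_edges, node_costs=None, sources=None):
    sg = SignalingGraph.from_edges(edges, tf_edges, sources=sources)
    sg.node_cost = {n: 0.0 for n in sg.graph.nodes}
    if node_costs:
        sg.node_cost.update(node_costs)
    return sg


def enumerate_oracle(sg, source, sink):
    """Minimum cost over ALL simple source->sink paths ending in a TF edge."""
    best = None
    for path in nx.all_simple_paths(sg.graph, source, sink):
        if (path[-2], path[-1]) not in sg.tf_edges:
            continue
        cost = sum(sg.cost(n) for n in path) + sum(
            sg.graph.edges[a, b]["cost"] for a, b in zip(path, path[1:])
        )
        cand = (cost, tuple(path))
        if best is None or cand < best:
            best = cand
    return best


class TestLoading:
    def test_confidence_to_cost_transform(self):
        sg = graph_from([("A", "B", 0.8)], [])
        assert sg.graph.edges["A", "B"]["cost"] == pytest.approx(0.2)

    def test_duplicate_edges_keep_max_confidence(self):
        sg = graph_from([("A", "B", 0.5), ("A", "B", 0.9)], [])
        assert sg.graph.number_of_edges() == 1
        assert sg.graph.edges["A", "B"]["confidence"] == 0.9

    def test_tf_edge_missing_from_edge_list_rejected(self):
        with pytest.raises(NetworkValidationError, match="absent"):
            SignalingGraph.from_edges([("A", "B", 0.8)], [("T", "G")])

    def test_bad_confidence_and_self_loop_rejected(self):
        with pytest.raises(NetworkValidationError):
            SignalingGraph.from_edges([("A", "B", 1.5)], [])
        with pytest.raises(NetworkValidationError):
            SignalingGraph.from_edges([("A", "A", 0.5)], [])

    def test_file_round_trip(self, tmp_path, network):
        e, t = tmp_path / "e.tsv", tmp_path / "t.tsv"
        network.write_edge_lists(e, t)
        back = load_signaling_network(e, t)
        assert sorted(back.graph.edges(data="confidence")) == sorted(
            network.graph.edges(data="confidence")
        )
        assert back.tf_edges == network.tf_edges


class TestNodeCostSchemes:
    def test_general_worked_vector(self):
        sg = graph_from([("a", "b", 0.5), ("b", "c", 0.5)], [])
        out = assign_node_costs(sg, {"a": -1.0, "b": 0.0, "c": 1.0}, "general")
        assert out.node_cost["a"] == pytest.approx(0.0)
        assert out.node_cost["b"] == pytest.approx(1.0)
        assert out.node_cost["c"] == pytest.approx(0.0)

    def test_phenotype_worked_vectors(self):
        sg = graph_from([("a", "b", 0.5), ("b", "c", 0.5)], [])
        nl = assign_node_costs(sg, {"a": -2.0, "b": 0.0, "c": 2.0}, "non_labor")
        assert [nl.node_cost[k] for k in "abc"] == pytest.approx([0.0, 0.5, 1.0])
        lab = assign_node_costs(sg, {"a": -2.0, "b": 0.0, "c": 2.0}, "labor")
        assert [lab.node_cost[k] for k in "abc"] == pytest.approx([1.0, 0.5, 0.0])

    def test_scheme_antisymmetry(self):
        rng = np.random.default_rng(4)
        loadings = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=40))}
        edges = [(f"g{i}", f"g{i+1}", 0.5) for i in range(39)]
        sg = graph_from(edges, [])
        nl = assign_node_costs(sg, loadings, "non_labor")
        lab = assign_node_costs(sg, loadings, "labor")
        for g in loadings:
            assert nl.node_cost[g] + lab.node_cost[g] == pytest.approx(1.0)

    def test_all_equal_loadings_degenerate_midpoint(self):
        sg = graph_from([("a", "b", 0.5)], [])
        out = assign_node_costs(sg, {"a": 2.0, "b": 2.0}, "general")
        assert out.node_cost["a"] == 0.5 and out.node_cost["b"] == 0.5

    def test_missing_loading_gets_maximal_cost(self):
        sg = graph_from([("a", "b", 0.5), ("b", "x", 0.5)], [])
        out = assign_node_costs(sg, {"a": -1.0, "b": 1.0}, "general")
        assert out.node_cost["x"] == 1.0

    def test_unknown_scheme_rejected(self):
        sg = graph_from([("a", "b", 0.5)], [])
        with pytest.raises(ValueError):
            assign_node_costs(sg, {"a": 1.0}, "mystery")


class TestSinkSelection:
    def test_worked_examples(self):
        loadings = {"a": -3.0, "b": 2.0, "c": 0.5}
        assert select_sink_genes(loadings, 1, "general")[0] == ["a", "b"]
        assert select_sink_genes(loadings, 1, "labor")[0] == ["b"]
        assert select_sink_genes(loadings, 1, "non_labor")[0] == ["a"]

    def test_graph_restriction_reports_uncoverable(self):
        sg = graph_from([("T", "a", 0.9), ("x", "T", 0.9)], [("T", "a")])
        sinks, uncoverable = select_sink_genes(
            {"a": -3.0, "b": 2.0}, 1, "general", graph=sg
        )
        assert sinks == ["a"] and uncoverable == ["b"]

    def test_truncation_warns(self):
        with pytest.warns(UserWarning):
            sinks, _ = select_sink_genes({"a": 1.0, "b": -1.0}, 5, "general")
        assert sorted(sinks) == ["a", "b"]


class TestConstrainedShortestPath:
    def test_simple_chain(self):
        sg = graph_from(
            [("S", "T", 1e-9), ("T", "G", 1e-9)], [("T", "G")]
        )
        for e in sg.graph.edges:
            sg.graph.edges[e]["cost"] = 1.0
        rec = constrained_shortest_path(sg, "S", "G")
        assert rec.nodes == ["S", "T", "G"]
        assert rec.cost == pytest.approx(2.0)

    def test_tf_constraint_excludes_equal_cost_alternative(self):
        edges = [("S", "X", 0.5), ("X", "G", 0.5), ("S", "T", 0.5), ("T", "G", 0.5)]
        sg = graph_from(edges, [("T", "G")])
        rec = constrained_shortest_path(sg, "S", "G")
        assert rec.nodes == ["S", "T", "G"]

    def test_no_tf_in_edge_is_unreachable(self):
        sg = graph_from([("S", "G", 0.9)], [])
        assert constrained_shortest_path(sg, "S", "G") is None

    def test_cost_recomputes_from_graph(self, network, combined, svd_result):
        loadings = svd_result.eigensample(1).to_dict()
        costed = assign_node_costs(network, loadings, "general")
        sink = next(g for (_, g) in sorted(costed.tf_edges))
        rec = constrained_shortest_path(costed, costed.sources[0], sink)
        recomputed = sum(costed.cost(n) for n in rec.nodes) + sum(
            costed.graph.edges[a, b]["cost"] for a, b in zip(rec.nodes, rec.nodes[1:])
        )
        assert rec.cost == pytest.approx(recomputed, abs=1e-10)

    def test_lexicographic_tie_break(self):
        # two equal-cost admissible paths; the lexicographically smaller wins
        edges = [("S", "A", 0.5), ("A", "G", 0.5), ("S", "B", 0.5), ("B", "G", 0.5)]
        sg = graph_from(edges, [("A", "G"), ("B", "G")])
        rec = constrained_shortest_path(sg, "S", "G")
        assert rec.nodes == ["S", "A", "G"]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(6, 13))
        nodes = [f"n{i}" for i in range(n)]
        edges = []
        for a, b in itertools.permutations(nodes, 2):
            if rng.random() < 0.25:
                edges.append((a, b, float(rng.uniform(0.05, 1.0))))
        if not edges:
            return
        tf_edges = [e[:2] for e in edges if rng.random() < 0.3]
        sg = SignalingGraph.from_edges(edges, tf_edges)
        sg.node_cost = {m: float(rng.uniform(0, 1)) for m in sg.graph.nodes}
        present = sorted(sg.graph.nodes)
        for source, sink in itertools.islice(itertools.permutations(present, 2), 12):
            got = constrained_shortest_path(sg, source, sink)
            expected = enumerate_oracle(sg, source, sink)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert got.cost == pytest.approx(expected[0], abs=1e-10)


class TestBuildNetwork:
    def test_retention_rule_exact(self):
        # chain graphs with 10 distinct-cost (source, sink) paths
        edges, tf_edges, sinks = [], [], []
        for i in range(10):
            conf = 0.95 - i * 0.05
            edges += [("S", f"t{i}", conf), (f"t{i}", f"g{i}", conf)]
            tf_edges.append((f"t{i}", f"g{i}"))
            sinks.append(f"g{i}")
        sg = graph_from(edges, tf_edges)
        net = build_parturition_network(sg, ["S"], sinks, "general", 0.5)
        assert len(net.retained_paths) == 5
        assert len(net.discarded_paths) == 5
        assert max(p.cost for p in net.retained_paths) <= min(
            p.cost for p in net.discarded_paths
        )
        assert {p.sink for p in net.retained_paths} == {f"g{i}" for i in range(5)}

    def test_phenotype_schemes_keep_all_paths(self):
        edges, tf_edges, sinks = [], [], []
        for i in range(3):
            edges += [("S1", f"t{i}", 0.9), ("S2", f"t{i}", 0.8), (f"t{i}", f"g{i}", 0.9)]
            tf_edges.append((f"t{i}", f"g{i}"))
            sinks.append(f"g{i}")
        sg = graph_from(edges, tf_edges)
        for scheme in ("non_labor", "labor"):
            net = build_parturition_network(sg, ["S1", "S2"], sinks, scheme)
            assert len(net.retained_paths) == 6
            assert net.discarded_paths == []

    def test_union_contains_exactly_retained_nodes_with_roles(self):
        edges = [("S", "m", 0.9), ("m", "T", 0.9), ("T", "G", 0.9)]
        sg = graph_from(edges, [("T", "G")])
        net = build_parturition_network(sg, ["S"], ["G"], "labor")
        assert set(net.graph.nodes) == {"S", "m", "T", "G"}
        roles = nx.get_node_attributes(net.graph, "role")
        assert roles == {
            "S": "receptor", "m": "signaling",
            "T": "transcription_factor", "G": "target_gene",
        }

    def test_empty_result_raises(self):
        sg = graph_from([("S", "X", 0.9)], [])
        with pytest.raises(NetworkValidationError):
            build_parturition_network(sg, ["S"], ["X"], "general")

    def test_planted_paths_recovered(self, sim_config, collection, combined, svd_result, network):
        _, truth = collection
        loadings = svd_result.eigensample(1).to_dict()
        costed = assign_node_costs(network, loadings, "general")
        sinks, _ = select_sink_genes(
            {g: v for g, v in loadings.items() if g in network.nodes},
            n_per_side=25, scheme="general", graph=network,
        )
        net = build_parturition_network(costed, network.sources, sinks, "general", 0.5)
        retained = {tuple(p.nodes) for p in net.retained_paths}
        hits = sum(tuple(p) in retained for p in truth.planted_active_paths)
        assert hits / len(truth.planted_active_paths) >= 0.9


class TestExport:
    def test_export_files_and_graphml_round_trip(self, tmp_path):
        edges = [("S", "T", 0.9), ("T", "G", 0.8)]
        sg = graph_from(edges, [("T", "G")])
        net = build_parturition_network(sg, ["S"], ["G"], "labor")
        files = export_network(net, tmp_path)
        sif = (tmp_path / "network_labor.sif").read_text().strip().splitlines()
        assert len(sif) == 2  # 3-node single path -> 2 interactions
        back = nx.read_graphml(files["graphml"])
        assert back.number_of_nodes() == net.graph.number_of_nodes()
        assert back.number_of_edges() == net.graph.number_of_edges()
        node_table = (tmp_path / "network_labor_nodes.tsv").read_text()
        for node in net.graph.nodes:
            assert node in node_table
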