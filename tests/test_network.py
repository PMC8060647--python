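"""Six-metric centralities, above-median hub extraction, tripartite network, exports."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from oracles import naive_centralities

from netpharm.genesets import intersect_targets, merge_sources
from netpharm.network import (
    METRICS,
    build_ppi,
    build_tripartite,
    compute_centralities,
    export_network,
    extract_core,
    median_filter_step,
    rank_compounds_by_degree,
    read_sif,
)
from netpharm.records import CompoundRecord, GeneSet, TargetAssociation
from netpharm.screen import collect_targets, screen_compounds


def graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestCentralities:
    def test_path_graph_hand_values(self):
        t = compute_centralities(graph([("a", "b"), ("b", "c")]))
        assert t.loc[["a", "b", "c"], "DC"].tolist() == [1, 2, 1]
        assert t.loc["b", "BC"] == pytest.approx(1.0)
        assert t.loc["a", "BC"] == 0 and t.loc["c", "BC"] == 0
        assert t.loc["b", "CC"] == pytest.approx(1.0)
        assert t.loc["a", "CC"] == pytest.approx(2 / 3)
        # adjacency eigenvector ~ (1, sqrt(2), 1), lambda = sqrt(2)
        assert t.loc["a", "EC"] == pytest.approx(0.5, abs=1e-9)
        assert t.loc["b", "EC"] == pytest.approx(math.sqrt(0.5), abs=1e-9)

    def test_triangle_lac_nc(self):
        t = compute_centralities(graph([("a", "b"), ("b", "c"), ("a", "c")]))
        assert np.allclose(t["LAC"], 1.0)
        assert np.allclose(t["NC"], 2.0)

    def test_star_no_triangles(self):
        t = compute_centralities(nx.star_graph(3))
        assert t.loc[0, "BC"] == pytest.approx(3.0)
        assert np.allclose(t["LAC"], 0.0) and np.allclose(t["NC"], 0.0)

    def test_degree_one_bc_zero_and_positive_ec_on_connected(self):
        g = random_graph(99, n_max=20)
        comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        t = compute_centralities(comp)
        assert (t["EC"] > 0).all()
        leaves = [v for v in comp if comp.degree(v) == 1]
        assert (t.loc[leaves, "BC"] == 0).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_oracle_on_random_graphs(self, seed):
        g = random_graph(seed, n_max=25)
        t = compute_centralities(g)
        ref = naive_centralities(g)
        for metric in METRICS:
            for v in g.nodes:
                assert t.loc[v, metric] == pytest.approx(ref[metric][v], abs=1e-9), (
                    metric,
                    v,
                )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            compute_centralities(nx.Graph())


class TestMedianFilter:
    def test_symmetric_graph_empties(self):
        g = nx.complete_graph(6)
        out = median_filter_step(g, compute_centralities(g))
        assert out.number_of_nodes() == 0

    def test_lollipop_ties_at_median_are_excluded(self):
        # triangle a,b,c plus pendant path c-d-e: c exceeds the DC/BC/CC/EC
        # medians but only TIES the LAC (2/3) and NC (2) medians, so the
        # strict rule keeps nothing — verified against the naive oracle
        g = graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")])
        t = compute_centralities(g)
        ref = naive_centralities(g)
        med = {m: np.median(sorted(ref[m].values())) for m in METRICS}
        expected = {
            v for v in g.nodes if all(ref[m][v] > med[m] for m in METRICS)
        }
        out = median_filter_step(g, t)
        assert set(out.nodes) == expected == set()
        strict_4 = {
            v for v in g.nodes
            if all(ref[m][v] > med[m] for m in ("DC", "BC", "CC", "EC"))
        }
        assert strict_4 == {"c"}

    @pytest.mark.parametrize("seed", range(8))
    def test_rank_invariance_under_monotone_transforms(self, seed):
        g = random_graph(seed + 500, n_max=25)
        t = compute_centralities(g)
        kept = set(median_filter_step(g, t).nodes)
        warped = t.copy()
        warped["DC"] = np.exp(warped["DC"])
        warped["BC"] = warped["BC"] ** 3 + 2 * warped["BC"]
        warped["CC"] = 5 * warped["CC"] + 1
        warped["EC"] = np.arctan(warped["EC"])
        warped["LAC"] = warped["LAC"] ** 1.5
        warped["NC"] = np.log1p(warped["NC"])
        assert set(median_filter_step(g, warped).nodes) == kept

    def test_table_graph_mismatch_rejected(self):
        g = graph([("a", "b")])
        t = compute_centralities(g)
        with pytest.raises(ValueError):
            median_filter_step(graph([("a", "c")]), t)


class TestExtractCore:
    def test_complete_graph_truncates_at_step_one(self):
        result = extract_core(nx.complete_graph(6))
        assert result.truncated
        assert result.steps == ()
        assert set(result.core.nodes) == set(range(6))  # last nonempty = primary

    def test_nested_chain_and_induced_edges(self):
        g = random_graph(1234, n_max=30)
        result = extract_core(g, steps=3)
        prev = set(g.nodes)
        for step in result.steps:
            cur = set(step.graph.nodes)
            assert cur <= prev
            induced = g.subgraph(cur)
            assert set(map(frozenset, step.graph.edges)) == set(
                map(frozenset, induced.edges)
            )
            prev = cur

    def test_recovers_planted_core(self):
        # median Jaccard over a small seed ensemble; the full 100-seed
        # version runs in the acceptance suite
        from netpharm.synthetic import gen_ppi_planted_core

        jaccs = []
        for seed in range(15):
            g, core = gen_ppi_planted_core(150, 23, 0.8, 0.05, seed)
            found = set(extract_core(g).core.nodes)
            jaccs.append(len(found & core) / len(found | core))
        assert np.median(jaccs) >= 0.6

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            extract_core(nx.complete_graph(3), steps=0)


def _mini_net():
    screened = [
        CompoundRecord("C1", "herbA", "quercetin", 50, 0.5),
        CompoundRecord("C2", "herbA", "kaempferol", 50, 0.5),
        CompoundRecord("C3", "herbB", "luteolin", 50, 0.5),
    ]
    assoc = [
        TargetAssociation("C1", "X"),
        TargetAssociation("C1", "Y"),
        TargetAssociation("C2", "Y"),
        TargetAssociation("C3", "Z"),  # outside intersection
    ]
    inter = GeneSet.from_symbols("i", ["X", "Y"])
    return screened, assoc, inter


class TestTripartite:
    def test_single_compound_single_target(self):
        screened, assoc, _ = _mini_net()
        net = build_tripartite(screened[:1], assoc[:1], GeneSet.from_symbols("i", ["X"]))
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 2
        layers = nx.get_node_attributes(net, "layer")
        assert sorted(layers.values()) == ["compound", "herb", "target"]

    def test_compound_outside_intersection_absent(self):
        screened, assoc, inter = _mini_net()
        net = build_tripartite(screened, assoc, inter)
        assert "C3" not in net
        assert all(d > 0 for _, d in net.degree)
        # no intra-layer edges
        layers = nx.get_node_attributes(net, "layer")
        assert all(layers[a] != layers[b] for a, b in net.edges)

    def test_compound_layer_matches_effective_compounds(self, bundle):
        from netpharm.genesets import effective_compounds

        screened = screen_compounds(list(bundle.compound_table))
        disease = merge_sources(bundle.disease_sources)
        inter = intersect_targets(
            collect_targets(screened, bundle.associations), disease
        )
        net = build_tripartite(screened, bundle.associations, inter)
        layers = nx.get_node_attributes(net, "layer")
        compounds = {v for v, l in layers.items() if l == "compound"}
        eff = {r.compound_id for r in effective_compounds(inter, bundle.associations, screened)}
        assert compounds == eff

    def test_ranking_matches_brute_force_and_breaks_ties_by_name(self, bundle):
        screened, assoc, inter = _mini_net()
        net = build_tripartite(screened, assoc, inter)
        # C1 hits 2 targets; C2 and C3(absent): top-1 is C1
        assert rank_compounds_by_degree(net, 1) == ["C1"]
        # full bundle: brute-force sort oracle
        screened = screen_compounds(list(bundle.compound_table))
        disease = merge_sources(bundle.disease_sources)
        inter = intersect_targets(collect_targets(screened, bundle.associations), disease)
        net = build_tripartite(screened, bundle.associations, inter)
        layers = nx.get_node_attributes(net, "layer")
        deg = {
            v: sum(1 for u in net.adj[v] if layers[u] == "target")
            for v, l in layers.items()
            if l == "compound"
        }
        names = {v: net.nodes[v]["name"] for v in deg}
        expected = [v for v in sorted(deg, key=lambda v: (-deg[v], names[v]))][:10]
        assert rank_compounds_by_degree(net, 10) == expected

    def test_rank_rejects_nonpositive_k(self):
        screened, assoc, inter = _mini_net()
        with pytest.raises(ValueError):
            rank_compounds_by_degree(build_tripartite(screened, assoc, inter), 0)


class TestExport:
    def test_empty_graph_roundtrip(self, tmp_path):
        p = tmp_path / "empty.sif"
        export_network(nx.Graph(), "sif", p)
        assert read_sif(p).number_of_nodes() == 0

    def test_k3_sif_lines(self, tmp_path):
        p = tmp_path / "k3.sif"
        export_network(nx.complete_graph(3), "sif", p)
        assert len(p.read_text().splitlines()) == 3

    @pytest.mark.parametrize("fmt", ["sif", "graphml"])
    def test_roundtrip_identity_on_random_graph(self, tmp_path, fmt):
        g = random_graph(7, n_max=20)
        p = tmp_path / f"g.{fmt}"
        export_network(g, fmt, p)
        back = read_sif(p) if fmt == "sif" else nx.read_graphml(p)
        assert {str(v) for v in back.nodes} == {str(v) for v in g.nodes}
        assert {frozenset(map(str, e)) for e in back.edges} == {
            frozenset(map(str, e)) for e in g.edges
        }

    def test_tripartite_sif_interaction_types(self, tmp_path):
        screened, assoc, inter = _mini_net()
        net = build_tripartite(screened, assoc, inter)
        p = tmp_path / "net.sif"
        export_network(net, "sif", p)
        kinds = {line.split("\t")[1] for line in p.read_text().splitlines()}
        assert kinds == {"hc", "ct"}

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(nx.Graph(), "gexf", tmp_path / "x")

    def test_min_confidence_filter(self):
        edges = [("A", "B", 0.9), ("B", "C", 0.2), ("C", "C", 1.0)]
        g = build_ppi(edges)
        assert g.number_of_edges() == 2  # self-loop dropped
        assert build_ppi(edges, min_confidence=0.5).number_of_edges() == 1
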