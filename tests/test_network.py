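"""KGML parsing, biograph merging, shortest paths, subnetwork extraction."""

import numpy as np
import pytest

from helpers import floyd_warshall, shortest_paths_enumerated
from nmrpath import network as net
from nmrpath import synthdata as syn
from nmrpath.errors import ArgumentError, GraphLookupError, MergeError, ParseError

CHAIN = syn.PathwayTopology(
    pathway_id="chain",
    name="chain pathway",
    compounds=["M1", "M2", "M3"],
    enzymes=["E1", "E2"],
    links=[("M1", "E1"), ("M2", "E1"), ("M2", "E2"), ("M3", "E2")],
)


@pytest.fixture
def chain_graph(tmp_path):
    (path,) = syn.make_toy_kgml([CHAIN], tmp_path)
    return net.build_biograph([net.parse_kgml(path)])


class TestParse:
    def test_chain_counts(self, chain_graph):
        assert chain_graph.counts == {
            "n_pathways": 1,
            "n_metabolites": 3,
            "n_enzymes": 2,
            "n_relations": 4,
        }

    def test_isolated_compound_kept_with_degree_zero(self, tmp_path):
        topo = syn.PathwayTopology("p", "x", ["M1", "M2", "LONER"], ["E1"],
                                   [("M1", "E1"), ("M2", "E1")])
        (path,) = syn.make_toy_kgml([topo], tmp_path)
        frag = net.parse_kgml(path)
        assert "LONER" in frag.graph
        assert frag.graph.degree["LONER"] == 0

    def test_malformed_xml_reported_with_file(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<pathway><entry id='1'")
        with pytest.raises(ParseError, match="bad.xml"):
            net.parse_kgml(bad)

    def test_unknown_entry_type_rejected(self, tmp_path):
        bad = tmp_path / "weird.xml"
        bad.write_text(
            '<pathway name="path:p1" title="t">'
            '<entry id="1" name="cpd:C1" type="wormhole"/></pathway>'
        )
        with pytest.raises(ParseError, match="wormhole"):
            net.parse_kgml(bad)

    def test_relation_compound_subtype_creates_edges(self, tmp_path):
        doc = (
            '<pathway name="path:p1" title="t">'
            '<entry id="1" name="ec:E1" type="enzyme"/>'
            '<entry id="2" name="ec:E2" type="gene"/>'
            '<entry id="3" name="cpd:C1" type="compound"/>'
            '<relation entry1="1" entry2="2" type="ECrel">'
            '<subtype name="compound" value="3"/></relation>'
            "</pathway>"
        )
        path = tmp_path / "rel.xml"
        path.write_text(doc)
        frag = net.parse_kgml(path)
        assert set(frag.graph.edges) == {("E1", "C1"), ("E2", "C1")} or set(
            frag.graph.edges
        ) == {("C1", "E1"), ("C1", "E2")}


class TestBuildBiograph:
    def test_disjoint_fragments_stay_disjoint(self, tmp_path):
        import networkx as nx

        topos = [
            syn.PathwayTopology("p1", "a", ["A1", "A2"], ["EA"], [("A1", "EA"), ("A2", "EA")]),
            syn.PathwayTopology("p2", "b", ["B1", "B2"], ["EB"], [("B1", "EB"), ("B2", "EB")]),
        ]
        files = syn.make_toy_kgml(topos, tmp_path)
        g = net.build_biograph([net.parse_kgml(f) for f in files])
        assert nx.number_connected_components(g.graph) == 2

    def test_conflicting_types_across_files_rejected(self, tmp_path):
        a = tmp_path / "a.xml"
        b = tmp_path / "b.xml"
        a.write_text('<pathway name="path:a" title="a"><entry id="1" name="cpd:X" type="compound"/></pathway>')
        b.write_text('<pathway name="path:b" title="b"><entry id="1" name="ec:X" type="enzyme"/></pathway>')
        with pytest.raises(MergeError, match="X"):
            net.build_biograph([net.parse_kgml(a), net.parse_kgml(b)])

    def test_counts_match_generator_declared_totals(self, tmp_path):
        topos = syn.random_pathway_topologies(70, seed=5)
        files = syn.make_toy_kgml(topos, tmp_path)
        g = net.build_biograph([net.parse_kgml(f) for f in files])
        all_compounds = {c for t in topos for c in t.compounds}
        all_enzymes = {e for t in topos for e in t.enzymes}
        all_links = {(c, e) for t in topos for c, e in t.links}
        assert g.counts["n_pathways"] == 70
        assert g.counts["n_metabolites"] == len(all_compounds)
        assert g.counts["n_enzymes"] == len(all_enzymes)
        assert g.counts["n_relations"] == len(all_links)

    def test_biograph_is_bipartite(self, tmp_path):
        topos = syn.random_pathway_topologies(10, seed=1)
        files = syn.make_toy_kgml(topos, tmp_path)
        g = net.build_biograph([net.parse_kgml(f) for f in files])
        assert g.is_bipartite()


class TestShortestPaths:
    def test_self_distance_zero(self, chain_graph):
        assert net.shortest_path_length(chain_graph, "M1", "M1") == 0

    def test_chain_end_to_end_distance_four(self, chain_graph):
        assert net.shortest_path_length(chain_graph, "M1", "M3") == 4

    def test_missing_node_raises_lookup_not_unreachable(self, chain_graph):
        with pytest.raises(GraphLookupError):
            net.shortest_path_length(chain_graph, "M1", "NOPE")

    def test_unreachable_is_infinite(self, tmp_path):
        topos = [
            syn.PathwayTopology("p1", "a", ["A1", "A2"], ["EA"], [("A1", "EA"), ("A2", "EA")]),
            syn.PathwayTopology("p2", "b", ["B1", "B2"], ["EB"], [("B1", "EB"), ("B2", "EB")]),
        ]
        files = syn.make_toy_kgml(topos, tmp_path)
        g = net.build_biograph([net.parse_kgml(f) for f in files])
        assert net.shortest_path_length(g, "A1", "B1") == float("inf")

    def test_metabolite_distances_are_even(self, tmp_path):
        topos = syn.random_pathway_topologies(4, seed=3)
        files = syn.make_toy_kgml(topos, tmp_path)
        g = net.build_biograph([net.parse_kgml(f) for f in files])
        mets = g.metabolites()
        for a in mets[:5]:
            for b in mets[:5]:
                d = net.shortest_path_length(g, a, b)
                if np.isfinite(d):
                    assert int(d) % 2 == 0

    def test_distances_match_floyd_warshall_oracle(self, tmp_path):
        for seed in range(20):
            topos = syn.random_pathway_topologies(3, seed=seed)
            files = syn.make_toy_kgml(topos, tmp_path / f"s{seed}")
            g = net.build_biograph([net.parse_kgml(f) for f in files])
            nodes = sorted(g.graph.nodes)
            dist = floyd_warshall(nodes, list(g.graph.edges))
            mets = g.metabolites()
            for a in mets:
                for b in mets:
                    assert net.shortest_path_length(g, a, b) == dist[(a, b)]


class TestExtractSubnetwork:
    def test_single_pair_through_one_enzyme(self, chain_graph):
        netw = net.extract_subnetwork(chain_graph, {("M1", "M2"): 0.95})
        assert set(netw.graph.nodes) == {"M1", "E1", "M2"}
        assert netw.roles == {"M1": "correlated-measured", "M2": "correlated-measured", "E1": "enzyme"}
        relations = [e for e in netw.graph.edges(data=True) if e[2].get("kind") != "correlation"]
        assert len(relations) == 2

    def test_both_equal_length_routes_included(self, tmp_path):
        topo = syn.PathwayTopology(
            "diamond", "d", ["M1", "M2"], ["E1", "E2"],
            [("M1", "E1"), ("M2", "E1"), ("M1", "E2"), ("M2", "E2")],
        )
        (path,) = syn.make_toy_kgml([topo], tmp_path)
        g = net.build_biograph([net.parse_kgml(path)])
        netw = net.extract_subnetwork(g, {("M1", "M2"): 0.9})
        assert {"E1", "E2"} <= set(netw.graph.nodes)

    def test_pair_beyond_max_len_skipped_and_reported(self, chain_graph):
        netw = net.extract_subnetwork(chain_graph, {("M1", "M3"): 0.9}, max_len=2)
        assert netw.skipped_pairs == [("M1", "M3", 4.0)]
        assert "M3" not in netw.graph

    def test_unmapped_metabolite_kept_as_external_node(self, chain_graph):
        netw = net.extract_subnetwork(chain_graph, {("M1", "LDL"): 0.92})
        assert netw.unmapped == ["LDL"]
        assert netw.roles["LDL"] == "external"
        assert netw.graph.edges["M1", "LDL"]["kind"] == "correlation"

    def test_empty_pair_list_rejected(self, chain_graph):
        with pytest.raises(ArgumentError):
            net.extract_subnetwork(chain_graph, {})

    def test_monotone_in_the_pair_set(self, tmp_path):
        topos = syn.random_pathway_topologies(3, seed=9)
        files = syn.make_toy_kgml(topos, tmp_path)
        g = net.build_biograph([net.parse_kgml(f) for f in files])
        mets = g.metabolites()
        pairs = {}
        prev_nodes: set = set()
        for a, b in [(mets[0], mets[1]), (mets[2], mets[3]), (mets[1], mets[4])]:
            pairs[(a, b)] = 0.9
            netw = net.extract_subnetwork(g, dict(pairs))
            assert prev_nodes <= set(netw.graph.nodes)
            prev_nodes = set(netw.graph.nodes)

    def test_intermediates_match_enumeration_oracle(self, tmp_path):
        for seed in (0, 1, 2):
            topos = syn.random_pathway_topologies(2, seed=seed, n_compounds=(4, 6))
            files = syn.make_toy_kgml(topos, tmp_path / f"s{seed}")
            g = net.build_biograph([net.parse_kgml(f) for f in files])
            mets = g.metabolites()
            pairs = {(mets[0], mets[-1]): 0.9}
            netw = net.extract_subnetwork(g, pairs)
            expected_interior = set()
            for p in shortest_paths_enumerated(g.graph, mets[0], mets[-1]):
                for node in p[1:-1]:
                    if g.graph.nodes[node]["type"] == "metabolite":
                        expected_interior.add(node)
            got = {n for n, r in netw.roles.items() if r == "intermediate"}
            assert got == expected_interior

    def test_direction_labels_attached(self, chain_graph):
        netw = net.extract_subnetwork(
            chain_graph, {("M1", "M2"): 0.95}, directions={"M1": "up", "M2": "down"}
        )
        assert netw.directions == {"M1": "up", "M2": "down"}


def test_write_outputs_produces_graphml_sif_manifest(chain_graph, tmp_path):
    netw = net.extract_subnetwork(chain_graph, {("M1", "M2"): 0.95})
    net.write_outputs(netw, tmp_path, "stage")
    assert (tmp_path / "stage.graphml").exists()
    sif = (tmp_path / "stage.sif").read_text().strip().splitlines()
    assert len(sif) == 3  # two relations plus the correlation edge
    import json

    manifest = json.loads((tmp_path / "stage.json").read_text())
    assert manifest["counts"]["n_enzymes"] == 1
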