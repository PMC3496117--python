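"""FI-network container, component extraction, gene mapping, and I/O."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fimodules.network import (
    FINetwork,
    NetworkParseError,
    export_network,
    largest_connected_component,
    load_network,
    map_genes,
)

gene_names = st.text(alphabet="ABCDEFGH", min_size=1, max_size=2)


class TestLoading:
    def test_duplicate_rows_collapse(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tC\nA\tB\n")
        net = load_network(p)
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {("A", "B"), ("B", "C")}

    def test_self_loop_dropped_and_logged(self, tmp_path, caplog):
        p = tmp_path / "net.tsv"
        p.write_text("A\tA\nA\tB\n")
        with caplog.at_level("INFO", logger="fimodules.network"):
            net = load_network(p)
        assert net.edges == {("A", "B")}
        assert any("self-loop" in rec.message for rec in caplog.records)

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nJUSTONE\n")
        with pytest.raises(NetworkParseError, match="line 2"):
            load_network(p)

    def test_empty_network_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# nothing here\n")
        with pytest.raises(NetworkParseError):
            load_network(p)

    def test_symbols_case_normalized(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("tnf\tTRAF2\nTnf\tbirc3\n")
        net = load_network(p)
        assert net.nodes == {"TNF", "TRAF2", "BIRC3"}

    def test_header_row_skipped(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("gene_a\tgene_b\nA\tB\n")
        assert load_network(p).edges == {("A", "B")}

    def test_sif_round_trip(self, toy_net, tmp_path):
        export_network(toy_net, path=tmp_path / "out")
        again = load_network(tmp_path / "out.sif")
        assert again.nodes == toy_net.nodes and again.edges == toy_net.edges


class TestGraphMLRoundTrip:
    def test_graph_and_annotations_preserved(self, tmp_path):
        net = FINetwork.from_edges(
            [("TNF", "TNFR1"), ("TNF", "TNFR2"), ("TRAF2", "TNFR2")],
            annotations={("TNF", "TNFR1"): "activates", ("TRAF2", "TNFR2"): "inhibits"},
        )
        export_network(net, node_roles={"TRAF2": "linker"}, path=tmp_path / "n")
        again = load_network(tmp_path / "n.graphml")
        assert again == net

    def test_load_export_load_idempotent(self, toy_net, tmp_path):
        export_network(toy_net, path=tmp_path / "a")
        first = load_network(tmp_path / "a.graphml")
        export_network(first, path=tmp_path / "b")
        assert load_network(tmp_path / "b.graphml") == first == toy_net


class TestLargestComponent:
    def test_picks_bigger_component(self, toy_net):
        lcc = largest_connected_component(toy_net)
        assert lcc.nodes == {"A", "B", "C", "D", "E"}

    def test_connected_graph_is_identity(self):
        net = FINetwork.from_edges([("A", "B"), ("B", "C")])
        assert largest_connected_component(net) == net

    def test_size_tie_broken_lexicographically(self):
        net = FINetwork.from_edges([("B", "C"), ("A", "D")])
        assert largest_connected_component(net).nodes == {"A", "D"}

    def test_matches_bfs_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        g = nx.gnp_random_graph(50, 0.04, seed=7)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        g.add_edge("N00", "N01")  # at least one edge
        net = FINetwork(g)

        # independent flood-fill labeling
        unvisited = set(g.nodes)
        comps = []
        while unvisited:
            start = unvisited.pop()
            stack, comp = [start], {start}
            while stack:
                for w in g[stack.pop()]:
                    if w in unvisited:
                        unvisited.discard(w)
                        comp.add(w)
                        stack.append(w)
            comps.append(comp)
        assert largest_connected_component(net).nodes == frozenset(
            max(comps, key=len)
        )

    def test_components_partition_nodes(self, toy_net):
        comps = toy_net.connected_components()
        assert sum(len(c) for c in comps) == len(toy_net)
        assert len(comps[0]) == max(len(c) for c in comps)


class TestMapGenes:
    def test_partial_overlap(self):
        net = FINetwork.from_edges([("A", "B"), ("B", "C")])
        m = map_genes(net, ["A", "B", "Z"])
        assert m.in_network == {"A", "B"}
        assert m.coverage_fraction == 0.667

    def test_full_overlap_is_one(self):
        net = FINetwork.from_edges([("A", "B")])
        assert map_genes(net, ["a", "b"]).coverage_fraction == 1.0

    def test_empty_query_rejected(self, toy_net):
        with pytest.raises(ValueError):
            map_genes(toy_net, [])

    def test_matches_set_intersection_oracle(self, toy_net):
        rng = np.random.default_rng(5)
        universe = sorted(toy_net.nodes) + ["Q", "R", "S"]
        for _ in range(50):
            query = list(rng.choice(universe, size=rng.integers(1, 8)))
            m = map_genes(toy_net, query)
            assert m.in_network == set(query) & set(toy_net.nodes)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(gene_names, min_size=1, max_size=10))
    def test_coverage_invariant_to_order_and_duplicates(self, query):
        net = FINetwork.from_edges([("A", "B"), ("C", "D")])
        base = map_genes(net, query)
        assert 0.0 <= base.coverage_fraction <= 1.0
        shuffled = map_genes(net, sorted(query, reverse=True) + query)
        assert shuffled.coverage_fraction == base.coverage_fraction


class TestExport:
    def test_two_node_export_rows(self, tmp_path):
        net = FINetwork.from_edges([("A", "B")])
        files = export_network(
            net,
            node_roles={"B": "linker"},
            direction_changes={"A": 2.5},
            path=tmp_path / "net",
        )
        sif = files["sif"].read_text().strip().splitlines()
        assert sif == ["A\tfi\tB"]
        rows = files["nodes"].read_text().strip().splitlines()
        assert rows == ["gene\trole\tdirection", "A\tseed\tup", "B\tlinker\tnone"]

    def test_default_role_is_seed(self, tmp_path):
        net = FINetwork.from_edges([("A", "B")])
        files = export_network(net, path=tmp_path / "net")
        body = files["nodes"].read_text()
        assert body.count("seed") == 2

    def test_unknown_attribute_node_rejected(self, toy_net, tmp_path):
        with pytest.raises(ValueError, match="unknown node"):
            export_network(
                toy_net, node_roles={"NOPE": "seed"}, path=tmp_path / "n"
            )
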