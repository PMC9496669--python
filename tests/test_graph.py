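"""Graph construction and native centrality against independent oracles."""

import math

import numpy as np
import pytest

from msmt_netpharm.cascade import TargetSet
from msmt_netpharm.graph import (
    CentralityTable,
    PPIGraph,
    betweenness_centrality,
    build_graph,
    degree_centrality,
    induced_subgraph,
    normalize_bc,
    read_edge_list,
    remove_isolates,
)

from conftest import matrix_power_bc, random_simple_graph


class TestBuildGraph:
    def test_empty_input_gives_empty_graph(self):
        g = build_graph([])
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_duplicate_and_reversed_rows_collapse(self):
        g = build_graph([("A", "B"), ("B", "A"), ("A", "B")])
        assert g.n_nodes == 2 and g.n_edges == 1

    def test_symbols_normalized_and_self_loops_dropped(self, caplog):
        g = build_graph([(" akt1", "alb "), ("ALB", "ALB")])
        assert g.nodes == {"AKT1", "ALB"}
        assert g.n_edges == 1

    def test_malformed_row_names_line(self):
        with pytest.raises(ValueError, match="row 2"):
            build_graph([("A", "B"), ("A", "B", "C")])

    def test_random_rows_match_set_dedup_oracle(self, rng):
        symbols = [f"S{i:02d}" for i in range(20)]
        rows = [tuple(rng.choice(symbols, size=2, replace=False)) for _ in range(50)]
        g = build_graph(rows)
        oracle_edges = {frozenset(r) for r in rows}
        oracle_nodes = {s for r in rows for s in r}
        assert g.n_edges == len(oracle_edges)
        assert g.n_nodes == len(oracle_nodes)


class TestEdgeListIO:
    def test_reads_string_dialect_with_scores_and_comments(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "protein1\tprotein2\tscore\n# comment\nAKT1\tALB\t0.9\nalb\tIL6\t0.4\n"
        )
        g = read_edge_list(path)
        assert g.nodes == {"AKT1", "ALB", "IL6"} and g.n_edges == 2

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nC\n")
        with pytest.raises(ValueError, match="line 2"):
            read_edge_list(path)


class TestRemoveIsolates:
    def test_five_untouched_members_leave_the_network(self, rng):
        # universe of 342 symbols, 5 of which touch no edge
        symbols = [f"G{i:03d}" for i in range(342)]
        connected, isolated = symbols[:337], symbols[337:]
        rows = list(zip(connected, connected[1:]))
        g = build_graph(rows)
        universe = TargetSet.from_symbols("universe", symbols)
        sub, isolates = remove_isolates(g, universe)
        assert sub.n_nodes == 337
        assert isolates == sorted(isolated)

    def test_fully_connected_graph_has_no_isolates(self, path_graph):
        sub, isolates = remove_isolates(path_graph, TargetSet.from_symbols("u", "ABC"))
        assert isolates == [] and sub.n_nodes == 3

    def test_empty_universe_gives_empty_outputs(self, path_graph):
        sub, isolates = remove_isolates(path_graph, TargetSet.from_symbols("u", []))
        assert sub.n_nodes == 0 and isolates == []

    def test_matches_per_node_degree_scan(self, rng):
        g = random_simple_graph(rng, n_max=12)
        universe = TargetSet.from_symbols("u", list(g.nodes) + ["ZZZZ1", "ZZZZ2"])
        sub, isolates = remove_isolates(g, universe)
        degree = g.degree()
        expected_isolates = sorted(
            s for s in universe.members if degree.get(s, 0) == 0
        )
        assert isolates == expected_isolates
        assert sub.nodes == {s for s in universe.members if degree.get(s, 0) > 0}


class TestDegreeCentrality:
    def test_triangle_and_path(self, path_graph):
        triangle = build_graph([("A", "B"), ("B", "C"), ("C", "A")])
        assert set(degree_centrality(triangle).frame["dc"]) == {2}
        dc = degree_centrality(path_graph).frame["dc"]
        assert dc["B"] == 2 and dc["A"] == dc["C"] == 1

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError, match="empty network"):
            degree_centrality(build_graph([]))

    def test_er_graph_matches_incidence_count_oracle(self, rng):
        g = random_simple_graph(rng, n_max=30)
        dc = degree_centrality(g).frame["dc"]
        for v in g.nodes:
            assert dc[v] == sum(1 for e in g.edges if v in e)

    def test_degree_sum_is_twice_edge_count(self, rng):
        for _ in range(10):
            g = random_simple_graph(rng)
            assert degree_centrality(g).frame["dc"].sum() == 2 * g.n_edges


class TestBetweenness:
    def test_path_middle_node_mediates_one_pair(self, path_graph):
        bc = betweenness_centrality(path_graph).frame["bc_raw"]
        assert bc["B"] == pytest.approx(1.0)
        assert bc["A"] == bc["C"] == 0.0

    def test_star_center_mediates_all_leaf_pairs(self, star_graph):
        bc = betweenness_centrality(star_graph).frame["bc_raw"]
        assert bc["X"] == pytest.approx(3.0)

    def test_four_cycle_split_dependency(self, cycle4_graph):
        bc = betweenness_centrality(cycle4_graph).frame["bc_raw"]
        assert all(v == pytest.approx(0.5) for v in bc)

    def test_matches_matrix_power_oracle_on_random_graphs(self, rng):
        for _ in range(40):
            g = random_simple_graph(rng, n_max=12)
            ours = betweenness_centrality(g).frame["bc_raw"]
            oracle = matrix_power_bc(g)
            for v in g.nodes:
                assert ours[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_matches_networkx_on_medium_graph(self, rng):
        networkx = pytest.importorskip("networkx")
        g = random_simple_graph(rng, n_max=40)
        nxg = networkx.Graph(list(g.edges))
        nxg.add_nodes_from(g.nodes)
        expected = networkx.betweenness_centrality(nxg, normalized=False)
        ours = betweenness_centrality(g).frame["bc_raw"]
        for v in g.nodes:
            assert ours[v] == pytest.approx(expected[v], abs=1e-9)

    def test_disconnected_components_contribute_zero_across(self):
        g = build_graph([("A", "B"), ("B", "C"), ("X", "Y"), ("Y", "Z")])
        bc = betweenness_centrality(g).frame["bc_raw"]
        assert bc["B"] == pytest.approx(1.0) and bc["Y"] == pytest.approx(1.0)

    def test_bit_reproducible_across_runs(self, rng):
        g = random_simple_graph(rng, n_max=25)
        first = betweenness_centrality(g).frame["bc_raw"]
        second = betweenness_centrality(g).frame["bc_raw"]
        assert (first == second).all()


class TestNormalization:
    def test_top_node_is_exactly_one(self, star_graph):
        table = betweenness_centrality(star_graph)
        assert table.frame["bc_norm"].max() == 1.0
        assert table.frame.loc["X", "bc_norm"] == 1.0

    def test_all_zero_stays_zero(self):
        g = build_graph([("A", "B")])
        table = betweenness_centrality(g)
        assert (table.frame["bc_norm"] == 0.0).all()

    def test_algebraic_identity(self, rng):
        g = random_simple_graph(rng, n_max=20)
        table = betweenness_centrality(g)
        peak = table.frame["bc_raw"].max()
        if peak > 0:
            recovered = table.frame["bc_norm"] * peak
            assert np.allclose(recovered, table.frame["bc_raw"], atol=1e-12)

    def test_norm_in_unit_interval_and_ordering_preserved(self, rng):
        g = random_simple_graph(rng, n_max=20)
        frame = betweenness_centrality(g).frame
        assert ((frame["bc_norm"] >= 0) & (frame["bc_norm"] <= 1)).all()
        order_raw = frame["bc_raw"].sort_values(ascending=False).index
        order_norm = frame["bc_norm"].sort_values(ascending=False).index
        assert list(order_raw) == list(order_norm)


class TestTableInvariants:
    def test_ranks_share_value_on_ties(self):
        table = CentralityTable.from_dc({"A": 5, "B": 5, "C": 3})
        ranks = table.frame["dc_rank"]
        assert ranks["A"] == ranks["B"] == 1 and ranks["C"] == 3

    def test_adding_edge_never_decreases_endpoint_degree(self, rng):
        g = random_simple_graph(rng, n_max=15)
        before = degree_centrality(g).frame["dc"]
        missing = [
            (a, b)
            for i, a in enumerate(sorted(g.nodes))
            for b in sorted(g.nodes)[i + 1 :]
            if not g.has_edge(a, b)
        ]
        if not missing:
            pytest.skip("graph already complete")
        a, b = missing[0]
        bigger = PPIGraph(g.nodes, g.edges | {(a, b)})
        after = degree_centrality(bigger).frame["dc"]
        assert after[a] == before[a] + 1 and after[b] == before[b] + 1

    def test_induced_subgraph_keeps_only_internal_edges(self, path_graph):
        sub = induced_subgraph(path_graph, ["A", "B"])
        assert sub.nodes == {"A", "B"} and sub.n_edges == 1
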