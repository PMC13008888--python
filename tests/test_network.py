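import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netpharm.network import (
    EDGE_INTERACTION,
    EDGE_PPI,
    build_network,
    centralities,
    dense_rank,
    write_graphml,
    write_sif,
)


def brute_force_centralities(g: nx.Graph):
    """Independent oracle: Floyd–Warshall distances + shortest-path counting
    by dynamic programming over the distance matrix (no networkx centrality
    code involved)."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = float("inf")
    dist = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for a, b in g.edges:
        dist[idx[a]][idx[b]] = dist[idx[b]][idx[a]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    # number of shortest paths between each pair, by recursion on distance
    npaths = [[0] * n for _ in range(n)]
    for i in range(n):
        npaths[i][i] = 1
    for length in range(1, n):
        for i, j in itertools.product(range(n), range(n)):
            if dist[i][j] == length:
                npaths[i][j] = sum(
                    npaths[i][idx[w]]
                    for w in g.neighbors(nodes[j])
                    if dist[i][idx[w]] == length - 1
                )
    betweenness = {}
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    for v in range(n):
        total = 0.0
        for s, t in itertools.combinations(range(n), 2):
            if s == v or t == v or dist[s][t] == INF:
                continue
            if dist[s][v] + dist[v][t] == dist[s][t]:
                total += npaths[s][v] * npaths[v][t] / npaths[s][t]
        betweenness[nodes[v]] = total / norm
    closeness = {}
    for v in range(n):
        reach = [dist[v][j] for j in range(n) if j != v and dist[v][j] < INF]
        closeness[nodes[v]] = (len(reach) / sum(reach)) if reach else 0.0
    degree = {v: g.degree(v) for v in nodes}
    return degree, betweenness, closeness


def classified(rows):
    return pd.DataFrame(
        rows, columns=["compound_id", "target_id", "mean_score", "classification"]
    )


def ppi(rows):
    return pd.DataFrame(rows, columns=["target_a", "target_b"])


class TestBuildNetwork:
    def test_include_filter_reduces_network(self):
        inter = classified(
            [("c1", "P1", -9.0, "probable_binder"),
             ("c2", "P1", -5.0, "probable_nonbinder"),
             ("c3", "P2", -8.0, "probable_binder")]
        )
        edges = ppi([("P1", "P2")])
        full = build_network(inter, edges,
                             include={"probable_binder", "probable_nonbinder"})
        reduced = build_network(inter, edges)
        assert full.number_of_edges() == 4
        assert reduced.number_of_edges() == 3
        assert "c2" not in reduced

    def test_target_with_no_binders_keeps_only_ppi_edges(self):
        inter = classified([("c1", "P1", -9.0, "probable_binder"),
                            ("c2", "P3", -5.1, "probable_nonbinder")])
        g = build_network(inter, ppi([("P1", "P3"), ("P2", "P3")]))
        assert g.degree("P3") == 2
        assert all(g.edges[e]["edge_type"] == EDGE_PPI for e in g.edges("P3"))

    def test_empty_interactions_leave_protein_only_network(self):
        g = build_network(classified([]), ppi([("P1", "P2")]))
        assert set(g.nodes) == {"P1", "P2"}
        assert g.number_of_edges() == 1

    def test_edge_typing_invariant(self):
        inter = classified([("c1", "P1", -9.0, "probable_binder")])
        g = build_network(inter, ppi([("P1", "P2")]))
        for a, b, data in g.edges(data=True):
            kinds = {g.nodes[a]["node_type"], g.nodes[b]["node_type"]}
            if data["edge_type"] == EDGE_INTERACTION:
                assert kinds == {"compound", "protein"}
            else:
                assert kinds == {"protein"}

    def test_self_loop_ppi_rejected(self):
        with pytest.raises(ValueError):
            build_network(classified([]), ppi([("P1", "P1")]))

    def test_removing_a_compound_never_increases_protein_degree(self):
        inter = classified([("c1", "P1", -9.0, "probable_binder"),
                            ("c2", "P1", -8.5, "probable_binder")])
        edges = ppi([("P1", "P2")])
        g_all = build_network(inter, edges)
        g_less = build_network(inter.iloc[:1], edges)
        assert g_less.degree("P1") <= g_all.degree("P1")


class TestCentralities:
    def test_path_graph_betweenness(self):
        g = build_network(classified([]), ppi([("A", "B"), ("B", "C")]))
        table = centralities(g).set_index("node")
        assert table.loc["B", "betweenness"] == pytest.approx(1.0)
        assert table.loc["A", "betweenness"] == 0.0
        assert table.loc["C", "betweenness"] == 0.0

    def test_star_graph_degrees(self):
        g = build_network(
            classified([]), ppi([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        )
        table = centralities(g).set_index("node")
        assert table.loc["hub", "degree"] == 3
        assert (table.loc[["l1", "l2", "l3"], "degree"] == 1).all()
        # leaves sit on no shortest path between other nodes
        assert (table.loc[["l1", "l2", "l3"], "betweenness"] == 0).all()

    def test_degree_sum_equals_twice_edge_count(self, rng):
        g = nx.gnp_random_graph(10, 0.4, seed=17)
        nx.set_node_attributes(g, "protein", "node_type")
        table = centralities(g)
        assert table["degree"].sum() == 2 * g.number_of_edges()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_graphs(self, seed):
        local = np.random.default_rng(seed)
        n = int(local.integers(2, 13))
        g = nx.gnp_random_graph(n, float(local.uniform(0.1, 0.9)), seed=seed)
        nx.set_node_attributes(g, "protein", "node_type")
        table = centralities(g).set_index("node")
        deg, bet, clo = brute_force_centralities(g)
        for v in g.nodes:
            assert table.loc[v, "degree"] == deg[v]
            assert table.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-12)
            assert table.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-12)

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph()
        g.add_node("lone", node_type="protein")
        table = centralities(g).set_index("node")
        assert table.loc["lone", "closeness"] == 0.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            centralities(nx.Graph())

    def test_protein_ranks_only_cover_protein_nodes(self):
        inter = classified([("c1", "P1", -9.0, "probable_binder")])
        table = centralities(build_network(inter, ppi([("P1", "P2")])))
        prot = table["node_type"] == "protein"
        assert table.loc[prot, "degree_rank"].notna().all()
        assert table.loc[~prot, "degree_rank"].isna().all()


class TestDenseRank:
    def test_tie_pattern_from_hub_degree_table(self):
        ranks = dense_rank([17, 16, 14, 10, 10, 9, 8, 5, 3])
        assert list(ranks) == [1, 2, 3, 4, 4, 5, 6, 7, 8]

    def test_all_equal_share_rank_one(self):
        assert list(dense_rank([5, 5, 5])) == [1, 1, 1]

    def test_descending_distinct_values(self):
        assert list(dense_rank([0.433, 0.307, 0.267, 0.0])) == [1, 2, 3, 4]

    def test_lower_is_better_orientation(self):
        assert list(dense_rank([3, 1, 2], higher_is_better=False)) == [3, 1, 2]


class TestExports:
    def test_sif_and_graphml_roundtrip(self, tmp_path):
        inter = classified([("c1", "P1", -9.0, "probable_binder")])
        g = build_network(inter, ppi([("P1", "P2")]))
        sif = tmp_path / "net.sif"
        gml = tmp_path / "net.graphml"
        write_sif(g, sif)
        write_graphml(g, gml)
        lines = sif.read_text().strip().splitlines()
        assert len(lines) == 2
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == 3
        assert back.number_of_edges() == 2
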