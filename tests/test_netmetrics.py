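"""Graph construction, structural metrics, Leiden/CPM and node turnover.

Density, clustering and average path length are validated exhaustively
against brute-force oracles on every graph with up to five nodes (the
networkx graph atlas); the CPM partition is validated against an
exhaustive search over all set partitions on small graphs.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lithnet.netmetrics import (
    apl,
    betweenness,
    build_network,
    clustering_global,
    density,
    eigenvector,
    leiden_cpm,
    network_metrics,
    ntr,
)

# ---------------------------------------------------------------- oracles


def oracle_density(adj):
    n = len(adj)
    m = sum(adj[i][j] for i in range(n) for j in range(i + 1, n))
    return 2 * m / (n * (n - 1))


def oracle_transitivity(adj):
    n = len(adj)
    paths = closed = 0
    for i, j, k in itertools.permutations(range(n), 3):
        if adj[i][j] and adj[j][k]:
            paths += 1
            if adj[i][k]:
                closed += 1
    return closed / paths if paths else 0.0


def oracle_apl(adj):
    """BFS from scratch; mean over reachable ordered pairs."""
    n = len(adj)
    total = pairs = 0
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u][v] and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if d > 0:
                total += d
                pairs += 1
    return total / pairs if pairs else None


def iter_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def cpm_objective(G, partition, gamma):
    """CPM quality, leidenalg's both-directions convention."""
    q = 0.0
    for block in partition:
        s = set(block)
        w = sum(d.get("weight", 1.0) for u, v, d in G.edges(data=True)
                if u in s and v in s)
        q += 2 * w - gamma * len(s) * (len(s) - 1)
    return q


def atlas_graphs(max_nodes=5):
    from networkx.generators.atlas import graph_atlas_g

    return [g for g in graph_atlas_g() if 2 <= g.number_of_nodes() <= max_nodes]


# ---------------------------------------------------------------- building


class TestBuildNetwork:
    def test_all_positive_similarity_gives_complete_graph(self):
        idx = list("abcd")
        J = pd.DataFrame(0.6, index=idx, columns=idx)
        np.fill_diagonal(J.values, 1.0)
        G = build_network(J, "bin")
        assert G.number_of_nodes() == 4
        assert G.number_of_edges() == 6
        assert not any(u == v for u, v in G.edges)

    def test_zero_similarity_gives_no_edge(self):
        J = pd.DataFrame(
            [[1.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        G = build_network(J)
        assert G.number_of_edges() == 2
        assert not G.has_edge("a", "c")
        assert G["a"]["b"]["weight"] == pytest.approx(0.5)

    def test_all_zero_matrix_gives_edgeless_graph(self):
        J = pd.DataFrame(0.0, index=list("abc"), columns=list("abc"))
        G = build_network(J)
        assert G.number_of_edges() == 0
        assert G.number_of_nodes() == 3


# ---------------------------------------------------------------- metrics


class TestMetricOracles:
    def test_density_clustering_apl_on_all_graphs_up_to_five_nodes(self):
        for G in atlas_graphs():
            adj = nx.to_numpy_array(G).astype(int).tolist()
            assert density(G) == pytest.approx(oracle_density(adj))
            assert clustering_global(G) == pytest.approx(oracle_transitivity(adj))
            expected_apl = oracle_apl(adj)
            if expected_apl is None:
                with pytest.raises(ValueError):
                    apl(G)
            else:
                assert apl(G) == pytest.approx(expected_apl)

    @pytest.mark.parametrize(
        "edges,n,value",
        [
            ([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], 4, 1.0),
            ([(0, 1), (1, 2), (0, 2)], 3, 1.0),  # complete / triangle: APL 1
            ([(0, 1), (1, 2)], 3, 4 / 3),  # 3-node path
            ([(0, 1), (2, 3)], 4, 1.0),  # two disjoint edges: within-component
        ],
    )
    def test_apl_worked_examples(self, edges, n, value):
        G = nx.Graph(edges)
        G.add_nodes_from(range(n))
        assert apl(G) == pytest.approx(value)

    def test_density_examples(self):
        assert density(nx.complete_graph(4)) == 1.0
        G = nx.gnm_random_graph(8, 3, seed=1)
        assert density(G) == pytest.approx(3 / 28)
        assert density(nx.empty_graph(5)) == 0.0

    def test_clustering_examples(self):
        assert clustering_global(nx.complete_graph(4)) == 1.0
        assert clustering_global(nx.path_graph(3)) == 0.0

    def test_star_betweenness_raw_pair_counts(self):
        G = nx.star_graph(4)  # centre 0 plus 4 leaves
        b = betweenness(G)
        assert b[0] == pytest.approx(6.0)  # all 6 leaf pairs route via centre
        assert all(b[v] == 0.0 for v in range(1, 5))

    def test_complete_graph_betweenness_zero(self):
        assert set(betweenness(nx.complete_graph(5)).values()) == {0.0}

    def test_star_eigenvector_max_at_centre(self):
        e = eigenvector(nx.star_graph(4))
        assert e[0] == pytest.approx(1.0)
        assert all(e[v] < 1.0 for v in range(1, 5))

    def test_edgeless_eigenvector_all_zero(self):
        assert set(eigenvector(nx.empty_graph(3)).values()) == {0.0}


# ---------------------------------------------------------------- leiden


class TestLeidenCPM:
    def test_two_cliques_recovered_and_match_exhaustive_search(self):
        G = nx.Graph()
        G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], weight=1.0)
        part = leiden_cpm(G, resolution=0.02, iterations=50, restarts=10, seed=1)
        assert part.n_communities == 2

        best_q, best_p = max(
            ((cpm_objective(G, p, 0.02), p) for p in iter_partitions(list(G))),
            key=lambda t: t[0],
        )
        assert part.quality_raw == pytest.approx(best_q)
        best_blocks = {frozenset(b) for b in best_p}
        got_blocks = {
            frozenset(v for v, c in part.membership.items() if c == k)
            for k in set(part.membership.values())
        }
        assert got_blocks == best_blocks == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_complete_uniform_graph_is_one_community(self):
        G = nx.complete_graph(6)
        nx.set_edge_attributes(G, 1.0, "weight")
        part = leiden_cpm(G, resolution=0.02, iterations=50, restarts=5, seed=0)
        assert part.n_communities == 1
        # CPM arithmetic: all-in-one beats the best split at this resolution
        one = cpm_objective(G, [list(G)], 0.02)
        split = cpm_objective(G, [[0, 1, 2], [3, 4, 5]], 0.02)
        assert one > split
        assert part.quality_raw == pytest.approx(one)

    def test_singleton_graph_is_one_community(self):
        G = nx.Graph()
        G.add_node("only")
        part = leiden_cpm(G, restarts=2, iterations=10, seed=0)
        assert part.n_communities == 1

    def test_quality_beats_trivial_partitions(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            G = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1000)))
            for u, v in G.edges:
                G[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            part = leiden_cpm(G, resolution=0.05, iterations=50, restarts=10, seed=3)
            singleton = cpm_objective(G, [[v] for v in G], 0.05)
            allinone = cpm_objective(G, [list(G)], 0.05)
            assert part.quality_raw >= max(singleton, allinone) - 1e-9

    def test_planted_partition_recovery_across_seeds(self):
        """Two dense blocks, sparse weak bridges: ARI >= 0.9 for 20 seeds."""
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            G = nx.Graph()
            blocks = [list(range(6)), list(range(6, 12))]
            for block in blocks:
                for u, v in itertools.combinations(block, 2):
                    if rng.random() < 0.9:
                        G.add_edge(u, v, weight=rng.uniform(0.6, 1.0))
            for u in blocks[0]:
                for v in blocks[1]:
                    if rng.random() < 0.1:
                        G.add_edge(u, v, weight=rng.uniform(0.01, 0.05))
            G.add_nodes_from(range(12))
            part = leiden_cpm(G, resolution=0.1, iterations=100, restarts=20, seed=seed)
            truth = [0] * 6 + [1] * 6
            hits.append(adjusted_rand_score(truth, part.labels(list(range(12)))))
        assert np.mean(hits) >= 0.9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            leiden_cpm(nx.Graph())


# ---------------------------------------------------------------- turnover


class TestNTR:
    def test_worked_transition(self):
        n1 = {"A", "B", "C", "D"}
        n2 = {"C", "D", "E", "F", "G", "H", "I"}  # shares 2, adds 5
        out = ntr([("b1", n1), ("b2", n2)])
        row = out.iloc[0]
        assert row["created"] == 5
        assert row["destroyed"] == 2
        assert row["ntr"] == pytest.approx((5 - 2) / 7)
        assert round(row["ntr"], 2) == 0.43

    def test_identical_sets_give_zero(self):
        out = ntr([("b1", {"A", "B"}), ("b2", {"A", "B"})])
        assert out.iloc[0]["ntr"] == 0.0

    def test_pure_loss_is_negative(self):
        out = ntr([("b1", {"A", "B", "C"}), ("b2", {"A", "B"})])
        assert out.iloc[0]["created"] == 0
        assert out.iloc[0]["ntr"] == pytest.approx(-0.5)

    def test_antisymmetry_under_swapping_roles(self):
        rng = np.random.default_rng(2)
        universe = list("abcdefghij")
        for _ in range(20):
            cur = set(rng.choice(universe, size=6, replace=False))
            prev = set(rng.choice(universe, size=6, replace=False))
            f = ntr([("p", prev), ("c", cur)]).iloc[0]
            # swapping which set arrives flips created/destroyed; at equal
            # |N_t| the ratio flips sign
            g = ntr([("p", cur), ("c", prev)]).iloc[0]
            assert f["created"] == g["destroyed"]
            assert f["ntr"] == pytest.approx(-g["ntr"])

    def test_empty_current_bin_rejected(self):
        with pytest.raises(ValueError, match="empty node set"):
            ntr([("b1", {"A"}), ("b2", set())])

    def test_needs_two_bins(self):
        with pytest.raises(ValueError):
            ntr([("b1", {"A"})])


def test_network_metrics_bundle_complete_graph():
    idx = list("abcd")
    J = pd.DataFrame(0.8, index=idx, columns=idx)
    np.fill_diagonal(J.values, 1.0)
    G = build_network(J, "8600-8401")
    m = network_metrics(G, iterations=20, restarts=5, seed=0)
    assert (m.n_nodes, m.n_edges) == (4, 6)
    assert m.density == 1.0
    assert m.clustering_global == 1.0
    assert m.apl == 1.0
    assert m.n_communities == 1
    assert 0.0 < m.leiden_quality <= 1.0
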