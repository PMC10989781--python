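"""SparCC recovery, network topology closed forms and cohesion."""

import networkx as nx
import numpy as np
import pytest

from rhizoecol import (AsvTable, SimulationConfig, build_network, cohesion,
                       filter_taxa, outer_network,
                       simulate_correlated_compositions, sparcc,
                       sparcc_pvalues, topology)
from rhizoecol.core_io import ValidationError

from conftest import oracle_shortest_paths


class TestFilterTaxa:
    def test_zero_threshold_is_identity(self, small_table):
        out = filter_taxa(small_table, 0.0)
        assert out.taxon_ids == small_table.taxon_ids

    def test_dominant_taxon_only(self):
        counts = np.array([[9990, 1, 1, 1], [9990, 1, 1, 1]])
        t = AsvTable(["a", "b"], ["dom", "r1", "r2", "r3"], counts)
        out = filter_taxa(t, 0.001)
        assert out.taxon_ids == ["dom"]

    def test_impossible_threshold_rejected(self, small_table):
        with pytest.raises(ValidationError):
            filter_taxa(small_table, 1.1)


class TestSparcc:
    def test_too_few_taxa_rejected(self):
        t = AsvTable(["a", "b"], ["x", "y", "z"],
                     np.array([[1, 2, 3], [4, 5, 6]]))
        with pytest.raises(ValidationError):
            sparcc(t)

    def test_independent_taxa_near_zero(self):
        ds = simulate_correlated_compositions(SimulationConfig(
            n_taxa=50, n_samples=200, depth=10_000, seed=21,
            basis_correlation=np.eye(50)))
        r = sparcc(ds.table, seed=3)
        off = r[~np.eye(50, dtype=bool)]
        assert np.abs(off).max() < 0.3

    def test_planted_pair_recovered(self):
        c = np.eye(50)
        c[0, 1] = c[1, 0] = 0.8
        ds = simulate_correlated_compositions(SimulationConfig(
            n_taxa=50, n_samples=200, depth=10_000, seed=22,
            basis_correlation=c))
        i = ds.table.taxon_ids.index("ASV_1")
        j = ds.table.taxon_ids.index("ASV_2")
        r = sparcc(ds.table, seed=4)
        assert abs(r[i, j] - 0.8) <= 0.15

    def test_estimate_shrinks_with_samples(self):
        # identity truth: max |r| decreases as samples grow
        maxima = []
        for n in (50, 200, 800):
            ds = simulate_correlated_compositions(SimulationConfig(
                n_taxa=30, n_samples=n, depth=10_000, seed=31,
                basis_correlation=np.eye(30)))
            r = sparcc(ds.table, n_iterations=10, seed=5)
            maxima.append(np.abs(r[~np.eye(30, dtype=bool)]).max())
        assert maxima[0] > maxima[1] > maxima[2]


class TestSparccPvalues:
    def test_planted_pair_minimal_p_and_range(self):
        c = np.eye(20)
        c[0, 1] = c[1, 0] = 0.8
        ds = simulate_correlated_compositions(SimulationConfig(
            n_taxa=20, n_samples=100, depth=10_000, seed=40,
            basis_correlation=c))
        r = sparcc(ds.table, n_iterations=10, seed=1)
        p = sparcc_pvalues(ds.table, r, n_bootstrap=49, seed=2)
        i = ds.table.taxon_ids.index("ASV_1")
        j = ds.table.taxon_ids.index("ASV_2")
        assert p[i, j] == pytest.approx(1 / 50)
        off = p[~np.eye(20, dtype=bool)]
        assert (off > 0).all() and (off <= 1).all()


class TestBuildNetwork:
    def test_thresholds(self):
        r = np.array([[1.0, 0.7, -0.65], [0.7, 1.0, 0.2],
                      [-0.65, 0.2, 1.0]])
        p = np.array([[0.0, 0.2, 0.01], [0.2, 0.0, 0.01],
                      [0.01, 0.01, 0.0]])
        g = build_network(r, p, ["a", "b", "c"])
        assert not g.has_edge("a", "b")          # p fails
        assert g.has_edge("a", "c")              # negative edge retained
        assert g["a"]["c"]["weight"] == pytest.approx(-0.65)

    def test_all_zero_gives_empty(self):
        g = build_network(np.eye(4), np.ones((4, 4)), list("abcd"))
        assert g.number_of_edges() == 0


class TestTopology:
    def test_two_cliques_modularity_half(self):
        g = nx.Graph()
        for base in ("a", "b"):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(f"{base}{i}", f"{base}{j}", weight=1.0)
        topo = topology(g)
        assert topo.modularity == pytest.approx(0.5)
        assert topo.n_nodes == 6 and topo.n_edges == 6

    def test_complete_graph_k4(self):
        g = nx.complete_graph(4)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        topo = topology(g)
        assert topo.clustering_coefficient == 1.0
        assert topo.diameter == 1
        assert topo.average_path_length == 1.0
        assert topo.modularity == pytest.approx(0.0)

    def test_star_has_no_triangles(self):
        g = nx.star_graph(3)
        topo = topology(g)
        assert topo.clustering_coefficient == 0.0
        assert sorted(d for _, d in g.degree()) == [1, 1, 1, 3]

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            topology(nx.Graph())

    def test_path_metrics_match_floyd_warshall(self):
        rng = np.random.default_rng(0)
        for rep in range(100):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = 1.0
            topo = topology(g)
            giant = max(nx.connected_components(g), key=len)
            nodes = sorted(giant)
            dist = oracle_shortest_paths(
                [e for e in g.edges if e[0] in giant and e[1] in giant],
                nodes)
            if len(nodes) > 1:
                iu = np.triu_indices(len(nodes), 1)
                assert topo.diameter == int(dist[iu].max())
                assert topo.average_path_length == pytest.approx(
                    dist[iu].mean())

    def test_cumulative_degree_distribution(self):
        g = nx.star_graph(3)
        topo = topology(g)
        assert topo.cumulative_degree_distribution[1] == 1.0
        assert topo.cumulative_degree_distribution[3] == pytest.approx(0.25)


class TestCohesion:
    def test_shuffled_data_corrected_correlations_near_zero(self):
        # fully shuffled data IS a draw from the null model, so the
        # null-corrected correlations should average out to ~0
        rng = np.random.default_rng(1)
        rel = rng.dirichlet(np.ones(20), size=30)
        for j in range(20):
            rel[:, j] = rel[rng.permutation(30), j]
        res = cohesion(rel, n_null=200, seed=2)
        c = res.corrected.to_numpy()
        off = c[~np.eye(c.shape[0], dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_signs_by_construction(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, (15, 10))
        t = AsvTable([f"s{i}" for i in range(15)],
                     [f"t{j}" for j in range(10)], counts)
        res = cohesion(t, n_null=50, seed=4)
        assert (res.cohesion_pos >= 0).all()
        assert (res.cohesion_neg <= 0).all()

    def test_planted_negative_pair_dominates_ratio(self):
        rng = np.random.default_rng(5)
        n = 40
        a = rng.uniform(0.3, 0.7, n)
        counts = np.empty((n, 4))
        counts[:, 0] = (a * 5000).astype(int)
        counts[:, 1] = ((1 - a) * 5000).astype(int)  # strong negative pair
        counts[:, 2] = rng.integers(50, 100, n)
        counts[:, 3] = rng.integers(50, 100, n)
        t = AsvTable([f"s{i}" for i in range(n)], list("wxyz"),
                     counts.astype(int))
        res = cohesion(t, n_null=100, seed=6)
        assert res.ratio > 1.0

    def test_ratio_invariant_to_sample_order(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 80, (20, 8))
        t1 = AsvTable([f"s{i}" for i in range(20)],
                      [f"t{j}" for j in range(8)], counts)
        perm = rng.permutation(20)
        t2 = AsvTable([f"s{i}" for i in perm],
                      [f"t{j}" for j in range(8)], counts[perm])
        r1 = cohesion(t1, n_null=100, seed=8).ratio
        r2 = cohesion(t2, n_null=100, seed=8).ratio
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestOuterNetwork:
    def test_duplicated_sample_gets_edge(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 100, (3, 30))
        taxa = [f"t{j}" for j in range(30)]
        t1 = AsvTable(["a1", "a2", "a3"], taxa, counts)
        t2 = AsvTable(["b1", "b2", "b3"], taxa, counts)  # identical profiles
        g = outer_network({"h1": t1, "h2": t2})
        assert g.has_edge("h1:a1", "h2:b1")
        assert g["h1:a1"]["h2:b1"]["weight"] == pytest.approx(1.0)

    def test_no_within_compartment_edges(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(1, 100, (4, 25))
        taxa = [f"t{j}" for j in range(25)]
        t1 = AsvTable(["a1", "a2"], taxa, counts[:2])
        t2 = AsvTable(["b1", "b2"], taxa, counts[2:])
        g = outer_network({"h1": t1, "h2": t2}, r_threshold=-1.0,
                          p_threshold=1.1)
        comps = nx.get_node_attributes(g, "compartment")
        for u, v in g.edges:
            assert comps[u] != comps[v]

    def test_independent_samples_few_edges(self):
        rng = np.random.default_rng(11)
        taxa = [f"t{j}" for j in range(40)]
        t1 = AsvTable([f"a{i}" for i in range(5)], taxa,
                      rng.integers(1, 100, (5, 40)))
        t2 = AsvTable([f"b{i}" for i in range(5)], taxa,
                      rng.integers(1, 100, (5, 40)))
        g = outer_network({"h1": t1, "h2": t2})
        assert g.number_of_edges() <= 2
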