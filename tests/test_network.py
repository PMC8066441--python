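import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecoassembly.network import (
    CorrNetwork,
    average_degree,
    build_network,
    correlation_matrix,
    edge_sign_percentages,
    export_network,
    filter_for_network,
    graph_density,
    network_metrics,
    node_roles,
    random_ensemble_sigma,
    rmt_threshold,
    small_world_sigma,
)
from ecoassembly.synthetic_communities import simulate_block_correlated_taxa
from ecoassembly.tables_io import CountTable


def _net_from_graph(g: nx.Graph, sign=1) -> CorrNetwork:
    for u, v in g.edges:
        g[u][v].setdefault("r", 0.9 * sign)
        g[u][v].setdefault("sign", sign)
    return CorrNetwork(graph=g, threshold=0.8)


@pytest.fixture(scope="module")
def block_table() -> CountTable:
    return simulate_block_correlated_taxa(
        60, [(12, 1, 0.9), (12, -1, 0.9), (40, 1, 0.05)], seed=3
    )


class TestFilterForNetwork:
    def _table(self, mat):
        mat = np.asarray(mat)
        return CountTable(
            pd.DataFrame(
                mat,
                index=[f"s{i}" for i in range(mat.shape[0])],
                columns=[f"t{j}" for j in range(mat.shape[1])],
            )
        )

    def test_occurrence_boundary_strict(self):
        # taxon b present in exactly 50% of samples -> excluded at 0.5
        t = self._table([[50, 10], [50, 0], [50, 10], [50, 0]])
        out = filter_for_network(t, min_rel_abund=0.001, min_occurrence=0.5)
        assert out.taxon_ids == ["t0"]

    def test_abundance_boundary_strict(self):
        # taxon at mean relative abundance exactly 0.05% -> excluded
        t = self._table([[1, 1999], [1, 1999], [1, 1999], [1, 1999]])
        out = filter_for_network(t, min_rel_abund=0.0005, min_occurrence=0.5)
        assert "t0" not in out.taxon_ids

    def test_matches_brute_force(self, block_table):
        out = filter_for_network(block_table, 0.01, 0.5)
        mat = block_table.matrix().astype(float)
        rel = mat / mat.sum(axis=1, keepdims=True)
        expected = [
            t
            for j, t in enumerate(block_table.taxon_ids)
            if rel[:, j].mean() > 0.01 and (mat[:, j] > 0).mean() > 0.5
        ]
        assert out.taxon_ids == expected

    def test_empty_result_error(self, block_table):
        with pytest.raises(ValueError, match="relax"):
            filter_for_network(block_table, 0.999, 0.999)


class TestCorrelationMatrix:
    def test_diagonal_one(self, block_table):
        corr = correlation_matrix(block_table)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_planted_block_recovery(self, block_table):
        corr = correlation_matrix(block_table)
        within = corr.iloc[:12, :12].to_numpy()[np.triu_indices(12, 1)]
        background = corr.iloc[24:, 24:].to_numpy()[np.triu_indices(36, 1)]
        assert np.median(within) > np.median(background) + 0.3

    def test_matches_brute_force(self, block_table):
        corr = correlation_matrix(block_table)
        mat = block_table.matrix().astype(float)
        rel = mat / mat.sum(axis=1, keepdims=True)
        a, b = rel[:, 0], rel[:, 1]
        brute = np.cov(a, b)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        assert corr.iloc[0, 1] == pytest.approx(brute)

    def test_too_few_samples(self):
        t = simulate_block_correlated_taxa(3, [(5, 1, 0.5)], seed=0)
        with pytest.raises(ValueError, match="4 samples"):
            correlation_matrix(t)


class TestRmtThreshold:
    def test_single_value_scan(self, block_table):
        corr = correlation_matrix(block_table)
        thr, diag = rmt_threshold(corr, scan=np.array([0.7]))
        assert thr == pytest.approx(0.7) or thr == 0.8  # fallback allowed
        assert len(diag) == 1

    def test_noise_scan_diagnostics_monotone(self):
        rng = np.random.default_rng(0)
        t = CountTable(
            pd.DataFrame(
                rng.integers(1, 100, size=(30, 100)),
                index=[f"s{i}" for i in range(30)],
                columns=[f"t{j}" for j in range(100)],
            )
        )
        corr = correlation_matrix(t)
        thr, diag = rmt_threshold(corr)
        assert 0 < thr < 1
        ne = diag["n_edges"].to_numpy()
        assert np.all(np.diff(ne) <= 0)  # surviving edges shrink as s grows

    def test_blocks_survive_chosen_threshold(self, block_table):
        corr = correlation_matrix(block_table)
        thr, _ = rmt_threshold(corr)
        within = corr.iloc[:12, :12].to_numpy()[np.triu_indices(12, 1)]
        assert thr < np.median(np.abs(within))

    def test_invalid_scan(self, block_table):
        corr = correlation_matrix(block_table)
        with pytest.raises(ValueError):
            rmt_threshold(corr, scan=np.array([0.0, 1.5]))


class TestBuildNetwork:
    def test_no_edges_error(self):
        corr = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        with pytest.raises(ValueError, match="no edges"):
            build_network(corr, 0.99)

    def test_triangle(self):
        r = np.full((3, 3), 0.9)
        np.fill_diagonal(r, 1.0)
        corr = pd.DataFrame(r, index=list("abc"), columns=list("abc"))
        net = build_network(corr, 0.8)
        assert net.n_nodes == 3 and net.n_edges == 3
        assert all(d["sign"] == 1 for _, _, d in net.graph.edges(data=True))

    def test_negative_edges_recovered(self, block_table):
        corr = correlation_matrix(block_table)
        net = build_network(corr, 0.6)
        cross = [
            d["sign"]
            for u, v, d in net.graph.edges(data=True)
            if u.startswith("B0_") != v.startswith("B0_")
            and (u.startswith("B0_") or u.startswith("B1_"))
            and (v.startswith("B0_") or v.startswith("B1_"))
        ]
        assert cross and all(s == -1 for s in cross)

    def test_edge_threshold_respected(self, block_table):
        corr = correlation_matrix(block_table)
        net = build_network(corr, 0.6)
        assert all(abs(d["r"]) >= 0.6 for _, _, d in net.graph.edges(data=True))


class TestNetworkMetrics:
    def test_triangle_closed_form(self):
        net = _net_from_graph(nx.complete_graph(3))
        m = network_metrics(net)
        assert m.avg_clustering == pytest.approx(1.0)
        assert m.avg_path_length == pytest.approx(1.0)
        assert m.diameter == 1
        assert m.avg_degree == pytest.approx(2.0)
        assert m.graph_density == pytest.approx(1.0)

    def test_path_p3_hand_computed(self):
        net = _net_from_graph(nx.path_graph(3))
        m = network_metrics(net)
        assert m.avg_clustering == pytest.approx(0.0)
        assert m.avg_path_length == pytest.approx(4 / 3)
        assert m.diameter == 2
        assert m.avg_degree == pytest.approx(4 / 3)
        assert m.graph_density == pytest.approx(2 / 3)

    def test_lake_row_arithmetic(self):
        # printed node/edge counts reproduce AD 36.59 and GD 0.321 (3 d.p.)
        assert round(average_degree(115, 2104), 2) == 36.59
        assert round(graph_density(115, 2104), 3) == 0.321

    def test_degree_consistency(self, block_table):
        corr = correlation_matrix(block_table)
        net = build_network(corr, 0.6)
        m = network_metrics(net)
        degs = [d for _, d in net.graph.degree()]
        assert m.avg_degree == pytest.approx(np.mean(degs), abs=1e-12)

    def test_sign_percentages_sum_100(self, block_table):
        corr = correlation_matrix(block_table)
        m = network_metrics(build_network(corr, 0.6))
        assert m.pct_pos + m.pct_neg == pytest.approx(100.0)
        assert m.n_pos + m.n_neg == m.n_edges

    def test_modularity_nonnegative(self, block_table):
        corr = correlation_matrix(block_table)
        m = network_metrics(build_network(corr, 0.6))
        assert m.modularity >= 0.0


class TestSmallWorld:
    def test_sigma_formula_identity(self):
        assert small_world_sigma(0.5, 0.5, 2.0, 2.0) == pytest.approx(1.0)

    def test_river_table_arithmetic(self):
        # printed avgCC/APL values give sigma = 3.2 at 2 significant figures
        sigma = small_world_sigma(0.376, 0.056, 7.07, 3.33)
        assert float(f"{sigma:.2g}") == 3.2

    def test_ensemble_mean_ad_exact(self):
        net = _net_from_graph(nx.gnm_random_graph(30, 60, seed=1))
        m = network_metrics(net)
        rng_graphs = [nx.gnm_random_graph(30, 60, seed=s) for s in range(5)]
        for g in rng_graphs:
            assert 2 * g.number_of_edges() / g.number_of_nodes() == pytest.approx(
                average_degree(30, 60)
            )

    def test_sigma_seeded(self):
        net = _net_from_graph(nx.gnm_random_graph(25, 50, seed=2))
        m = network_metrics(net)
        a = random_ensemble_sigma(m, n_random=10, seed=5)
        b = random_ensemble_sigma(m, n_random=10, seed=5)
        assert a.sigma == b.sigma

    def test_too_many_edges_error(self):
        net = _net_from_graph(nx.complete_graph(4))
        m = network_metrics(net)
        m.n_edges = 100
        with pytest.raises(ValueError):
            random_ensemble_sigma(m, n_random=10, seed=0)


class TestNodeRoles:
    def test_all_links_within_module(self):
        g = nx.complete_graph(4)
        net = _net_from_graph(g)
        roles = node_roles(net, {v: 0 for v in g.nodes})
        assert all(r.pi == 0.0 for r in roles)
        assert all(r.category == "peripheral" for r in roles)

    def test_even_split_pi_half(self):
        g = nx.Graph([(0, 1), (0, 2)])
        net = _net_from_graph(g)
        roles = node_roles(net, {0: 0, 1: 1, 2: 2})
        r0 = next(r for r in roles if r.node == "0")
        assert r0.pi == pytest.approx(0.5)

    def test_missing_module_error(self):
        net = _net_from_graph(nx.path_graph(3))
        with pytest.raises(ValueError, match="module"):
            node_roles(net, {0: 0})


class TestExportNetwork:
    def test_round_trip_and_counts(self, tmp_path, block_table):
        corr = correlation_matrix(block_table)
        net = build_network(corr, 0.6)
        m = network_metrics(net)
        roles = node_roles(net, m.modules)
        paths = export_network(net, m, roles, tmp_path)
        back = nx.read_graphml(paths["graphml"])
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.graph.edges))
        edges = pd.read_csv(paths["edges"], sep="\t")
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        assert len(edges) == m.n_edges
        assert len(nodes) == m.n_nodes
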