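import itertools

import numpy as np
import pytest

import axogrow as ax
from axogrow.errors import InvalidParameterError


def _random_weighted_graph(rng, n=8, p=0.5):
    w = np.where(rng.random((n, n)) < p, rng.random((n, n)) * 4 + 0.5, 0.0)
    w = np.triu(w, 1)
    w = w + w.T
    # ensure connectivity for CPL comparisons: add a weak ring
    for i in range(n):
        j = (i + 1) % n
        if w[i, j] == 0:
            w[i, j] = w[j, i] = 0.1
    return ax.WeightedNetwork(w)


def _set_partitions(items):
    """All set partitions (Bell-number enumeration) of a small collection."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


class TestWeightedClustering:
    def test_uniform_complete_graph_is_one(self):
        w = np.ones((5, 5)) - np.eye(5)
        _, mean_cc = ax.weighted_clustering(ax.WeightedNetwork(w))
        assert np.isclose(mean_cc, 1.0)

    def test_star_graph_is_zero(self):
        w = np.zeros((5, 5))
        for leaf in range(1, 5):
            w[0, leaf] = w[leaf, 0] = 2.0
        _, mean_cc = ax.weighted_clustering(ax.WeightedNetwork(w))
        assert mean_cc == 0.0

    def test_matches_triple_enumeration_oracle(self, rng):
        net = _random_weighted_graph(rng)
        coeffs, _ = ax.weighted_clustering(net)
        w = net.weights / net.weights.max()
        n = net.n_nodes
        for i in range(n):
            acc = 0.0
            for j in range(n):
                for h in range(n):
                    if j != i and h != i and j != h:
                        acc += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
            k = np.count_nonzero(net.weights[i])
            expected = acc / (k * (k - 1)) if k > 1 else 0.0
            assert np.isclose(coeffs[i], expected, atol=1e-9)

    def test_negative_weights_rejected(self):
        net = _random_weighted_graph(np.random.default_rng(0))
        net.weights[0, 1] = net.weights[1, 0] = -1.0
        with pytest.raises(InvalidParameterError):
            ax.weighted_clustering(net)


class TestWeightedCPL:
    def test_three_node_path_unit_weights(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert np.isclose(ax.weighted_cpl(ax.WeightedNetwork(w)), 4 / 3)

    def test_uniform_complete_graph(self):
        w = (np.ones((6, 6)) - np.eye(6)) * 2.5
        assert np.isclose(ax.weighted_cpl(ax.WeightedNetwork(w)), 1 / 2.5)

    def test_matches_floyd_warshall_oracle(self, rng):
        net = _random_weighted_graph(rng)
        n = net.n_nodes
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        i, j, w = net.edges()
        d[i, j] = d[j, i] = 1.0 / w
        for k in range(n):
            for a in range(n):
                for b in range(n):
                    d[a, b] = min(d[a, b], d[a, k] + d[k, b])
        expected = d[~np.eye(n, dtype=bool)].mean()
        assert np.isclose(ax.weighted_cpl(net), expected, atol=1e-9)


class TestModularity:
    def test_two_disconnected_cliques_half(self):
        w = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        q, part = ax.modularity(ax.WeightedNetwork(w), seed=0)
        assert np.isclose(q, 0.5, atol=1e-12)
        assert len(part) == 2

    def test_uniform_complete_graph_zero(self):
        w = np.ones((6, 6)) - np.eye(6)
        q, _ = ax.modularity(ax.WeightedNetwork(w), seed=0)
        assert np.isclose(q, 0.0, atol=1e-12)

    def test_matches_exhaustive_partition_search(self, rng):
        # Bell-number brute force on 7 nodes with clear two-block structure
        w = np.zeros((7, 7))
        for i, j in itertools.combinations(range(4), 2):
            w[i, j] = w[j, i] = 3.0
        for i, j in itertools.combinations(range(4, 7), 2):
            w[i, j] = w[j, i] = 3.0
        w[0, 4] = w[4, 0] = 0.5
        net = ax.WeightedNetwork(w)
        two_m = net.weights.sum()
        s = net.strength
        best = -np.inf
        for part in _set_partitions(list(range(7))):
            q = 0.0
            for block in part:
                for i in block:
                    for j in block:
                        q += net.weights[i, j] - s[i] * s[j] / two_m
            best = max(best, q / two_m)
        q_louvain, _ = ax.modularity(net, n_runs=10, seed=1)
        assert np.isclose(q_louvain, best, atol=1e-9)

    def test_empty_network_rejected(self):
        with pytest.raises(InvalidParameterError):
            ax.modularity(ax.WeightedNetwork(np.zeros((4, 4))))


class TestNullModel:
    def test_degree_sequence_preserved(self, small_model_network):
        net = ax.threshold_to_density(small_model_network, 0.10)
        null = ax.degree_strength_preserving_null(net, seed=0)
        assert np.array_equal(np.sort(null.degree), np.sort(net.degree))
        assert np.array_equal(null.degree, net.degree)

    def test_weight_multiset_preserved(self, small_model_network):
        net = ax.threshold_to_density(small_model_network, 0.10)
        null = ax.degree_strength_preserving_null(net, seed=1)
        _, _, w0 = net.edges()
        _, _, w1 = null.edges()
        assert np.allclose(np.sort(w0), np.sort(w1))

    def test_strengths_highly_correlated(self, small_model_network):
        net = ax.threshold_to_density(small_model_network, 0.10)
        null = ax.degree_strength_preserving_null(net, seed=2)
        r = np.corrcoef(net.strength, null.strength)[0, 1]
        assert r > 0.9

    def test_topology_actually_rewired(self, small_model_network):
        net = ax.threshold_to_density(small_model_network, 0.10)
        null = ax.degree_strength_preserving_null(net, seed=3)
        assert not np.array_equal(net.weights > 0, null.weights > 0)


class TestTopologyReport:
    def test_self_null_normalizes_to_one(self, small_model_network):
        net = ax.prepare_for_topology(small_model_network, 0.10, 2e5)
        rep = ax.topology_report(net, null_networks=[net], seed=0)
        assert np.isclose(rep.cc_normalized, 1.0)
        assert np.isclose(rep.cpl_normalized, 1.0)
        assert np.isclose(rep.q_normalized, 1.0)
        assert np.isclose(rep.sw, 1.0)

    def test_sw_identity(self, small_model_network):
        net = ax.prepare_for_topology(small_model_network, 0.10, 2e5)
        rep = ax.topology_report(net, n_nulls=3, seed=4)
        assert np.isclose(rep.sw, (rep.cc / rep.cc_null) * (rep.cpl_null / rep.cpl), rtol=1e-12)

    def test_model_network_clustered_relative_to_null(self, small_model_network):
        net = ax.prepare_for_topology(small_model_network, 0.10, 2e5)
        rep = ax.topology_report(net, n_nulls=5, seed=5)
        assert rep.cc_normalized > 1.0
        assert rep.cpl_normalized > 1.0


class TestLandscape:
    def test_single_cell_single_landscape_matches_report(self):
        df = ax.landscape(
            [1.0], [1.0], n_landscapes=1, n_axons=20_000, n_nulls=3, seed=6
        )
        assert len(df) == 1
        row = df.iloc[0]
        assert not row.ignored
        assert row.cc_normalized > 0
        assert np.isclose(row.sw, row.cc_normalized / row.cpl_normalized, rtol=1e-9)

    def test_same_seed_reproducible(self):
        kwargs = dict(n_landscapes=1, n_axons=10_000, n_nulls=2, seed=8)
        a = ax.landscape([1.0], [1.5], **kwargs)
        b = ax.landscape([1.0], [1.5], **kwargs)
        assert np.allclose(a[["cc", "cpl", "q", "sw"]], b[["cc", "cpl", "q", "sw"]])

    def test_sparse_cells_flagged_ignored(self):
        df = ax.landscape([1.0], [0.1], n_landscapes=1, n_axons=5_000, n_nulls=2, seed=9)
        assert bool(df.iloc[0].ignored)
        assert np.isnan(df.iloc[0].cc)
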