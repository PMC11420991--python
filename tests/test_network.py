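import itertools

import networkx as nx
import numpy as np
import pytest

from myconet.io import CountTable
from myconet.network import (
    CooccurrenceNetwork,
    build_network,
    clr_transform,
    global_topology,
    prevalence_filter,
    rmt_select_threshold,
    spearman_matrix,
)


def _table(counts, prefix="s"):
    counts = np.asarray(counts)
    return CountTable(
        [f"{prefix}{i}" for i in range(counts.shape[0])],
        [f"o{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestPrevalenceFilter:
    @pytest.mark.parametrize("n_present,kept", [(9, True), (7, True), (6, False)])
    def test_seven_of_nine_rule(self, n_present, kept):
        col = np.array([1] * n_present + [0] * (9 - n_present))
        counts = np.column_stack([col, np.ones(9, dtype=int)])
        out = prevalence_filter(_table(counts))
        assert ("o0" in out.otu_ids) == kept

    def test_empty_result_errors(self):
        counts = np.zeros((9, 3), dtype=int)
        counts[0, :] = 1
        with pytest.raises(ValueError, match="lower"):
            prevalence_filter(_table(counts))


class TestClr:
    def test_uniform_row_is_zero(self):
        x = clr_transform(_table([[1, 1, 1, 1]]))
        assert np.allclose(x, 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        x = clr_transform(_table(rng.integers(0, 50, (5, 12))))
        assert np.allclose(x.sum(axis=1), 0.0, atol=1e-12)

    def test_scale_invariance(self):
        row = np.array([[2, 5, 11, 0]], dtype=float) + 1  # counts + pseudocount
        a = np.log(row) - np.log(row).mean()
        b = np.log(3 * row) - np.log(3 * row).mean()
        assert np.allclose(a, b)

    def test_positive_pseudocount_required(self):
        with pytest.raises(ValueError):
            clr_transform(_table([[1, 2]]), pseudocount=0)


class TestSpearmanMatrix:
    def test_monotone_and_reversed_pairs(self):
        x = np.column_stack([np.arange(6), np.arange(6) ** 2, 6 - np.arange(6)])
        r, p, flags = spearman_matrix(x)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert not flags.any()

    def test_constant_column_flagged_zero(self):
        x = np.column_stack([np.arange(6), np.full(6, 3.0)])
        r, _p, flags = spearman_matrix(x)
        assert flags[1] and r[0, 1] == 0.0

    def test_matches_scipy_pairwise(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 6))
        r, p, _ = spearman_matrix(x)
        for i, j in itertools.combinations(range(6), 2):
            sr = spearmanr(x[:, i], x[:, j])
            assert r[i, j] == pytest.approx(sr.statistic, abs=1e-12)
            assert p[i, j] == pytest.approx(sr.pvalue, rel=1e-6)


class TestRmtThreshold:
    def test_identity_matrix_degenerate(self):
        with pytest.raises(ValueError):
            rmt_select_threshold(np.eye(40))

    def test_independent_variables_find_some_threshold(self):
        rng = np.random.default_rng(1)
        r = np.corrcoef(rng.standard_normal((100, 200)), rowvar=False)
        scan = rmt_select_threshold(r)
        assert 0.3 <= scan.chosen <= 0.99
        assert (np.diff(scan.thresholds) > 0).all()

    def test_block_structure_isolated_exactly(self):
        # five 10-variable factor blocks + 100 independent variables
        rng = np.random.default_rng(2)
        cols = []
        for _ in range(5):
            f = rng.standard_normal(500)
            cols.extend(
                0.95 * f + np.sqrt(1 - 0.95**2) * rng.standard_normal(500)
                for _ in range(10)
            )
        cols.extend(rng.standard_normal(500) for _ in range(100))
        r = np.corrcoef(np.array(cols).T, rowvar=False)
        scan = rmt_select_threshold(r)
        assert scan.chosen <= 0.9
        net = build_network(r, scan.chosen, [str(i) for i in range(150)])
        within = {
            (str(i), str(j))
            for b in range(5)
            for i, j in itertools.combinations(range(b * 10, b * 10 + 10), 2)
        }
        assert {(a, b) for a, b, _ in net.edges} == within


class TestBuildNetwork:
    def _r(self, n, pairs):
        r = np.eye(n)
        for i, j, v in pairs:
            r[i, j] = r[j, i] = v
        return r

    def test_single_positive_edge(self):
        net = build_network(self._r(3, [(0, 1, 0.95)]), 0.9, ["a", "b", "c"])
        assert net.n_edges == 1 and net.n_nodes == 2
        assert net.positive_edges() == 1

    def test_negative_edge(self):
        net = build_network(self._r(3, [(0, 1, -0.95)]), 0.9, ["a", "b", "c"])
        assert net.negative_edges() == 1

    def test_threshold_one_keeps_only_perfect(self):
        net = build_network(self._r(3, [(0, 1, 0.99)]), 1.0, ["a", "b", "c"])
        assert net.n_edges == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 15))
        r = np.corrcoef(x, rowvar=False)
        ids = [f"o{i}" for i in range(15)]
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8, 0.95):
            n = build_network(r, t, ids).n_edges
            if prev is not None:
                assert n <= prev
            prev = n


class TestGlobalTopology:
    def test_complete_graph_k4(self):
        edges = [
            (a, b, 0.95) for a, b in itertools.combinations("abcd", 2)
        ]
        rec = global_topology(CooccurrenceNetwork(edges, 0.9, "fixed", "g"))
        assert rec.average_degree == pytest.approx(3.0)
        assert rec.geodesic_efficiency == pytest.approx(1.0)
        assert rec.average_path_distance == pytest.approx(1.0)

    def test_two_triangles_modularity_half(self):
        edges = [
            ("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9),
            ("x", "y", 0.9), ("y", "z", 0.9), ("x", "z", 0.9),
        ]
        rec = global_topology(CooccurrenceNetwork(edges, 0.9, "fixed", "g"))
        # closed form: Q = sum(e_ii/m - (d_i/2m)^2) for the 2-clique split
        assert rec.modularity == pytest.approx(0.5)
        assert rec.n_modules == 2

    def test_sign_partition_identity_random_networks(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(4, 15)
            ids = [f"o{i}" for i in range(n)]
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.3:
                    edges.append((ids[i], ids[j], rng.choice([-1, 1]) * rng.uniform(0.9, 1)))
            net = CooccurrenceNetwork(edges, 0.9, "fixed", "g")
            rec = global_topology(net)
            assert rec.positive_edges + rec.negative_edges == rec.total_edges

    def test_empty_network_flagged(self):
        rec = global_topology(CooccurrenceNetwork([], 0.9, "fixed", "g"))
        assert rec.empty and rec.total_nodes == 0

    def test_path_statistics_match_floyd_warshall(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            edges = [(f"n{a}", f"n{b}", 0.95) for a, b in g.edges]
            if not edges:
                continue
            net = CooccurrenceNetwork(edges, 0.9, "fixed", "g")
            rec = global_topology(net)
            nodes = net.nodes
            idx = {n: i for i, n in enumerate(nodes)}
            n = len(nodes)
            d = np.full((n, n), np.inf)
            np.fill_diagonal(d, 0)
            for a, b, _ in net.edges:
                d[idx[a], idx[b]] = d[idx[b], idx[a]] = 1
            for k in range(n):
                d = np.minimum(d, d[:, [k]] + d[[k], :])
            off = ~np.eye(n, dtype=bool)
            finite = np.isfinite(d) & off
            assert rec.average_path_distance == pytest.approx(d[finite].mean())
            inv = np.where(finite, 1 / np.where(d == 0, 1, d), 0.0)
            assert rec.geodesic_efficiency == pytest.approx(
                inv[off].sum() / (n * (n - 1))
            )
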