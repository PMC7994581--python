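"""Signed networks: PPI construction, Louvain Q*, distances, diversity, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mathstrat.network import (
    ConnectivityMatrix,
    Partition,
    brute_force_modules,
    diversity_coefficient,
    group_average_network,
    louvain_modules,
    node_change_tests,
    partition_distance,
    ppi_edge_weights,
    read_matrix,
    signed_modularity,
    write_matrix,
)
from mathstrat.network import test_distance_nonzero as distance_nonzero_test
from mathstrat.synth import simulate_roi_timeseries


def planted_block_matrix(rng, sizes, within=0.6, between=-0.2, noise=0.05):
    n = sum(sizes)
    aff = np.concatenate([[m + 1] * s for m, s in enumerate(sizes)])
    same = aff[:, None] == aff[None, :]
    w = np.where(same, within, between) + rng.normal(0, noise, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w, aff


class TestConnectivityMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            ConnectivityMatrix(np.ones((3, 3)), ["a", "b", "c"])  # nonzero diagonal
        w = np.zeros((3, 3))
        w[0, 1] = 1.0  # asymmetric
        with pytest.raises(ValueError):
            ConnectivityMatrix(w, ["a", "b", "c"])

    def test_roundtrip_csv(self, tmp_path):
        rng = np.random.default_rng(1)
        w, _ = planted_block_matrix(rng, [3, 3])
        m = ConnectivityMatrix(w, [f"n{i}" for i in range(6)], "p0", "pre")
        write_matrix(m, tmp_path / "m.csv")
        m2 = read_matrix(tmp_path / "m.csv")
        np.testing.assert_allclose(m.weights, m2.weights, atol=1e-12)
        assert m2.node_labels == m.node_labels


class TestPPI:
    def test_null_coupling_gives_near_zero_weights(self):
        ts, task = simulate_roi_timeseries(6, 600, 10, coupling=None, seed=0)
        cm = ppi_edge_weights(ts, task)
        assert np.abs(cm.weights).max() < 0.2
        np.testing.assert_allclose(cm.weights, cm.weights.T)
        assert np.all(np.diag(cm.weights) == 0)

    def test_planted_task_coupling_recovered(self):
        # coupling g applies only during task-on samples; regressing with the
        # 0/1 task gate identifies the planted g directly (with the +1/-1
        # contrast coding the same structure loads g/2 on the interaction)
        g = 0.3
        est = []
        for rep in range(100):
            ts, task = simulate_roi_timeseries(4, 400, 8, coupling=[(0, 1, g)],
                                               seed=100 + rep)
            gate = (task == 1).astype(float)
            est.append(ppi_edge_weights(ts, gate).weights[0, 1])
        assert np.mean(est) == pytest.approx(g, abs=0.03)

    def test_constant_task_rejected(self):
        ts, _ = simulate_roi_timeseries(3, 100, 2, seed=1)
        with pytest.raises(ValueError, match="task_indicator"):
            ppi_edge_weights(ts, np.ones(100))


class TestLouvain:
    def test_two_positive_cliques(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        p = louvain_modules(w, n_restarts=20, seed=0)
        assert p.n_modules == 2
        assert len(set(p.affiliation[:4])) == 1
        assert len(set(p.affiliation[4:])) == 1

    @pytest.mark.parametrize("n,seed", [(6, 0), (7, 1), (8, 2), (8, 3), (8, 4)])
    def test_matches_brute_force_on_small_signed_matrices(self, n, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(0, 0.5, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        oracle = brute_force_modules(w)
        p = louvain_modules(w, n_restarts=50, seed=seed)
        assert p.quality == pytest.approx(oracle.quality, abs=1e-9)

    def test_planted_signed_partition_recovered(self):
        hits = 0
        runs = 20
        for rep in range(runs):
            rng = np.random.default_rng(rep)
            w, aff = planted_block_matrix(rng, [4, 4, 4], within=0.6,
                                          between=-0.2, noise=0.1)
            p = louvain_modules(w, n_restarts=30, seed=rep)
            hits += partition_distance(p, Partition(aff)) == 0.0
        assert hits / runs >= 0.95

    def test_quality_at_least_single_module(self):
        rng = np.random.default_rng(9)
        w, _ = planted_block_matrix(rng, [5, 5], noise=0.2)
        p = louvain_modules(w, n_restarts=20, seed=0)
        q_single = signed_modularity(w, np.ones(10, dtype=int))
        assert p.quality >= q_single - 1e-12

    def test_all_zero_matrix_single_module(self):
        with pytest.warns(UserWarning):
            p = louvain_modules(np.zeros((5, 5)), seed=0)
        assert p.n_modules == 1
        assert p.quality == 0.0


class TestPartitionDistance:
    def test_identical_partitions(self):
        p = Partition(np.array([1, 1, 2, 2, 3]))
        assert partition_distance(p, p) == 0.0
        relabeled = Partition(np.array([3, 3, 1, 1, 2]))
        assert partition_distance(p, relabeled) == 0.0

    def test_independent_partitions(self):
        p1 = Partition(np.array([1, 1, 2, 2]))
        p2 = Partition(np.array([1, 2, 1, 2]))
        assert partition_distance(p1, p2) == pytest.approx(1.0)

    def test_hand_computed_contingency_value(self):
        # [1,1,2,2] vs [1,1,1,2]: counts (2,0;1,1), n=4
        p1 = Partition(np.array([1, 1, 2, 2]))
        p2 = Partition(np.array([1, 1, 1, 2]))
        h1 = np.log(2.0)
        h2 = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        mi = (0.5 * np.log(0.5 / (0.5 * 0.75))
              + 0.25 * np.log(0.25 / (0.5 * 0.75))
              + 0.25 * np.log(0.25 / (0.5 * 0.25)))
        expected = 1.0 - 2.0 * mi / (h1 + h2)
        assert partition_distance(p1, p2) == pytest.approx(expected, abs=1e-10)

    def test_semimetric_properties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = Partition(rng.integers(1, 4, 12))
            b = Partition(rng.integers(1, 4, 12))
            d = partition_distance(a, b)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(partition_distance(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_distance(Partition(np.ones(3, int)), Partition(np.ones(4, int)))


class TestDiversity:
    def _matrix_with_node_strengths(self, strengths):
        """Node 0 connected into 3 modules (nodes 1-3) with given weights."""
        w = np.zeros((4, 4))
        for j, s in enumerate(strengths, start=1):
            w[0, j] = w[j, 0] = s
        return w, Partition(np.array([1, 1, 2, 3]))

    def test_uniform_strength_gives_one(self):
        w, p = self._matrix_with_node_strengths([1.0, 1.0, 1.0])
        d = diversity_coefficient(w, p)
        assert d.values[0] == pytest.approx(1.0)

    def test_single_module_strength_gives_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        p = Partition(np.array([1, 1, 2, 3]))
        assert diversity_coefficient(w, p).values[0] == 0.0

    def test_hand_computed_entropy_value(self):
        w, p = self._matrix_with_node_strengths([0.5, 0.25, 0.25])
        assert diversity_coefficient(w, p).values[0] == pytest.approx(0.94639, abs=1e-5)

    def test_relabel_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        w, aff = planted_block_matrix(rng, [4, 4, 4], between=0.1)
        p1 = Partition(aff)
        p2 = Partition((aff % 3) + 1)  # relabeled, same grouping
        d1 = diversity_coefficient(w, p1).values
        d2 = diversity_coefficient(w, p2).values
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        d3 = diversity_coefficient(w * 7.5, p1).values
        np.testing.assert_allclose(d1, d3, atol=1e-12)

    def test_isolated_node_zero(self):
        w = np.zeros((4, 4))
        w[1, 2] = w[2, 1] = 1.0
        p = Partition(np.array([1, 1, 2, 2]))
        assert diversity_coefficient(w, p).values[0] == 0.0

    def test_negative_channel(self):
        w, p = self._matrix_with_node_strengths([1.0, 1.0, 1.0])
        d = diversity_coefficient(-w, p, channel="negative")
        assert d.values[0] == pytest.approx(1.0)


class TestGroupAverage:
    def test_identity_and_cancellation(self):
        rng = np.random.default_rng(4)
        w, _ = planted_block_matrix(rng, [3, 3])
        m = ConnectivityMatrix(w, list("abcdef"))
        avg = group_average_network([m, m, m])
        np.testing.assert_allclose(avg.weights, w)
        neg = ConnectivityMatrix(-w, list("abcdef"))
        np.testing.assert_allclose(group_average_network([m, neg]).weights, 0.0,
                                   atol=1e-12)

    def test_label_mismatch_rejected(self):
        w = np.zeros((2, 2))
        with pytest.raises(ValueError):
            group_average_network([ConnectivityMatrix(w, ["a", "b"]),
                                   ConnectivityMatrix(w, ["b", "a"])])

    def test_planted_cohort_mean_has_block_structure(self):
        rng = np.random.default_rng(5)
        mats = []
        aff = None
        for _ in range(20):
            w, aff = planted_block_matrix(rng, [5, 5], within=0.3, between=0.0,
                                          noise=0.3)
            mats.append(ConnectivityMatrix(w, [f"n{i}" for i in range(10)]))
        avg = group_average_network(mats).weights
        same = aff[:, None] == aff[None, :]
        np.fill_diagonal(same, False)
        assert avg[same].mean() > avg[~same & (np.eye(10) == 0)].mean()


class TestDistanceAndNodeTests:
    def test_zero_distances(self):
        res = distance_nonzero_test(np.zeros(10))
        assert res["mean"] == 0.0 and res["p"] == 1.0

    def test_degenerate_constant_distances(self):
        res = distance_nonzero_test([0.5, 0.5, 0.5, 0.5])
        assert res["degenerate"] and res["sd"] == 0.0

    def test_t_matches_hand_formula(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.9, 0.05, 35)
        res = distance_nonzero_test(d)
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(35))
        assert res["t"] == pytest.approx(expected, rel=1e-12)
        assert res["n"] == 35

    def test_no_change_gives_adjusted_p_one(self):
        rng = np.random.default_rng(7)
        pre = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        out = node_change_tests(pre, pre.copy())
        assert (out["p_fdr"] == 1.0).all()

    def test_adjusted_p_matches_step_up_formula(self):
        rng = np.random.default_rng(11)
        pre = pd.DataFrame(rng.normal(0.5, 0.1, (15, 5)),
                           columns=[f"n{i}" for i in range(5)])
        post = pre + rng.normal(0.02, 0.08, (15, 5))
        out = node_change_tests(pre, post)
        # hand step-up: sort ascending, p_(i) * m / i, cumulative min from top
        p = out["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(out["p_fdr"].to_numpy(), expected, atol=1e-12)

    def test_planted_decrease_detected(self):
        rng = np.random.default_rng(8)
        pre = pd.DataFrame(rng.normal(0.8, 0.05, (35, 6)),
                           columns=[f"n{i}" for i in range(6)])
        post = pre + rng.normal(0, 0.05, (35, 6))
        post["n2"] -= 0.15
        out = node_change_tests(pre, post).set_index("node")
        assert out.loc["n2", "significant"]
        assert out.loc["n2", "mean_change"] < 0

    def test_pooling_bilateral_nodes(self):
        rng = np.random.default_rng(9)
        cols = ["L_IPS", "R_IPS", "hipp"]
        pre = pd.DataFrame(rng.random((12, 3)), columns=cols)
        post = pd.DataFrame(rng.random((12, 3)), columns=cols)
        out = node_change_tests(pre, post, pool={"IPS": ["L_IPS", "R_IPS"]})
        assert set(out["node"]) == {"hipp", "IPS"}
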