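"""Rest preprocessing, PC-stable skeleton, spectral partition, seed maps."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mionpipe import netgraph, synth


def gaussian_sample(precision, n, seed):
    cov = np.linalg.inv(precision)
    L = np.linalg.cholesky(cov)
    return L @ np.random.default_rng(seed).standard_normal((precision.shape[0], n))


class TestPreprocess:
    def test_passband_preserves_sinusoid(self):
        t = np.arange(400) * 2.5
        s = np.sin(2 * np.pi * 0.05 * t)
        out = netgraph.preprocess_rest(s[None], None, (0.01, 0.1), 2.5)
        assert out.matrix[0].std() / s.std() >= 0.99

    def test_stopband_kills_sinusoid(self):
        t = np.arange(400) * 2.5
        s = np.sin(2 * np.pi * 0.15 * t)
        out = netgraph.preprocess_rest(s[None], None, (0.01, 0.1), 2.5)
        assert out.matrix[0].std() <= 1e-6 * s.std()

    def test_confound_projection_annihilates_confound(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(300)
        out = netgraph.preprocess_rest(np.vstack([c, 2 * c]), c, (0.01, 0.1), 2.5)
        assert np.abs(out.matrix).max() < 1e-10

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            netgraph.preprocess_rest(np.zeros((2, 100)), None, (0.01, 0.3), 2.5)

    def test_rows_zero_mean(self):
        rng = np.random.default_rng(1)
        out = netgraph.preprocess_rest(rng.random((3, 200)) + 5, None, (0.01, 0.1), 2.5)
        assert np.abs(out.matrix.mean(axis=1)).max() < 1e-10


class TestExtractRoi:
    def test_small_regions_dropped(self):
        labels = np.zeros((4, 4, 1), int)
        labels[:2, :2, 0] = 1          # 4 voxels
        labels[2:, :, 0] = 2           # 8 voxels
        mask = np.ones_like(labels, bool)
        mask[0, 0, 0] = False          # region 1 down to 3 significant voxels
        series = np.random.default_rng(2).random((4, 4, 1, 50))
        mat, kept, dropped = netgraph.extract_roi_series(series, labels, mask, min_voxels=4)
        assert kept == [2] and dropped == [1]
        assert mat.shape == (1, 50)

    def test_homogeneous_region_mean_equals_voxel(self):
        labels = np.ones((2, 2, 1), int)
        series = np.tile(np.arange(30.0), (2, 2, 1, 1))
        mat, kept, _ = netgraph.extract_roi_series(
            labels=labels, significance_mask=np.ones_like(labels, bool),
            voxel_series=series, min_voxels=4,
        )
        np.testing.assert_allclose(mat[0], np.arange(30.0))

    def test_all_regions_too_small_rejected(self):
        labels = np.ones((2, 1, 1), int)
        series = np.zeros((2, 1, 1, 10))
        with pytest.raises(ValueError, match="no region"):
            netgraph.extract_roi_series(series, labels, np.ones_like(labels, bool), 4)


class TestPcStable:
    def test_orthogonal_series_empty_skeleton(self):
        n = 300
        t = np.arange(n)
        X = np.vstack([np.sin(2 * np.pi * 3 * t / n),
                       np.sin(2 * np.pi * 7 * t / n),
                       np.sin(2 * np.pi * 11 * t / n)])
        rs = netgraph.RestSeries(matrix=X, sampling_interval=1.0)
        cg = netgraph.pc_stable_skeleton(rs, ci_alpha=0.01)
        assert cg.graph.number_of_edges() == 0

    def test_chain_recovered(self):
        P = np.array([[1.0, -0.4, 0.0], [-0.4, 1.0, -0.4], [0.0, -0.4, 1.0]])
        X = gaussian_sample(P, 2000, seed=0)
        rs = netgraph.RestSeries(matrix=X, sampling_interval=1.0, node_ids=["X", "Y", "Z"])
        cg = netgraph.pc_stable_skeleton(rs, ci_alpha=0.01)
        assert sorted(tuple(sorted(e)) for e in cg.graph.edges) == [("X", "Y"), ("Y", "Z")]
        # weights are the net (smallest-magnitude) partial correlations
        for _, _, d in cg.graph.edges(data=True):
            assert -1 < d["weight"] < 1 and d["min_test_p"] <= 0.01

    def test_order_invariance(self):
        P = np.array([[1.0, -0.4, 0.0], [-0.4, 1.0, -0.4], [0.0, -0.4, 1.0]])
        X = gaussian_sample(P, 1500, seed=3)
        perm = [2, 0, 1]
        a = netgraph.pc_stable_skeleton(
            netgraph.RestSeries(matrix=X, sampling_interval=1.0, node_ids=[0, 1, 2]), 0.01
        )
        b = netgraph.pc_stable_skeleton(
            netgraph.RestSeries(matrix=X[perm], sampling_interval=1.0,
                                node_ids=[perm[i] for i in range(3)]), 0.01
        )
        assert set(map(frozenset, a.graph.edges)) == set(map(frozenset, b.graph.edges))

    def test_constant_node_rejected(self):
        X = np.random.default_rng(0).random((3, 100))
        X[1] = 2.0
        rs = netgraph.RestSeries(matrix=X, sampling_interval=1.0, node_ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="b"):
            netgraph.pc_stable_skeleton(rs, 0.01)

    def test_matches_brute_force_on_random_model(self):
        rng = np.random.default_rng(12)
        P = np.eye(5)
        P[0, 1] = P[1, 0] = -0.35
        P[2, 3] = P[3, 2] = 0.3
        P[1, 4] = P[4, 1] = -0.3
        X = gaussian_sample(P, 2000, seed=9)
        rs = netgraph.RestSeries(matrix=X, sampling_interval=1.0)
        pc = netgraph.pc_stable_skeleton(rs, 0.01)
        oracle = netgraph.brute_force_skeleton(rs, 0.01)
        assert set(map(frozenset, pc.graph.edges)) == set(map(frozenset, oracle.graph.edges))


class TestComponentsAndPartition:
    def _graph(self, edges):
        import networkx as nx

        G = nx.Graph()
        G.add_weighted_edges_from(edges)
        return netgraph.ConnectivityGraph(graph=G, ci_alpha=0.01)

    def test_connected_graph_unchanged(self):
        cg = self._graph([(1, 2, 0.5), (2, 3, 0.4)])
        assert set(netgraph.largest_component(cg).graph.nodes) == {1, 2, 3}

    def test_largest_of_two_components(self):
        cg = self._graph(
            [(1, 2, 0.5), (2, 3, 0.4), (3, 4, 0.3), (4, 5, 0.3), (10, 11, 0.9), (11, 12, 0.9)]
        )
        assert set(netgraph.largest_component(cg).graph.nodes) == {1, 2, 3, 4, 5}

    def test_edgeless_graph_single_node(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from([7, 3, 9])
        cg = netgraph.ConnectivityGraph(graph=G, ci_alpha=0.01)
        with pytest.warns(UserWarning, match="edgeless"):
            out = netgraph.largest_component(cg)
        assert set(out.graph.nodes) == {3}

    def test_two_cliques_k2(self):
        edges = [(i, j, 0.5) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j, 0.5) for i in range(4, 8) for j in range(i + 1, 8)]
        edges += [(3, 4, 1e-9)]    # hairline bridge keeps one component
        part = netgraph.spectral_partition(self._graph(edges), k=2, seed=0)
        groups = {}
        for n, c in part.assignment.items():
            groups.setdefault(c, set()).add(n)
        assert sorted(map(sorted, groups.values())) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_planted_partition_recovery_and_stability(self):
        rng = np.random.default_rng(4)
        import networkx as nx

        G = nx.Graph()
        true = {}
        for blk in range(4):
            nodes = range(6 * blk, 6 * blk + 6)
            for n in nodes:
                true[n] = blk
            for i in nodes:
                for j in nodes:
                    if i < j:
                        G.add_edge(i, j, weight=0.6)
        for i in range(24):
            for j in range(i + 1, 24):
                if true[i] != true[j] and rng.random() < 0.3:
                    G.add_edge(i, j, weight=0.05)
        cg = netgraph.ConnectivityGraph(graph=G, ci_alpha=0.01)
        p1 = netgraph.spectral_partition(cg, k=4, seed=1)
        p2 = netgraph.spectral_partition(cg, k=4, seed=2)
        truth_labels = [true[n] for n in p1.nodes]
        assert adjusted_rand_score(truth_labels, p1.labels()) == 1.0
        assert adjusted_rand_score(p1.labels(), p2.labels()) >= 0.9
        # identical seeds give identical output
        p1b = netgraph.spectral_partition(cg, k=4, seed=1)
        assert p1.assignment == p1b.assignment

    def test_too_few_nodes_rejected(self):
        cg = self._graph([(1, 2, 0.5)])
        with pytest.raises(ValueError, match="fewer than"):
            netgraph.spectral_partition(cg, k=4, seed=0)


class TestSeedCorrelation:
    def _setup(self):
        rng = np.random.default_rng(6)
        region_series = rng.standard_normal((4, 500))
        region_ids = [1, 2, 3, 4]
        part = netgraph.NetworkPartition(
            assignment={1: 1, 2: 1, 3: 2, 4: 2}, k=2, nodes=region_ids
        )
        return rng, region_series, region_ids, part

    def test_voxel_equal_to_centroid_r1(self):
        rng, series, ids, part = self._setup()
        cent = series[:2].mean(axis=0)
        vox = np.zeros((2, 2, 1, 500))
        vox[0, 0, 0] = cent
        vox[..., :] += 1e-8 * rng.standard_normal(vox.shape)
        mask = np.ones((2, 2, 1), bool)
        out = netgraph.seed_correlation_map(part, series, ids, vox, mask)
        assert out[1]["r"][0, 0, 0] == pytest.approx(1.0, abs=1e-4)

    def test_sign_symmetry(self):
        rng, series, ids, part = self._setup()
        vox = rng.standard_normal((2, 2, 1, 500))
        mask = np.ones((2, 2, 1), bool)
        out = netgraph.seed_correlation_map(part, series, ids, vox, mask)
        out_neg = netgraph.seed_correlation_map(part, -series, ids, vox, mask)
        np.testing.assert_allclose(out[1]["r"], -out_neg[1]["r"], atol=1e-12)

    def test_null_voxels_rarely_survive(self):
        rng, series, ids, part = self._setup()
        vox = rng.standard_normal((10, 10, 5, 500))
        mask = np.ones((10, 10, 5), bool)
        out = netgraph.seed_correlation_map(part, series, ids, vox, mask, min_voxels=2)
        frac = out[1]["survivors"].mean()
        assert frac <= 0.01

    def test_empty_mask_rejected(self):
        _, series, ids, part = self._setup()
        with pytest.raises(ValueError, match="empty"):
            netgraph.seed_correlation_map(
                part, series, ids, np.zeros((2, 2, 1, 500)), np.zeros((2, 2, 1), bool)
            )
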