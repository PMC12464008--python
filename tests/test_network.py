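"""Network building blocks: LSE, pooling, SA/FP layers, full forward."""

import numpy as np
import pytest

from phenocloud.autograd import Tensor
from phenocloud.network import (
    FPLayer,
    NetConfig,
    NetworkConfigError,
    SALayer,
    SALayerConfig,
    SegmentationNetwork,
    SharedMLP,
    attention_pool,
    dap_pool,
    interpolate_features,
    lse_encode,
    max_pool,
)
from phenocloud.pointops import knn_group


class TestLSE:
    def test_encoding_input_is_ten_wide_and_degenerate_self_neighbor(self, rng):
        coords = rng.random((12, 3))
        nbhd = knn_group(coords, np.arange(12), 4)
        mlp = SharedMLP(np.random.default_rng(0), 10, (6,))
        feats = Tensor(rng.random((12, 6)))
        out = lse_encode(coords, feats, nbhd, mlp)
        assert out.shape == (12, 4, 12)  # r_ik (6) concat q_ik (6)
        # self-neighbor: relative coords and distance are zero
        np.testing.assert_allclose(nbhd.neighbor_distances[:, 0], 0, atol=1e-12)

    def test_identity_mlp_recovers_distances(self, rng):
        """With weights selecting the distance channel, r_ik reproduces
        d(p_i, p_ik) from a brute-force oracle."""
        coords = rng.random((20, 3))
        nbhd = knn_group(coords, np.arange(20), 5)
        mlp = SharedMLP(np.random.default_rng(0), 10, (1,), norm=False)
        W = np.zeros((10, 1))
        W[9, 0] = 1.0  # the distance slot of [p_i, p_ik, p_i - p_ik, d]
        mlp.weights[0].data = W
        feats = Tensor(rng.random((20, 1)))
        out = lse_encode(coords, feats, nbhd, mlp)
        for i in range(20):
            for k in range(5):
                expected = np.linalg.norm(
                    coords[i] - coords[nbhd.neighbor_indices[i, k]]
                )
                assert out.data[i, k, 0] == pytest.approx(expected, abs=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        coords = rng.random((8, 3))
        nbhd = knn_group(coords, np.arange(8), 3)
        mlp = SharedMLP(np.random.default_rng(0), 10, (4,))
        feats = Tensor(rng.random((8, 6)))  # 6 != 4
        with pytest.raises(NetworkConfigError):
            lse_encode(coords, feats, nbhd, mlp)


class TestPooling:
    def test_constant_scorer_gives_neighbor_mean(self, rng):
        feats = Tensor(rng.random((7, 5, 4)))
        scorer = SharedMLP(np.random.default_rng(0), 4, (4,), final_relu=False,
                           norm=False)
        scorer.weights[0].data[:] = 0.0  # constant scores -> uniform weights
        out = attention_pool(feats, scorer)
        np.testing.assert_allclose(out.data, feats.data.mean(axis=1), atol=1e-12)

    def test_attention_weights_sum_to_one(self, rng):
        from phenocloud.autograd import softmax

        scores = Tensor(rng.normal(0, 3, (6, 8, 5)))
        w = softmax(scores, axis=1)
        np.testing.assert_allclose(w.data.sum(axis=1), 1.0, atol=1e-6)

    def test_k1_attention_is_identity(self, rng):
        feats = Tensor(rng.random((3, 1, 4)))
        scorer = SharedMLP(np.random.default_rng(1), 4, (4,), final_relu=False)
        out = attention_pool(feats, scorer)
        np.testing.assert_allclose(out.data, feats.data[:, 0], atol=1e-12)

    def test_max_pool_example_and_oracle(self, rng):
        feats = Tensor(np.array([[[1.0, 5.0], [3.0, 2.0]]]))
        np.testing.assert_array_equal(max_pool(feats).data, [[3.0, 5.0]])
        x = rng.normal(0, 1, (10, 6, 4))
        got = max_pool(Tensor(x)).data
        expected = np.array([[x[i, :, c].max() for c in range(4)] for i in range(10)])
        np.testing.assert_allclose(got, expected)

    def test_dap_shape_and_identity_fusion_width(self, rng):
        t = Tensor(rng.random((9, 4, 6)))
        high = rng.random(9) > 0.5
        scorer = SharedMLP(np.random.default_rng(0), 6, (6,), final_relu=False)
        out = dap_pool(t, high, None, scorer)
        assert out.shape == (9, 12)  # concat of two 6-wide branches

    def test_dap_gradient_reaches_both_branches(self, rng):
        """Finite-difference check that the fused output backpropagates into
        the neighbor features through both the max and the attention branch."""
        t_data = rng.random((5, 3, 4))
        high = np.array([True, False, True, False, True])
        scorer = SharedMLP(np.random.default_rng(2), 4, (4,), final_relu=False)
        fusion = SharedMLP(np.random.default_rng(3), 8, (4,))

        def loss_of(data):
            out = dap_pool(Tensor(data), high, fusion, scorer)
            return float((out * out).sum().data)

        t = Tensor(t_data.copy(), requires_grad=True)
        out = dap_pool(t, high, fusion, scorer)
        (out * out).sum().backward()
        assert t.grad is not None and np.abs(t.grad).max() > 0
        rng2 = np.random.default_rng(4)
        for _ in range(6):
            i, k, c = rng2.integers(0, [5, 3, 4])
            eps = 1e-6
            bumped = t_data.copy()
            bumped[i, k, c] += eps
            num = (loss_of(bumped) - loss_of(t_data)) / eps
            assert num == pytest.approx(t.grad[i, k, c], rel=1e-3, abs=1e-6)


class TestSALayer:
    def test_center_halving_stack(self, rng):
        cfg = NetConfig(num_points=1024, k=8, sa_channels=((8, 8), (8, 8), (8, 8)))
        centers = [c.n_centers for c in cfg.sa_configs()]
        assert centers == [512, 256, 128]

    def test_full_scale_halving(self):
        cfg = NetConfig(num_points=8192)
        assert cfg.sa_configs()[0].n_centers == 4096

    def test_layer_output_count(self, rng):
        coords = rng.random((64, 3))
        layer = SALayer(np.random.default_rng(0), 3,
                        SALayerConfig(n_centers=32, K=8, mlp_channels=(8, 16)))
        out_coords, out_feats = layer(coords, Tensor(coords), seed=0)
        assert out_coords.shape == (32, 3)
        assert out_feats.shape == (32, 16)

    def test_ablation_layer_matches_plain_reference(self, rng):
        """With LSE and DAP off, the layer is plain grouped-MLP + max pool;
        verify against a numpy re-implementation using the same weights."""
        coords = rng.random((40, 3))
        feats = rng.random((40, 3))
        layer = SALayer(
            np.random.default_rng(5), 3,
            SALayerConfig(n_centers=16, K=6, mlp_channels=(8,),
                          uses_lse=False, uses_dap=False),
        )
        out_coords, out_feats = layer(coords, Tensor(feats), seed=3)

        from phenocloud.pointops import farthest_point_sample

        centers = farthest_point_sample(coords, 16, seed=3)
        nbhd = knn_group(coords, centers, 6)
        rel = coords[centers][:, None, :] - coords[nbhd.neighbor_indices]
        grouped = np.concatenate([rel, feats[nbhd.neighbor_indices]], axis=-1)
        W = layer.fusion.weights[0].data
        b = layer.fusion.biases[0].data
        lin = grouped @ W + b
        flat = lin.reshape(-1, lin.shape[-1])
        mu, var = flat.mean(axis=0), flat.var(axis=0)
        normed = (flat - mu) / np.sqrt(var + SharedMLP.LN_EPS)
        normed = normed * layer.fusion.gammas[0].data + layer.fusion.betas[0].data
        act = np.maximum(normed, 0).reshape(lin.shape)
        expected = act.max(axis=1)
        np.testing.assert_allclose(out_feats.data, expected, atol=1e-10)
        np.testing.assert_allclose(out_coords, coords[centers])


class TestFeaturePropagation:
    def test_weights_sum_to_one_and_coincident_point(self, rng):
        coarse = rng.random((10, 3))
        fine = np.vstack([coarse[3], rng.random((5, 3))])
        feats = Tensor(rng.random((10, 4)))
        out = interpolate_features(fine, coarse, feats)
        # coincident fine point inherits the coarse feature (eps-dominated)
        np.testing.assert_allclose(out.data[0], feats.data[3], atol=1e-6)

    def test_two_equidistant_coarse_points_average(self):
        coarse = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        fine = np.array([[1.0, 0, 0]])
        feats = Tensor(np.array([[1.0, 3.0], [5.0, 7.0]]))
        out = interpolate_features(fine, coarse, feats)
        np.testing.assert_allclose(out.data[0], [3.0, 5.0], atol=1e-6)


@pytest.fixture(scope="module")
def small_net():
    return SegmentationNetwork(
        NetConfig(num_points=64, k=4, input_embed=(8,),
                  sa_channels=((8, 8), (8, 8)), fp_channels=(8, 8),
                  head_channels=8, dropout=0.0, seed=2)
    )


class TestForward:

    def test_output_shape_and_order(self, small_net, rng):
        coords = rng.random((64, 3))
        logits = small_net.forward(coords, seed=0)
        assert logits.shape == (64, 2)

    def test_wrong_point_count_rejected(self, small_net, rng):
        with pytest.raises(NetworkConfigError):
            small_net.forward(rng.random((32, 3)))

    def test_zero_initialized_head_gives_uniform_logits(self, small_net, rng):
        fresh = SegmentationNetwork(
            NetConfig(num_points=64, k=4, sa_channels=((8, 8),),
                      fp_channels=(8,), head_channels=8, dropout=0.0, seed=3)
        )
        logits = fresh.forward(rng.random((64, 3)), seed=0)
        np.testing.assert_allclose(logits.data, 0.0, atol=1e-12)

    def test_permutation_equivariance(self, small_net, rng):
        coords = rng.random((64, 3))
        base_starts = [5, 3]
        logits1 = small_net.forward(coords, seed=0, fps_start=base_starts)
        perm = rng.permutation(64)
        inv = np.argsort(perm)
        # first-layer start index follows its point; deeper layers index
        # the (identical) centre arrays and stay put
        starts2 = [int(inv[base_starts[0]]), base_starts[1]]
        logits2 = small_net.forward(coords[perm], seed=0, fps_start=starts2)
        np.testing.assert_allclose(logits2.data, logits1.data[perm], atol=1e-8)

    def test_checkpoint_round_trip(self, small_net, rng, tmp_path):
        coords = rng.random((64, 3))
        before = small_net.forward(coords, seed=1).data
        path = tmp_path / "ckpt.json"
        small_net.save(path)
        loaded = SegmentationNetwork.load(path)
        after = loaded.forward(coords, seed=1).data
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_ablation_has_fewer_parameters(self):
        full = SegmentationNetwork(
            NetConfig(num_points=64, k=4, sa_channels=((8, 8),), fp_channels=(8,),
                      head_channels=8, seed=0)
        )
        plain = SegmentationNetwork(
            NetConfig(num_points=64, k=4, sa_channels=((8, 8),), fp_channels=(8,),
                      head_channels=8, seed=0, uses_lse=False, uses_dap=False)
        )
        n_full = sum(p.data.size for p in full.parameters())
        n_plain = sum(p.data.size for p in plain.parameters())
        assert n_plain < n_full
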