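"""Saliency oracles: hand-evaluated CAM weights, rollout matrix products,
sign-partitioned SVM weight maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fusimap.containers import SaliencyMap
from fusimap.nn import CNNSpec, build_cnn
from fusimap.saliency import (
    FeatureActivations,
    attention_rollout,
    mean_map_over_time,
    svm_weight_map,
    upsample_bilinear,
    xgrad_cam,
)


class TestXGradCAM:
    def test_zero_gradients_give_zero_map(self):
        acts = FeatureActivations(
            maps=np.random.default_rng(0).random((3, 4, 5)),
            gradients=np.zeros((3, 4, 5)),
            class_score=1.0,
        )
        assert np.allclose(xgrad_cam(acts).grid, 0)

    def test_single_constant_channel_hand_evaluation(self):
        """A == 1 on 2x2, grad == g: w = g, map = max(0, g) everywhere."""
        for g in (0.7, -0.3):
            acts = FeatureActivations(
                maps=np.ones((1, 2, 2)),
                gradients=np.full((1, 2, 2), g),
                class_score=0.0,
            )
            assert np.allclose(xgrad_cam(acts).grid, max(0.0, g))

    def test_gap_linear_head_closed_form(self):
        """For a GAP+linear head the map equals max(0, sum_k theta_k A_k)/(h w)."""
        m = build_cnn(CNNSpec(n_conv_layers=2, channels=(3, 5), n_downsample=1), (10, 12))
        img = np.random.default_rng(1).random((10, 12)).astype(np.float32)
        for c in (0, 1):
            A, g, _ = m.feature_activations(img, c)
            cam = xgrad_cam(FeatureActivations(maps=A, gradients=g, class_score=0.0))
            h, w = A.shape[1:]
            theta = m.head.P["w"][:, c].astype(float)
            direct = np.maximum(0.0, np.tensordot(theta, A, axes=(0, 0)) / (h * w))
            assert np.allclose(cam.grid, direct, atol=1e-5)

    def test_weights_match_finite_difference_gradients(self):
        """Eq-style weights from backprop agree with central differences of
        the class score w.r.t. the target-layer activations."""
        m = build_cnn(CNNSpec(n_conv_layers=2, channels=(2, 2), n_downsample=2), (9, 12))
        img = np.random.default_rng(2).random((9, 12)).astype(np.float32)
        A, g, _ = m.feature_activations(img, 1)
        eps = 1e-3
        num = np.zeros_like(A)
        for k in range(A.shape[0]):
            for i in range(A.shape[1]):
                for j in range(A.shape[2]):
                    up, dn = A.copy(), A.copy()
                    up[k, i, j] += eps
                    dn[k, i, j] -= eps
                    num[k, i, j] = (
                        m.head_scores(up[None])[0, 1] - m.head_scores(dn[None])[0, 1]
                    ) / (2 * eps)
        assert np.abs(num - g).max() < 1e-3

    def test_all_zero_channel_is_inert(self):
        rng = np.random.default_rng(3)
        maps = rng.random((3, 4, 4))
        grads = rng.random((3, 4, 4))
        maps[1] = 0.0
        base = xgrad_cam(FeatureActivations(maps=maps, gradients=grads, class_score=0.0))
        grads2 = grads.copy()
        grads2[1] = 99.0  # a dead channel's gradients must not matter
        other = xgrad_cam(FeatureActivations(maps=maps, gradients=grads2, class_score=0.0))
        assert np.allclose(base.grid, other.grid)
        assert np.all(np.isfinite(base.grid))

    def test_invariant_to_other_class_logit(self):
        """Only dY_c/dA enters: shifting the other logit's weights changes nothing."""
        m = build_cnn(CNNSpec(n_conv_layers=1, channels=(4,), n_downsample=1), (8, 8))
        img = np.random.default_rng(4).random((8, 8)).astype(np.float32)
        A, g, _ = m.feature_activations(img, 1)
        before = xgrad_cam(FeatureActivations(maps=A, gradients=g, class_score=0.0)).grid
        m.head.P["w"][:, 0] += 5.0
        A2, g2, _ = m.feature_activations(img, 1)
        after = xgrad_cam(FeatureActivations(maps=A2, gradients=g2, class_score=0.0)).grid
        assert np.allclose(before, after)


class TestUpsample:
    def test_constant_preserved(self):
        m = SaliencyMap("drug", np.full((12, 16), 5.0), "cam")
        up = upsample_bilinear(m, (91, 128))
        assert up.grid.shape == (91, 128)
        assert np.allclose(up.grid, 5.0)

    def test_range_preserved_and_roundtrip_correlates(self):
        rng = np.random.default_rng(0)
        grid = rng.random((12, 16))
        up = upsample_bilinear(SaliencyMap("drug", grid, "cam"), (91, 128))
        assert up.grid.min() >= grid.min() - 1e-12
        assert up.grid.max() <= grid.max() + 1e-12
        # block-average back down to 12x16 (91 rows ~ 7.58 rows/cell: use crop)
        from skimage.transform import resize

        down = resize(up.grid, (12, 16), order=1, anti_aliasing=False)
        r = np.corrcoef(down.ravel(), grid.ravel())[0, 1]
        assert r > 0.95

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError):
            upsample_bilinear(SaliencyMap("drug", np.ones((12, 16)), "cam"), (6, 8))


class TestAttentionRollout:
    def test_identity_attention_degenerates_to_class_token_only(self):
        eye = np.eye(5)
        m = attention_rollout([eye, eye], discard_ratio=0.0, grid=(2, 2))
        assert np.allclose(m.grid, 0.0)

    def test_single_uniform_layer_closed_form(self):
        n = 5
        uni = np.full((n, n), 1.0 / n)
        m = attention_rollout([uni], discard_ratio=0.0, grid=(2, 2))
        # (A + I) row-normalized: class row = [(1+1/n)/2, 1/(2n), ...]
        assert np.allclose(m.grid, 1.0 / (2 * n))

    def test_two_layers_equal_explicit_matrix_product(self):
        rng = np.random.default_rng(5)
        mats = []
        for _ in range(2):
            a = rng.random((6, 6))
            mats.append(a / a.sum(axis=1, keepdims=True))
        got = attention_rollout(mats, discard_ratio=0.0, grid=None).grid.ravel()
        procs = []
        for a in mats:
            b = a + np.eye(6)
            procs.append(b / b.sum(axis=1, keepdims=True))
        expected = (procs[1] @ procs[0])[0, 1:]
        assert np.allclose(got, expected)

    def test_discard_spares_class_token_column(self):
        rng = np.random.default_rng(6)
        a = rng.random((8, 8))
        a = a / a.sum(axis=1, keepdims=True)
        m = attention_rollout([a], discard_ratio=0.9, grid=None)
        assert np.all(np.isfinite(m.grid))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            attention_rollout([np.ones((3, 4))])
        with pytest.raises(ValueError):
            attention_rollout([np.ones((3, 3))])  # rows sum to 3, not stochastic


class TestSVMWeightMap:
    def test_hand_example_sign_filter_and_inversion(self):
        w = np.array([-2.0, 1.0, 0.0, -0.5])
        maps = svm_weight_map([w], image_shape=(2, 2))
        assert np.allclose(maps[0].grid, [[2.0, 0.0], [0.0, 0.5]])

    def test_all_positive_weights_give_zero_map(self):
        maps = svm_weight_map([np.ones(6)], image_shape=(2, 3))
        assert np.allclose(maps[0].grid, 0)

    def test_order_and_count_preserved(self):
        ws = [np.full(4, -float(i + 1)) for i in range(5)]
        maps = svm_weight_map(ws, image_shape=(2, 2))
        assert len(maps) == 5
        assert [m.grid[0, 0] for m in maps] == [1.0, 2.0, 3.0, 4.0, 5.0]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(np.float64, (12,), elements=st.floats(-5, 5, allow_nan=False))
    )
    def test_sign_partition_reconstructs_absolute_value(self, w):
        pos = svm_weight_map([w], image_shape=(3, 4))[0].grid
        neg = svm_weight_map([-w], image_shape=(3, 4))[0].grid
        assert np.allclose(pos + neg, np.abs(w).reshape(3, 4))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            svm_weight_map([np.ones(5)], image_shape=(2, 2))


class TestMeanMap:
    def test_mean_of_constant_maps(self):
        m0 = SaliencyMap("drug", np.zeros((3, 3)), "cam")
        m2 = SaliencyMap("drug", np.full((3, 3), 2.0), "cam")
        assert np.allclose(mean_map_over_time([m0, m2]).grid, 1.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        maps = [SaliencyMap("drug", rng.random((4, 4)), "cam") for _ in range(4)]
        a = mean_map_over_time(maps).grid
        b = mean_map_over_time(maps[::-1]).grid
        assert np.allclose(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_map_over_time([])
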