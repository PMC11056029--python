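"""Masked layer, cross-sample attention, fusion, loss and training contracts."""

import math

import numpy as np
import pytest

from pathattn.autodiff import Tensor
from pathattn.model import (AttentionParams, HierarchicalLayerParams,
                            PathAttnModel, TrainConfig, compute_class_weights,
                            fuse, masked_forward, pathway_self_attention,
                            predict, train, weighted_loss)
from pathattn.pathways import MembershipMatrix


def hier(mask, mode="trainable", activation="identity", seed=0):
    return HierarchicalLayerParams(np.asarray(mask, float), activation=activation,
                                   mode=mode, rng=np.random.default_rng(seed))


class TestMaskedForward:
    def test_literal_mode_matches_hand_product(self):
        layer = hier([[1, 0], [1, 1]], mode="literal")
        out = masked_forward(layer, np.array([[1.0, 2.0]]))
        np.testing.assert_allclose(out.data, [[3.0, 2.0]])

    def test_all_ones_mask_equals_dense_affine(self, rng):
        layer = hier(np.ones((6, 4)), activation="tanh")
        X = rng.normal(size=(5, 6))
        out = masked_forward(layer, X)
        dense = np.tanh(X @ layer.weight.data + layer.bias.data)
        np.testing.assert_allclose(out.data, dense, atol=1e-6)

    def test_all_zero_mask_broadcasts_bias(self, rng):
        layer = hier(np.zeros((3, 2)))
        layer.bias.data[:] = [1.5, -2.0]
        out = masked_forward(layer, rng.normal(size=(4, 3)))
        np.testing.assert_allclose(out.data, np.tile([1.5, -2.0], (4, 1)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="features"):
            masked_forward(hier(np.ones((3, 2))), rng.normal(size=(2, 4)))

    def test_mask_zero_positions_get_zero_gradient_and_no_influence(self, rng):
        mask = (rng.random((8, 5)) < 0.4).astype(float)
        mask[0, 0] = 1.0  # keep at least one connection
        layer = hier(mask, activation="relu")
        X = rng.normal(size=(6, 8))
        out = masked_forward(layer, X)
        out.sum().backward()
        assert (layer.weight.grad[mask == 0] == 0).all()
        # overwriting masked weights does not change the forward pass
        before = masked_forward(layer, X).data
        layer.weight.data[mask == 0] = rng.normal(size=int((mask == 0).sum())) * 1e3
        after = masked_forward(layer, X).data
        np.testing.assert_array_equal(before, after)


class TestAttention:
    def test_batch_of_one_is_identity_on_v(self, rng):
        params = AttentionParams(4, 3, rng=rng)
        H = rng.normal(size=(1, 4))
        B, rec = pathway_self_attention(params, H)
        np.testing.assert_allclose(rec.attn_weights, [[1.0]])
        np.testing.assert_allclose(B.data, H @ params.Wv.data)

    def test_identical_rows_give_uniform_weights(self, rng):
        params = AttentionParams(4, 3, rng=rng)
        H = np.tile(rng.normal(size=(1, 4)), (5, 1))
        B, rec = pathway_self_attention(params, H)
        np.testing.assert_allclose(rec.attn_weights, np.full((5, 5), 0.2),
                                   atol=1e-12)
        np.testing.assert_allclose(B.data, np.tile(H[:1] @ params.Wv.data, (5, 1)))

    def test_two_sample_toy_matches_hand_arithmetic(self):
        # H=[[1],[2]], Wq=Wk=Wv=[[1]], d=1: alpha=[[1,2],[2,4]],
        # w_11 = 1/(1+e), B_i = w_i1*1 + w_i2*2
        params = AttentionParams(1, 1)
        for W in (params.Wq, params.Wk, params.Wv):
            W.data[:] = 1.0
        B, rec = pathway_self_attention(params, np.array([[1.0], [2.0]]))
        np.testing.assert_allclose(rec.attn_scores, [[1, 2], [2, 4]], atol=1e-12)
        assert rec.attn_weights[0, 0] == pytest.approx(1 / (1 + math.e), abs=1e-12)
        w = rec.attn_weights
        expected_B = np.array([[w[0, 0] + 2 * w[0, 1]], [w[1, 0] + 2 * w[1, 1]]])
        np.testing.assert_allclose(B.data, expected_B, atol=1e-12)

    def test_rows_sum_to_one_and_values_recombine(self, rng):
        params = AttentionParams(6, 4, rng=rng)
        H = rng.normal(size=(7, 6))
        B, rec = pathway_self_attention(params, H)
        np.testing.assert_allclose(rec.attn_weights.sum(axis=1), np.ones(7),
                                   atol=1e-6)
        V = H @ params.Wv.data
        np.testing.assert_allclose(B.data, rec.attn_weights @ V, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        params = AttentionParams(5, 3, rng=rng)
        H = rng.normal(size=(6, 5))
        perm = rng.permutation(6)
        B, _ = pathway_self_attention(params, H)
        Bp, _ = pathway_self_attention(params, H[perm])
        np.testing.assert_allclose(Bp.data, B.data[perm], atol=1e-10)

    def test_non_finite_input_rejected(self, rng):
        params = AttentionParams(2, 2, rng=rng)
        with pytest.raises(ValueError, match="non-finite"):
            pathway_self_attention(params, np.array([[1.0, np.nan]]))


class TestFuse:
    def test_concatenation_shape(self, rng):
        parts = [rng.normal(size=(3, 64)) for _ in range(3)]
        assert fuse(parts).shape == (3, 192)

    def test_single_modality_identity(self, rng):
        X = rng.normal(size=(4, 8))
        np.testing.assert_array_equal(fuse([X]).data, X)

    def test_batch_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="batch"):
            fuse([rng.normal(size=(3, 2)), rng.normal(size=(4, 2))])


class TestClassWeights:
    def test_balanced(self):
        assert compute_class_weights([0] * 50 + [1] * 50) == (1.0, 1.0)

    def test_imbalanced_100_150(self):
        w0, w1 = compute_class_weights([1] * 100 + [0] * 150)
        assert w1 == pytest.approx(1.25)
        assert w0 == pytest.approx(0.83333333)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights([1, 1, 1])


class TestWeightedLoss:
    def test_half_probability_gives_ln2(self):
        loss = weighted_loss(None, Tensor([0.5]), [1], 1.0, 1.0, 0.0)
        assert loss.data == pytest.approx(math.log(2), abs=1e-9)

    def test_matches_textbook_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, size=40)
        y = rng.integers(0, 2, size=40)
        loss = weighted_loss(None, Tensor(p), y, 1.0, 1.0, 0.0)
        ref = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert loss.data == pytest.approx(ref, abs=1e-7)

    def test_regularizer_linear_in_gamma(self, small_selected):
        cohort, mems, _ = small_selected
        model = PathAttnModel(mems, TrainConfig(seed=0))
        p = Tensor(np.full(4, 0.3))
        y = np.array([0, 1, 0, 1])
        l1 = weighted_loss(model, p, y, 1.0, 1.0, 1e-3).data
        l2 = weighted_loss(model, p, y, 1.0, 1.0, 2e-3).data
        norm2 = sum(float((t.data ** 2).sum()) for t in model.l2_terms())
        assert l2 - l1 == pytest.approx(1e-3 * norm2, rel=1e-9)

    def test_extreme_probabilities_clamped(self):
        loss = weighted_loss(None, Tensor([0.0, 1.0]), [0, 1], 1.0, 1.0, 0.0)
        assert np.isfinite(loss.data)


class TestTrainPredict:
    def test_same_seed_reproduces_loss_trajectory(self, small_selected):
        cohort, mems, _ = small_selected
        cfg = TrainConfig(epochs=3, seed=11)
        _, log1 = train(cohort, mems, cfg)
        _, log2 = train(cohort, mems, cfg)
        assert log1["loss"].tolist() == log2["loss"].tolist()
        assert log1["train_auc"].tolist() == log2["train_auc"].tolist()

    def test_loss_decreases_on_planted_signal(self, trained_model):
        _, log, _, _ = trained_model
        assert log["loss"].iloc[-1] < log["loss"].iloc[0]

    def test_masked_positions_untouched_by_training(self, small_selected):
        cohort, mems, _ = small_selected
        cfg = TrainConfig(epochs=2, seed=5)
        model, _ = train(cohort, mems, cfg)
        for mod in model.modalities:
            hl = model.hierarchical[mod]
            fresh = PathAttnModel(mems, cfg).hierarchical[mod]
            mask0 = hl.mask.data == 0
            np.testing.assert_array_equal(hl.weight.data[mask0],
                                          fresh.weight.data[mask0])

    def test_untrained_zeroed_head_predicts_half(self, small_selected):
        cohort, mems, _ = small_selected
        model = PathAttnModel(mems, TrainConfig(seed=0))
        model.head.zero_output_layer()
        scores = predict(model, cohort, batch_policy="self")
        np.testing.assert_allclose(scores, 0.5, atol=1e-12)

    def test_self_policy_is_permutation_equivariant(self, trained_model, rng):
        model, _, cohort, _ = trained_model
        X = {m: cohort.layers[m].values[:20] for m in model.modalities}
        perm = rng.permutation(20)
        s1 = predict(model, X, batch_policy="self")
        s2 = predict(model, {m: v[perm] for m, v in X.items()},
                     batch_policy="self")
        np.testing.assert_allclose(s2, s1[perm], atol=1e-12)

    def test_reference_policy_independent_of_cobatch(self, trained_model):
        model, _, cohort, _ = trained_model
        X = {m: cohort.layers[m].values for m in model.modalities}
        alone = predict(model, {m: v[:1] for m, v in X.items()},
                        batch_policy="reference")
        together = predict(model, {m: v[:10] for m, v in X.items()},
                           batch_policy="reference")
        assert together[0] == pytest.approx(alone[0], abs=1e-12)

    def test_probabilities_in_unit_interval(self, trained_model):
        model, _, cohort, _ = trained_model
        scores = predict(model, cohort, batch_policy="self")
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_literal_mode_trains_bias_only(self, small_selected):
        cohort, mems, _ = small_selected
        cfg = TrainConfig(epochs=2, seed=5, mask_mode="literal")
        model, log = train(cohort, mems, cfg)
        for mod in model.modalities:
            np.testing.assert_array_equal(model.hierarchical[mod].weight.data,
                                          np.ones(mems[mod].values.shape))
        assert np.isfinite(log["loss"]).all()

    def test_save_load_round_trip(self, trained_model, tmp_path):
        model, _, cohort, _ = trained_model
        model.save(tmp_path / "ckpt.npz")
        clone = PathAttnModel.load(tmp_path / "ckpt.npz")
        X = {m: cohort.layers[m].values[:8] for m in model.modalities}
        np.testing.assert_allclose(predict(clone, X, "self"),
                                   predict(model, X, "self"), atol=1e-12)


def test_train_config_validates_batch_size():
    with pytest.raises(ValueError, match="batch_size"):
        TrainConfig(batch_size=1, attn_dim=8)


def test_train_config_allows_batch_one_without_attention():
    TrainConfig(batch_size=1, attn_dim=0)
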