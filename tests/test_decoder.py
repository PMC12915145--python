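"""Cross-attention decoder: attention oracle values, window construction,
norm-weighted aggregation, classifier identities, masking invariances."""

import numpy as np
import pytest

from resbind._autodiff import Tensor
from resbind.datamodel import ProteinRecord, RunConfig
from resbind.decoder import (
    Classifier,
    DecoderLayer,
    aggregate_significance,
    attention,
    build_local_context,
)
from resbind.embedding import SyntheticEmbedder
from resbind.model import BindingSiteModel, predict_protein


class TestAttention:
    def test_single_unmasked_key_copies_value(self):
        Q = np.array([[0.3, -0.2]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[5.0, 6.0], [7.0, 8.0]])
        mask = np.array([1.0, 0.0])
        out, weights = attention(Q, K, V, mask)
        np.testing.assert_allclose(out.data, [[5.0, 6.0]])
        np.testing.assert_allclose(weights.data, [[1.0, 0.0]])

    def test_identical_keys_average_values(self, rng):
        K = np.tile(rng.normal(size=(1, 3)), (4, 1))
        V = rng.normal(size=(4, 3))
        out, weights = attention(rng.normal(size=(2, 3)), K, V)
        np.testing.assert_allclose(weights.data, np.full((2, 4), 0.25))
        np.testing.assert_allclose(out.data, np.tile(V.mean(axis=0), (2, 1)))

    def test_hand_softmax_example(self):
        """Two keys, d_k = 2: weights are softmax([1/sqrt(2), 0])."""
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out, weights = attention(Q, K, V)
        e = np.exp(1.0 / np.sqrt(2.0))
        expected = np.array([e, 1.0]) / (e + 1.0)
        np.testing.assert_allclose(weights.data[0], expected, atol=1e-12)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)
        assert abs(expected[0] - 0.670) < 1e-3  # hand-computed oracle

    def test_rows_sum_to_one_and_masked_keys_zero(self, rng):
        Q = rng.normal(size=(6, 4))
        K = rng.normal(size=(9, 4))
        V = rng.normal(size=(9, 4))
        mask = np.ones(9)
        mask[5:] = 0
        _, weights = attention(Q, K, V, mask)
        np.testing.assert_allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(weights.data[:, 5:] == 0.0)

    def test_fully_masked_query_rejected(self, rng):
        with pytest.raises(ValueError, match="unmasked key"):
            attention(rng.normal(size=(1, 2)), rng.normal(size=(3, 2)),
                      rng.normal(size=(3, 2)), np.zeros(3))


class TestLocalContext:
    def test_boundary_masking(self, rng):
        P = Tensor(rng.normal(size=(10, 6)))
        ctx = build_local_context(P, np.array([0]), window_size=5)
        assert ctx.mask[0].tolist() == [0.0, 0.0, 1.0, 1.0, 1.0]
        assert np.all(ctx.values.data[0, :2] == 0.0)
        assert ctx.center_index == 2

    def test_interior_fully_valid_and_contents(self, rng):
        P = Tensor(rng.normal(size=(10, 6)))
        ctx = build_local_context(P, np.array([5]), window_size=5)
        assert ctx.mask[0].all()
        np.testing.assert_allclose(ctx.values.data[0], P.data[3:8])

    def test_degenerate_window_is_residue_itself(self, rng):
        P = Tensor(rng.normal(size=(10, 6)))
        ctx = build_local_context(P, np.array([4]), window_size=1)
        np.testing.assert_allclose(ctx.values.data[0], P.data[4:5])

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError):
            build_local_context(Tensor(rng.normal(size=(5, 3))), np.array([1]), window_size=4)

    def test_position_embedding_added_to_valid_slots_only(self, rng):
        P = Tensor(rng.normal(size=(8, 4)))
        pe = Tensor(rng.normal(size=(5, 4)))
        ctx = build_local_context(P, np.array([0, 4]), window_size=5, position_embedding=pe)
        np.testing.assert_allclose(ctx.values.data[1], P.data[2:7] + pe.data)
        assert np.all(ctx.values.data[0, :2] == 0.0)


class TestAggregation:
    def test_equal_rows_uniform_weights(self):
        H = np.tile(np.array([1.0, 2.0]), (1, 4, 1))
        out = aggregate_significance(Tensor(H), np.ones((1, 4)))
        np.testing.assert_allclose(out.data, [[1.0, 2.0]], atol=1e-9)

    def test_single_valid_row_passthrough(self, rng):
        H = rng.normal(size=(1, 3, 4))
        mask = np.array([[0.0, 1.0, 0.0]])
        out = aggregate_significance(Tensor(H), mask)
        np.testing.assert_allclose(out.data[0], H[0, 1], atol=1e-9)

    def test_worked_norm_example(self):
        """Rows [3,4] (norm 5) and [0,0] (norm 0): weights e^5 : 1."""
        H = np.array([[[3.0, 4.0], [0.0, 0.0]]])
        out = aggregate_significance(Tensor(H), np.ones((1, 2)))
        w = np.exp(5.0) / (np.exp(5.0) + 1.0)
        np.testing.assert_allclose(out.data[0], [3.0 * w, 4.0 * w], atol=1e-6)
        np.testing.assert_allclose(out.data[0], [2.9799, 3.9732], atol=1e-3)

    def test_convex_combination(self, rng):
        """Weights are >= 0, sum to 1 over valid rows; output in convex hull."""
        H = rng.normal(size=(3, 5, 4))
        mask = np.ones((3, 5))
        mask[0, 3:] = 0
        out = aggregate_significance(Tensor(H), mask).data
        for b in range(3):
            valid = H[b][mask[b].astype(bool)]
            lo, hi = valid.min(axis=0), valid.max(axis=0)
            assert np.all(out[b] >= lo - 1e-9) and np.all(out[b] <= hi + 1e-9)

    def test_squared_norm_variant(self):
        H = np.array([[[3.0, 4.0], [0.0, 0.0]]])
        out = aggregate_significance(Tensor(H), np.ones((1, 2)), squared_norm=True)
        w = np.exp(25.0) / (np.exp(25.0) + 1.0)
        np.testing.assert_allclose(out.data[0], [3.0 * w, 4.0 * w], atol=1e-6)

    def test_all_masked_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate_significance(Tensor(rng.normal(size=(1, 3, 2))), np.zeros((1, 3)))


class TestClassifier:
    def test_probabilities_sum_to_one(self, rng):
        clf = Classifier(d_hid=8, rng=rng)
        z, prob = clf(Tensor(rng.normal(size=(5, 8))))
        full = np.exp(z.data - z.data.max(axis=-1, keepdims=True))
        full /= full.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(prob.data, full[:, 1], atol=1e-12)
        assert z.shape == (5, 2)

    def test_zero_weights_give_half(self, rng):
        clf = Classifier(d_hid=8, rng=rng)
        for p in clf.parameters():
            p.data[:] = 0.0
        _, prob = clf(Tensor(rng.normal(size=(3, 8))))
        np.testing.assert_allclose(prob.data, 0.5)

    def test_probability_is_sigmoid_of_logit_difference(self, rng):
        clf = Classifier(d_hid=8, rng=rng)
        z, prob = clf(Tensor(rng.normal(size=(4, 8))))
        diff = z.data[:, 1] - z.data[:, 0]
        np.testing.assert_allclose(prob.data, 1.0 / (1.0 + np.exp(-diff)), atol=1e-12)


class TestDecoderLayer:
    def test_padding_rows_in_protein_do_not_change_output(self, small_config, rng):
        layer = DecoderLayer(small_config, rng)
        d = small_config.d_hid
        x = Tensor(rng.normal(size=(3, 5, d)))
        H_p = rng.normal(size=(1, 8, d))
        out1, _ = layer(x, Tensor(H_p), np.ones((3, 5)), np.ones((1, 8)))
        H_pad = np.concatenate([H_p, rng.normal(size=(1, 4, d))], axis=1)
        pmask = np.concatenate([np.ones((1, 8)), np.zeros((1, 4))], axis=1)
        out2, _ = layer(Tensor(x.data.copy()), Tensor(H_pad), np.ones((3, 5)), pmask)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-5)

    def test_zeroed_sublayers_reduce_to_iterated_layernorm(self, small_config, rng):
        layer = DecoderLayer(small_config, rng)
        for attn in (layer.self_attn, layer.cross_attn):
            for p in attn.parameters():
                p.data[:] = 0.0
        for p in layer.ffn.parameters():
            p.data[:] = 0.0
        d = small_config.d_hid
        x = rng.normal(size=(2, 3, d))
        H_p = Tensor(rng.normal(size=(1, 6, d)))
        out, _ = layer(Tensor(x), H_p, np.ones((2, 3)), np.ones((1, 6)))
        expected = x
        for norm in (layer.norm1, layer.norm2, layer.norm3):
            expected = norm(Tensor(expected)).data
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_attention_rows_sum_to_one(self, small_config, rng):
        layer = DecoderLayer(small_config, rng)
        d = small_config.d_hid
        wmask = np.ones((2, 5))
        wmask[0, :2] = 0
        _, (w_self, w_cross) = layer(
            Tensor(rng.normal(size=(2, 5, d))), Tensor(rng.normal(size=(1, 7, d))),
            wmask, np.ones((1, 7)),
        )
        np.testing.assert_allclose(w_self.data.sum(axis=-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(w_cross.data.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w_self.data[0, :, :, :2] == 0.0)  # masked keys: zero weight


class TestPredictProtein:
    def test_one_row_per_residue_and_determinism(self, small_config):
        protein = ProteinRecord("p1", "MKVLINGKTLKG")
        embedder = SyntheticEmbedder(d_p=8, seed=1)
        model = BindingSiteModel(small_config, d_p=8, seed=2)
        t1 = predict_protein(protein, embedder, model)
        t2 = predict_protein(protein, embedder, model)
        assert len(t1) == len(protein)
        assert [r.probability for r in t1.rows] == [r.probability for r in t2.rows]
        assert all(r.call == (r.probability >= 0.5) for r in t1.rows)

    def test_chunk_size_invariance(self, small_config):
        protein = ProteinRecord("p1", "MKVLINGKTLKGEITVDGAKNAVLPILA")
        embedder = SyntheticEmbedder(d_p=8, seed=1)
        model = BindingSiteModel(small_config, d_p=8, seed=2)
        emb = embedder(protein)
        p_small = model.predict_probabilities(emb, chunk_size=4)
        p_large = model.predict_probabilities(emb, chunk_size=256)
        np.testing.assert_allclose(p_small, p_large, atol=1e-6)

    def test_cross_attention_ablated_prediction_is_window_local(self, small_config):
        """With the cross-attention output zeroed, a residue's prediction
        depends only on its local window, not the rest of the protein."""
        model = BindingSiteModel(small_config, d_p=8, seed=9)
        for layer in model.dec_layers:
            layer.cross_attn.wo.weight.data[:] = 0.0
            layer.cross_attn.wo.bias.data[:] = 0.0
        rng = np.random.default_rng(0)
        shared = rng.normal(size=(small_config.window_size, 8))
        emb_a = np.vstack([shared, rng.normal(size=(6, 8))])
        emb_b = np.vstack([shared, rng.normal(size=(6, 8))])  # different tail
        from resbind.embedding import EmbeddingMatrix

        center = (small_config.window_size - 1) // 2
        pa, _, _ = model.forward_residues(EmbeddingMatrix("a", emb_a), np.array([center]))
        pb, _, _ = model.forward_residues(EmbeddingMatrix("b", emb_b), np.array([center]))
        np.testing.assert_allclose(pa.data, pb.data, atol=1e-9)

    def test_wrong_embedding_width_rejected(self, small_config, toy_protein):
        model = BindingSiteModel(small_config, d_p=8, seed=2)
        bad = SyntheticEmbedder(d_p=16, seed=1)
        with pytest.raises(ValueError, match="d_p"):
            model.forward_residues(bad(toy_protein), np.array([0]))
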