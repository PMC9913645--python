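"""Architecture contracts: backbone shapes, attention, transformer blocks,
classifier head, and the cross-entropy loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

from restransnet.model import (
    ModelConfig,
    ResTransNet,
    TransformerBlock,
    attention,
    ce_loss,
    load_checkpoint,
    save_checkpoint,
)
from restransnet.nn import Tensor

from conftest import tiny_config


# ------------------------------------------------------------ scalar oracle
def _layer_norm_rows(x, gamma, beta, eps=1e-5):
    out = np.empty_like(x)
    for i, row in enumerate(x):
        out[i] = (row - row.mean()) / np.sqrt(row.var() + eps) * gamma + beta
    return out


def _gelu(x):
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def attention_oracle(q, k, v):
    """Loop-based softmax-weighted sum over tokens (single head)."""
    n, dk = q.shape
    out = np.zeros_like(v)
    for i in range(n):
        scores = np.array([q[i] @ k[j] / np.sqrt(dk) for j in range(n)])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        for j in range(n):
            out[i] += w[j] * v[j]
    return out


def block_oracle(x, blk: TransformerBlock):
    """Scalar re-implementation of Z = MSA(LN(X)) + X, Y = MLP(LN(Z)) + Z
    for a single-head block, straight from the module's weights."""
    h = _layer_norm_rows(x, blk.ln1.gamma.data, blk.ln1.beta.data)
    q = h @ blk.msa.wq.weight.data + blk.msa.wq.bias.data
    k = h @ blk.msa.wk.weight.data + blk.msa.wk.bias.data
    v = h @ blk.msa.wv.weight.data + blk.msa.wv.bias.data
    z = attention_oracle(q, k, v) @ blk.msa.wo.weight.data + blk.msa.wo.bias.data + x
    h2 = _layer_norm_rows(z, blk.ln2.gamma.data, blk.ln2.beta.data)
    mlp = _gelu(h2 @ blk.fc1.weight.data + blk.fc1.bias.data)
    return mlp @ blk.fc2.weight.data + blk.fc2.bias.data + z


def _to_float64(module):
    for p in module.parameters():
        p.data = p.data.astype(np.float64)


class TestAttention:
    def test_single_token_returns_values_exactly(self):
        rng = np.random.default_rng(0)
        q, k, v = (Tensor(rng.normal(size=(1, 1, 4))) for _ in range(3))
        out, w = attention(q, k, v)
        np.testing.assert_allclose(out.data, v.data)
        assert w[0, 0, 0] == pytest.approx(1.0)

    def test_identical_keys_give_uniform_attention(self):
        rng = np.random.default_rng(1)
        q = Tensor(rng.normal(size=(1, 3, 4)))
        k = Tensor(np.tile(rng.normal(size=(1, 1, 4)), (1, 3, 1)))
        v = Tensor(rng.normal(size=(1, 3, 4)))
        out, w = attention(q, k, v)
        np.testing.assert_allclose(w, 1.0 / 3.0, atol=1e-7)
        np.testing.assert_allclose(out.data, np.broadcast_to(
            v.data.mean(axis=1, keepdims=True), out.shape), atol=1e-7)

    def test_three_token_instance_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        q, k, v = (rng.normal(size=(3, 4)) for _ in range(3))
        out, _ = attention(Tensor(q), Tensor(k), Tensor(v))
        np.testing.assert_allclose(out.data, attention_oracle(q, k, v), atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_attention_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        q, k, v = (Tensor(rng.normal(size=(2, 5, 3))) for _ in range(3))
        _, w = attention(q, k, v)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)


class TestTransformerBlock:
    def test_matches_scalar_oracle_on_three_tokens(self):
        rng = np.random.default_rng(3)
        blk = TransformerBlock(d=4, n_heads=1, mlp_ratio=2, rng=rng)
        _to_float64(blk)
        x = rng.normal(size=(3, 4))
        got = blk(Tensor(x[None])).data[0]
        np.testing.assert_allclose(got, block_oracle(x, blk), atol=1e-10)

    def test_zeroed_output_projections_give_exact_identity(self):
        rng = np.random.default_rng(4)
        blk = TransformerBlock(d=8, n_heads=2, mlp_ratio=4, rng=rng)
        for lin in (blk.msa.wo, blk.fc2):
            lin.weight.data = np.zeros_like(lin.weight.data)
            lin.bias.data = np.zeros_like(lin.bias.data)
        x = rng.normal(size=(2, 5, 8)).astype(np.float32)
        np.testing.assert_array_equal(blk(Tensor(x)).data, x)

    def test_shape_preserved_through_all_blocks(self, tiny_model):
        rng = np.random.default_rng(5)
        seq = Tensor(rng.normal(size=(2, 5, 16)).astype(np.float32))
        for blk in tiny_model.blocks:
            seq = blk(seq)
            assert seq.shape == (2, 5, 16)

    def test_loss_gradient_reaches_every_token(self, tiny_model):
        rng = np.random.default_rng(6)
        seq = Tensor(rng.normal(size=(1, 5, 16)).astype(np.float32),
                     requires_grad=True)
        out = tiny_model.head_forward(tiny_model.transformer_forward(seq))
        ce_loss(out.softmax(axis=-1)[:, 1], np.array([1])).backward()
        token_grad_norms = np.linalg.norm(seq.grad[0], axis=1)
        assert (token_grad_norms > 0).all()


class TestBackboneAndEmbedding:
    def test_default_backbone_shape_and_channel_progression(self):
        model = ResTransNet(ModelConfig(depth=1))
        x = Tensor(np.random.default_rng(0).random((2, 1, 128, 128),
                                                   dtype=np.float32))
        feat = model.backbone(x)
        assert feat.shape == (2, 16, 16, 64)  # channels-last feature map
        assert model.backbone.block1.conv1.weight.shape[0] == 16
        assert model.backbone.block2.conv1.weight.shape[0] == 32
        assert model.backbone.block3.conv1.weight.shape[0] == 64

    def test_zeroed_residual_branch_reduces_to_shortcut(self, tiny_model):
        blk = tiny_model.backbone.block2
        for conv in (blk.conv1, blk.conv2):
            conv.weight.data = np.zeros_like(conv.weight.data)
            conv.bias.data = np.zeros_like(conv.bias.data)
        blk.bn2.beta.data = np.zeros_like(blk.bn2.beta.data)
        tiny_model.eval()
        x = Tensor(np.random.default_rng(1).random((2, 64, 64, 2),
                                                   dtype=np.float32))
        np.testing.assert_allclose(blk(x).data, blk.shortcut(x).relu().data,
                                   atol=1e-6)

    def test_eval_mode_batching_invariance(self, tiny_model, small_cohort):
        tiny_model.eval()
        x = np.stack([s.image.pixels for s in small_cohort[:4]])[:, None]
        batch = tiny_model.forward(x).data
        singles = np.concatenate([tiny_model.forward(x[i:i + 1]).data
                                  for i in range(4)])
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_patch_embedding_shapes(self, tiny_model):
        feat = Tensor(np.random.default_rng(2).random((3, 16, 16, 8),
                                                      dtype=np.float32))
        patches = tiny_model.embed.patchify(feat)
        assert patches.shape == (3, 16, 8 * 4 * 4)  # n=16 patches, c*ph*pw dims
        seq = tiny_model.embed(feat)
        assert seq.shape == (3, 17, 16)  # class token prepended

    def test_whole_map_as_single_patch_gives_length_two_sequence(self):
        model = ResTransNet(tiny_config(patch_grid=1))
        feat = Tensor(np.zeros((1, 16, 16, 8), dtype=np.float32))
        assert model.embed(feat).shape == (1, 2, 16)

    def test_default_patch_dimensions_match_feature_map(self):
        model = ResTransNet(ModelConfig(depth=1))
        feat = Tensor(np.zeros((1, 16, 16, 64), dtype=np.float32))
        patches = model.embed.patchify(feat)
        assert patches.shape == (1, 16, 64 * 4 * 4)

    def test_invalid_patch_grid_raises(self):
        with pytest.raises(ValueError):
            ModelConfig(patch_grid=5)


class TestPositionSensitivity:
    @staticmethod
    def _permute_feature_patches(feat, grid, perm, rng_shape=16):
        ph = feat.shape[1] // grid
        f = feat.reshape(feat.shape[0], grid, ph, grid, ph, feat.shape[-1])
        f = f.transpose(0, 1, 3, 2, 4, 5).reshape(feat.shape[0], grid * grid,
                                                  ph, ph, feat.shape[-1])
        f = f[:, perm]
        f = f.reshape(feat.shape[0], grid, grid, ph, ph, feat.shape[-1])
        return f.transpose(0, 1, 3, 2, 4, 5).reshape(feat.shape)

    def test_zero_position_embeddings_make_class_logits_permutation_invariant(self):
        model = ResTransNet(tiny_config(depth=2))
        model.embed.pos_embed.data = np.zeros_like(model.embed.pos_embed.data)
        model.eval()
        rng = np.random.default_rng(7)
        feat = rng.normal(size=(1, 16, 16, 8)).astype(np.float32)
        perm = rng.permutation(16)
        out_a = model.head_forward(model.transformer_forward(
            model.embed(Tensor(feat)))).data
        out_b = model.head_forward(model.transformer_forward(
            model.embed(Tensor(self._permute_feature_patches(feat, 4, perm))))).data
        np.testing.assert_allclose(out_a, out_b, atol=1e-5)

    def test_learned_position_embeddings_break_permutation_invariance(self):
        model = ResTransNet(tiny_config(depth=2, seed=3))
        model.eval()
        rng = np.random.default_rng(8)
        feat = rng.normal(size=(1, 16, 16, 8)).astype(np.float32)
        perm = np.roll(np.arange(16), 1)
        out_a = model.head_forward(model.transformer_forward(
            model.embed(Tensor(feat)))).data
        out_b = model.head_forward(model.transformer_forward(
            model.embed(Tensor(self._permute_feature_patches(feat, 4, perm))))).data
        assert np.abs(out_a - out_b).max() > 1e-6


class TestForward:
    def test_logits_length_two_and_softmax_normalised(self, tiny_model):
        x = np.random.default_rng(0).random((3, 1, 128, 128), dtype=np.float32)
        logits = tiny_model.forward(x)
        assert logits.shape == (3, 2)
        np.testing.assert_allclose(logits.softmax(axis=-1).data.sum(axis=1),
                                   1.0, atol=1e-6)

    def test_identical_images_get_identical_logits_in_eval(self, tiny_model):
        tiny_model.eval()
        x = np.random.default_rng(1).random((1, 1, 128, 128), dtype=np.float32)
        logits = tiny_model.forward(np.concatenate([x, x])).data
        np.testing.assert_allclose(logits[0], logits[1], atol=1e-6)

    def test_wrong_input_shape_raises(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((2, 1, 64, 64), dtype=np.float32))

    def test_checkpoint_round_trip_preserves_predictions(self, tiny_model,
                                                         small_cohort, tmp_path):
        x = np.stack([s.image.pixels for s in small_cohort[:3]])[:, None]
        path = str(tmp_path / "model.npz")
        save_checkpoint(tiny_model, path)
        clone = load_checkpoint(path)
        np.testing.assert_array_equal(tiny_model.predict_proba(x),
                                      clone.predict_proba(x))


class TestCeLoss:
    def test_perfect_prediction_is_zero(self):
        assert ce_loss(np.array([1.0]), np.array([1])).item() == pytest.approx(
            0.0, abs=1e-6)

    def test_half_probability_is_ln_two(self):
        assert ce_loss(np.array([0.5]), np.array([1])).item() == pytest.approx(
            np.log(2.0), abs=1e-9)

    def test_summed_batch_matches_hand_computation(self):
        loss = ce_loss(np.array([0.9, 0.2]), np.array([1, 0]), reduction="sum")
        assert loss.item() == pytest.approx(-(np.log(0.9) + np.log(0.8)), abs=1e-9)

    def test_mean_reduction_and_class_weights(self):
        base = ce_loss(np.array([0.9, 0.2]), np.array([1, 0])).item()
        assert base == pytest.approx(-(np.log(0.9) + np.log(0.8)) / 2, abs=1e-9)
        weighted = ce_loss(np.array([0.9, 0.2]), np.array([1, 0]),
                           class_weights=np.array([0.0, 2.0])).item()
        assert weighted == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_out_of_range_probabilities_are_clamped(self):
        loss = ce_loss(np.array([0.0]), np.array([1])).item()
        assert np.isfinite(loss) and loss > 10
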