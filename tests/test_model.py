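"""Attention mathematics, adapters, conditioning and the decoder stack."""

import numpy as np
import pytest

import targen as tg
from targen.nn.autograd import Tensor
from targen.nn.model import (AdapterParams, AttentionParams, adapter_forward,
                             multi_head_attention, scaled_dot_attention,
                             save_checkpoint, load_checkpoint)


def brute_force_attention(Q, K, V, mask=None):
    """Independent loop-based softmax(QKᵀ/√d_k)V."""
    T, d_k = Q.shape
    M = K.shape[0]
    out = np.zeros((T, V.shape[1]))
    for t in range(T):
        scores = np.array([Q[t] @ K[m] / np.sqrt(d_k) for m in range(M)])
        if mask is not None:
            scores = np.where(mask[t], -np.inf, scores)
        w = np.exp(scores - scores[np.isfinite(scores)].max())
        w = np.where(np.isfinite(scores), w, 0.0)
        w /= w.sum()
        out[t] = sum(w[m] * V[m] for m in range(M))
    return out


def brute_force_mha(Q, K, V, params: AttentionParams, mask=None):
    heads = [brute_force_attention(Q @ params.W_q.data[i],
                                   K @ params.W_k.data[i],
                                   V @ params.W_v.data[i], mask)
             for i in range(params.W_q.data.shape[0])]
    return np.concatenate(heads, axis=1) @ params.W_o.data


def random_attention_params(rng, h, d_model, d_k):
    return AttentionParams(
        W_q=Tensor(rng.normal(size=(h, d_model, d_k))),
        W_k=Tensor(rng.normal(size=(h, d_model, d_k))),
        W_v=Tensor(rng.normal(size=(h, d_model, d_k))),
        W_o=Tensor(rng.normal(size=(h * d_k, d_model))))


class TestScaledDotAttention:
    def test_single_slot_softmax_weight_is_one(self):
        out = scaled_dot_attention([[1.0]], [[1.0]], [[1.0]])
        assert np.allclose(out.data, [[1.0]])

    def test_identical_value_rows_dominate_any_query(self, rng):
        v = rng.normal(size=4)
        V = np.tile(v, (3, 1))
        out = scaled_dot_attention(rng.normal(size=(2, 5)),
                                   rng.normal(size=(3, 5)), V)
        assert np.allclose(out.data, np.tile(v, (2, 1)))

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle(self, rng, trial):
        T, M, d_k, d_v = rng.integers(1, 5, size=4)
        Q = rng.integers(-3, 4, size=(T, d_k)).astype(float)
        K = rng.integers(-3, 4, size=(M, d_k)).astype(float)
        V = rng.integers(-3, 4, size=(M, d_v)).astype(float)
        assert np.allclose(scaled_dot_attention(Q, K, V).data,
                           brute_force_attention(Q, K, V), atol=1e-6)

    def test_masked_rows_match_oracle_and_sum_to_one(self, rng):
        Q = rng.normal(size=(3, 2))
        K = rng.normal(size=(3, 2))
        V = rng.normal(size=(3, 2))
        mask = np.triu(np.ones((3, 3), dtype=bool), k=1)
        assert np.allclose(scaled_dot_attention(Q, K, V, mask).data,
                           brute_force_attention(Q, K, V, mask), atol=1e-6)

    def test_fully_masked_row_is_an_error(self, rng):
        mask = np.array([[True, True], [False, False]])
        with pytest.raises(ValueError, match="fully masked"):
            scaled_dot_attention(rng.normal(size=(2, 2)),
                                 rng.normal(size=(2, 2)),
                                 rng.normal(size=(2, 2)), mask)


class TestMultiHeadAttention:
    def test_single_identity_head_reduces_to_scaled_dot(self, rng):
        d = 3
        params = AttentionParams(W_q=Tensor(np.eye(d)[None]),
                                 W_k=Tensor(np.eye(d)[None]),
                                 W_v=Tensor(np.eye(d)[None]),
                                 W_o=Tensor(np.eye(d)))
        X = rng.normal(size=(4, d))
        assert np.allclose(multi_head_attention(X, X, X, params).data,
                           scaled_dot_attention(X, X, X).data, atol=1e-12)

    def test_zero_memory_yields_exactly_zero(self, rng):
        """K/V from the all-zeros vector → zero output: the mechanism that
        makes target id 0 contribute nothing through conditional attention."""
        params = random_attention_params(rng, h=2, d_model=6, d_k=3)
        Q = rng.normal(size=(5, 6))
        mem = np.zeros((1, 6))
        out = multi_head_attention(Q, mem, mem, params)
        assert np.all(out.data == 0.0)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_brute_force_two_heads(self, rng, trial):
        params = random_attention_params(rng, h=2, d_model=4, d_k=2)
        Q = rng.normal(size=(3, 4))
        K = rng.normal(size=(4, 4))
        V = rng.normal(size=(4, 4))
        assert np.allclose(multi_head_attention(Q, K, V, params).data,
                           brute_force_mha(Q, K, V, params), atol=1e-6)


class TestAdapter:
    def test_zero_up_projection_is_identity(self, rng):
        params = AdapterParams(W_down=Tensor(rng.normal(size=(4, 2))),
                               W_up=Tensor(np.zeros((2, 4))))
        x = rng.normal(size=(3, 4))
        assert np.array_equal(adapter_forward(x, params).data, x)

    def test_residual_definition(self, rng):
        params = AdapterParams(W_down=Tensor(rng.normal(size=(4, 2))),
                               W_up=Tensor(rng.normal(size=(2, 4))))
        x = rng.normal(size=(3, 4))
        delta = adapter_forward(x, params).data - x
        up_path = np.maximum(x @ params.W_down.data, 0) @ params.W_up.data
        assert np.allclose(delta, up_path, atol=1e-12)

    def test_hand_computed_identity_activation(self):
        params = AdapterParams(W_down=Tensor([[2.0], [1.0]]),
                               W_up=Tensor([[0.5, -1.0]]),
                               nonlinearity="identity")
        out = adapter_forward(np.array([[1.0, 3.0]]), params)
        # down: 1*2 + 3*1 = 5; up: (2.5, -5); residual: (3.5, -2)
        assert np.allclose(out.data, [[3.5, -2.0]])


@pytest.fixture
def small_model(vocab300):
    cfg = tg.ModelConfig(vocab_size=len(vocab300), d_model=16, n_heads=2,
                         n_blocks=3, adapter_dim=4, max_len=20, dropout=0.0)
    return tg.ConditionalDecoder(cfg, seed=5)


class TestDecoderBlock:
    def test_zero_conditioning_and_adapter_equal_stripped_block(self, small_model, rng):
        """With a zero target embedding and zero-init adapters, the block is
        exactly the block with both the conditional attention and the adapter
        removed."""
        small_model.add_adapters((1, 2), seed=0)
        x = Tensor(rng.normal(size=(2, 5, 16)))
        mem = Tensor(np.zeros((2, 1, 16)))
        causal = np.triu(np.ones((5, 5), dtype=bool), k=1)
        full = small_model.block_forward(1, x, mem, causal)
        stripped = small_model.block_forward(1, x, mem, causal,
                                             use_adapter=False,
                                             use_conditioning=False)
        assert np.array_equal(full.data, stripped.data)

    def test_causal_mask_blocks_future_positions(self, small_model, rng):
        x1 = rng.normal(size=(1, 6, 16))
        x2 = x1.copy()
        x2[0, 4:] += rng.normal(size=(2, 16))          # perturb the future
        mem = Tensor(rng.normal(size=(1, 1, 16)))
        causal = np.triu(np.ones((6, 6), dtype=bool), k=1)
        y1 = small_model.block_forward(0, Tensor(x1), mem, causal)
        y2 = small_model.block_forward(0, Tensor(x2), mem, causal)
        assert np.allclose(y1.data[0, :4], y2.data[0, :4], atol=1e-12)
        assert not np.allclose(y1.data[0, 4:], y2.data[0, 4:])


class TestModelForward:
    def test_logit_shape(self, small_model):
        logits = small_model.forward(np.array([[1, 3, 4, 2]]), 0)
        assert logits.shape == (1, 4, small_model.config.vocab_size)

    def test_causality_full_perturbation(self, small_model, rng):
        tokens = rng.integers(0, small_model.config.vocab_size, size=(3, 8))
        base = small_model.forward(tokens, 0).data
        for t in range(1, 8):
            perturbed = tokens.copy()
            perturbed[:, t] = (perturbed[:, t] + 1) % small_model.config.vocab_size
            out = small_model.forward(perturbed, 0).data
            assert np.allclose(out[:, :t], base[:, :t], atol=1e-12)

    def test_token_and_target_range_checks(self, small_model):
        with pytest.raises(ValueError, match="token index"):
            small_model.forward(np.array([[9999]]), 0)
        with pytest.raises(ValueError, match="target id"):
            small_model.forward(np.array([[1]]), 7)

    def test_zero_init_adapter_insertion_changes_no_logit(self, pretrained_tiny,
                                                          clone, rng):
        """Identity at insertion: fine-tuning starts from the pre-trained
        function exactly."""
        tokens = rng.integers(0, pretrained_tiny.config.vocab_size, size=(4, 10))
        before = pretrained_tiny.forward(tokens, 0).data
        twin = clone(pretrained_tiny)
        twin.add_adapters((1, 2), seed=9)
        after = twin.forward(tokens, 0).data
        assert np.max(np.abs(after - before)) < 1e-6

    def test_unconditional_equals_zero_target(self, pretrained_tiny, rng):
        tokens = rng.integers(0, pretrained_tiny.config.vocab_size, size=(2, 6))
        a = pretrained_tiny.forward(tokens, 0).data
        b = pretrained_tiny.forward(tokens, np.zeros(2, dtype=int)).data
        assert np.array_equal(a, b)


class TestParameterGroups:
    def test_partition_covers_every_parameter(self, small_model):
        groups = small_model.parameter_groups()
        names = [n for g in groups.values() for n in g]
        assert sorted(names) == sorted(small_model.params)

    def test_adapter_group_size_formula(self, small_model):
        small_model.add_adapters((1, 2), seed=0)
        groups = small_model.parameter_groups()
        c = small_model.config
        per_block = 2 * c.d_model * c.adapter_dim   # W_down + W_up, no biases
        total = sum(small_model.params[n].data.size
                    for b in (1, 2) for n in groups[f"block{b}.adapter"])
        assert total == 2 * per_block

    def test_group_census_matches_hand_count(self, vocab300):
        """Parameter count of a d_model=512, h=8, 3-block model against
        independent arithmetic."""
        V = len(vocab300)
        cfg = tg.ModelConfig(vocab_size=V)
        model = tg.ConditionalDecoder(cfg, seed=0)
        d, f, L = 512, 2048, 72
        attn = 4 * d * d + 2 * d          # q,k,v,o projections + ln gain/bias
        ffn = d * f + f + f * d + d + 2 * d
        expected = (V * d + L * d          # token + positional embeddings
                    + 4 * d                # target table (3 targets + null row)
                    + 3 * (2 * attn + ffn)
                    + 2 * d                # final layer norm
                    + d * V + V)           # output projection
        assert model.n_parameters() == expected


def test_checkpoint_round_trip_is_bit_exact(tmp_path, pretrained_tiny, clone):
    model = clone(pretrained_tiny)
    model.add_adapters((1, 2), seed=4)
    save_checkpoint(model, tmp_path / "m.npz", vocab_hash="abc")
    restored, meta = load_checkpoint(tmp_path / "m.npz", expect_vocab_hash="abc")
    assert meta["adapter_blocks"] == [1, 2]
    for name, p in model.params.items():
        assert np.array_equal(restored.params[name].data, p.data)
    with pytest.raises(ValueError, match="hash"):
        load_checkpoint(tmp_path / "m.npz", expect_vocab_hash="other")
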