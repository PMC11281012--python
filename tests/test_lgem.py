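"""LGEM: concatenation, compression MLP, attention, enhancement.

Oracle strategy: every composite operation is compared against an
independent step-by-step composition of its primitives — brute-force
nested loops for attention, one-primitive-at-a-time evaluation for the
MLP and the full forward pass.
"""

import numpy as np
import pytest

from rgbdet import nn
from rgbdet.lgem import (LGEM, LocalMLP, concat_modalities, enhance,
                         flatten_tokens, global_weight, lgem_forward,
                         lgem_forward_tri, local_mlp, self_attention,
                         upsample_tokens)
from rgbdet.nn import Tensor


def brute_force_attention(q, k, v):
    """Two-nested-loop softmax/weighted-sum reference."""
    b, _, c, n = q.shape
    out = np.zeros_like(q)
    for bi in range(b):
        Q = q[bi, 0].T  # (n, c)
        K = k[bi, 0].T
        V = v[bi, 0].T
        for i in range(n):
            logits = np.array([Q[i] @ K[j] / np.sqrt(c) for j in range(n)])
            weights = np.exp(logits - logits.max())
            weights /= weights.sum()
            out[bi, 0, :, i] = sum(weights[j] * V[j] for j in range(n))
    return out


class TestConcat:
    def test_shape_and_ordering(self):
        rng = np.random.default_rng(0)
        rgb = rng.normal(size=(1, 2, 4, 4))
        depth = rng.normal(size=(1, 2, 4, 4))
        out = concat_modalities(rgb, depth)
        assert out.shape == (1, 4, 4, 4)
        np.testing.assert_array_equal(out[:, :2], rgb)
        np.testing.assert_array_equal(out[:, 2:], depth)

    def test_self_concat_halves_equal(self):
        x = np.random.default_rng(1).normal(size=(2, 3, 2, 2))
        out = concat_modalities(x, x)
        np.testing.assert_array_equal(out[:, :3], out[:, 3:])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            concat_modalities(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 4, 5)))

    def test_tri_modal_blocks(self):
        x = np.random.default_rng(2).normal(size=(1, 2, 3, 3))
        out = concat_modalities(x, x, x)
        assert out.shape == (1, 6, 3, 3)
        np.testing.assert_array_equal(out[:, 2:4], x)


class TestLocalMLP:
    def test_output_single_channel(self):
        mlp = LocalMLP(4, 1, 1, rng=np.random.default_rng(0))
        out = local_mlp(mlp, np.random.default_rng(1).normal(size=(1, 4, 4, 4)))
        assert out.shape == (1, 1, 4, 4)

    def test_zero_weights_give_zero_map(self):
        mlp = LocalMLP(4, 1, 1, rng=np.random.default_rng(0))
        for _, p in mlp.named_parameters():
            p.data = np.zeros_like(p.data)
        out = local_mlp(mlp, np.random.default_rng(1).normal(size=(2, 4, 5, 5)))
        # LN(0) is 0 (affine shift is zero), residual conv of zeros is 0
        np.testing.assert_array_equal(out, np.zeros((2, 1, 5, 5)))

    def test_odd_channel_count_rejected(self):
        mlp = LocalMLP(4, 1, 1, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="even"):
            local_mlp(mlp, np.zeros((1, 3, 4, 4)))

    def test_matches_primitive_composition(self):
        """Random input/weights equal conv -> conv -> relu -> conv -> LN
        plus the residual conv, each applied independently."""
        rng = np.random.default_rng(3)
        mlp = LocalMLP(6, 1, 1, rng=rng)
        x = rng.normal(size=(2, 6, 4, 4))
        got = local_mlp(mlp, x)
        h = mlp.conv1(Tensor(x)).data
        h = mlp.conv2(Tensor(h)).data
        h = np.maximum(h, 0)
        h = mlp.conv3(Tensor(h)).data
        mu = h.mean(axis=(1, 2, 3), keepdims=True)
        var = h.var(axis=(1, 2, 3), keepdims=True)
        ln = (h - mu) / np.sqrt(var + 1e-5) * mlp.norm.gamma.data + mlp.norm.beta.data
        expected = ln + mlp.residual(Tensor(x)).data
        np.testing.assert_allclose(got, expected, atol=1e-6)


class TestTokens:
    def test_flatten_length(self):
        t = flatten_tokens(np.arange(6.0).reshape(1, 1, 2, 3))
        assert t.shape == (1, 1, 1, 6)

    def test_round_trip_bit_exact(self):
        x = np.random.default_rng(0).normal(size=(2, 3, 4, 5))
        np.testing.assert_array_equal(upsample_tokens(flatten_tokens(x), 4, 5), x)

    def test_element_multiset_preserved(self):
        x = np.random.default_rng(1).normal(size=(1, 2, 3, 3))
        np.testing.assert_array_equal(np.sort(flatten_tokens(x), axis=None),
                                      np.sort(x, axis=None))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="h\\*w"):
            upsample_tokens(np.zeros((1, 1, 2, 6)), 2, 2)


class TestSelfAttention:
    def test_single_token_returns_value(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(2, 1, 3, 1))
        v = rng.normal(size=(2, 1, 3, 1))
        np.testing.assert_allclose(self_attention(q, q, v), v, atol=1e-12)

    def test_rows_sum_to_one(self):
        # verified through a uniform-value probe: with v == 1 the output
        # is the attention row sums
        rng = np.random.default_rng(1)
        q = rng.normal(size=(1, 1, 2, 5))
        k = rng.normal(size=(1, 1, 2, 5))
        ones = np.ones_like(q)
        np.testing.assert_allclose(self_attention(q, k, ones), ones, atol=1e-6)

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(2)
        q = rng.normal(size=(2, 1, 2, 2))
        k = rng.normal(size=(2, 1, 2, 2))
        v = rng.normal(size=(2, 1, 2, 2))
        np.testing.assert_allclose(self_attention(q, k, v),
                                   brute_force_attention(q, k, v), atol=1e-6)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            self_attention(np.zeros((1, 1, 2, 3)), np.zeros((1, 1, 2, 4)),
                           np.zeros((1, 1, 2, 4)))


class TestGlobalWeight:
    def test_identity_convolution(self):
        attn = np.random.default_rng(0).normal(size=(1, 1, 1, 12))
        out = global_weight(attn, 3, 4)
        np.testing.assert_array_equal(out, attn.reshape(1, 1, 3, 4))

    def test_random_weight_matches_reshape_then_scale(self):
        rng = np.random.default_rng(1)
        attn = rng.normal(size=(2, 1, 1, 6))
        w, b = 1.7, -0.3
        out = global_weight(attn, 2, 3, weight=w, bias=b)
        np.testing.assert_allclose(out, attn.reshape(2, 1, 2, 3) * w + b, atol=1e-12)

    def test_shape_is_b1hw(self):
        out = global_weight(np.zeros((3, 1, 1, 8)), 2, 4)
        assert out.shape == (3, 1, 2, 4)


class TestEnhance:
    def test_ones_is_identity(self):
        rng = np.random.default_rng(0)
        rgb, depth = rng.normal(size=(1, 3, 4, 4)), rng.normal(size=(1, 3, 4, 4))
        r, d = enhance(rgb, depth, np.ones((1, 1, 4, 4)))
        np.testing.assert_array_equal(r, rgb)
        np.testing.assert_array_equal(d, depth)

    def test_zeros_zeroes_everything(self):
        rgb = np.random.default_rng(1).normal(size=(1, 2, 3, 3))
        r, d = enhance(rgb, rgb, np.zeros((1, 1, 3, 3)))
        assert not r.any() and not d.any()

    def test_homogeneity_in_the_weight_map(self):
        rng = np.random.default_rng(2)
        rgb, depth = rng.normal(size=(1, 2, 3, 3)), rng.normal(size=(1, 2, 3, 3))
        e = rng.normal(size=(1, 1, 3, 3))
        r1, d1 = enhance(rgb, depth, e)
        r2, d2 = enhance(rgb, depth, 2.5 * e)
        np.testing.assert_allclose(r2, 2.5 * r1)
        np.testing.assert_allclose(d2, 2.5 * d1)

    def test_spatial_mismatch_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            enhance(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 4, 4)),
                    np.zeros((1, 1, 2, 2)))


def chained_lgem_oracle(block: LGEM, streams):
    """Recompute the forward pass from the five functional primitives."""
    local = concat_modalities(*streams)
    elocal = block.mlp(Tensor(local)).data
    assert elocal.shape[1] == 1
    tok = flatten_tokens(elocal)
    attn = self_attention(tok, tok, tok)
    h, w = streams[0].shape[2:]
    eglobal = global_weight(attn, h, w,
                            weight=block.refine.weight.data,
                            bias=float(block.refine.bias.data[0]))
    return tuple(s * eglobal for s in streams)


class TestLGEMForward:
    def test_shape_contract_and_determinism(self):
        rng = np.random.default_rng(0)
        block = LGEM(8, rng=np.random.default_rng(1))
        rgb, depth = rng.normal(size=(2, 8, 16, 16)), rng.normal(size=(2, 8, 16, 16))
        r1, d1 = lgem_forward(block, rgb, depth)
        r2, d2 = lgem_forward(block, rgb, depth)
        assert r1.shape == rgb.shape and d1.shape == depth.shape
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(d1, d2)

    def test_matches_chained_oracle(self):
        rng = np.random.default_rng(2)
        block = LGEM(4, rng=np.random.default_rng(3))
        rgb, depth = rng.normal(size=(1, 4, 3, 4)), rng.normal(size=(1, 4, 3, 4))
        got = lgem_forward(block, rgb, depth)
        want = chained_lgem_oracle(block, (rgb, depth))
        for g, w in zip(got, want):
            np.testing.assert_allclose(g, w, atol=1e-6)

    def test_odd_channels_rejected_at_construction(self):
        with pytest.raises(ValueError, match="even"):
            LGEM(3)

    def test_tri_modal_matches_oracle_and_shares_weight_map(self):
        rng = np.random.default_rng(4)
        block = LGEM(4, n_streams=3, rng=np.random.default_rng(5))
        x = rng.normal(size=(1, 4, 3, 3))
        y = rng.normal(size=(1, 4, 3, 3))
        z = rng.normal(size=(1, 4, 3, 3))
        got = lgem_forward_tri(block, x, y, z)
        want = chained_lgem_oracle(block, (x, y, z))
        for g, w in zip(got, want):
            np.testing.assert_allclose(g, w, atol=1e-6)
        # shared weight map: elementwise ratios to the inputs agree
        with np.errstate(divide="ignore", invalid="ignore"):
            np.testing.assert_allclose(got[0] / x, got[2] / z, atol=1e-6)

    def test_stream_count_enforced(self):
        block = LGEM(4, n_streams=2, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="streams"):
            block(Tensor(np.zeros((1, 4, 2, 2))), Tensor(np.zeros((1, 4, 2, 2))),
                  Tensor(np.zeros((1, 4, 2, 2))))
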