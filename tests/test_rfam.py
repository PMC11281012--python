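"""RFAM: cross-attention, coarse fusion, directional pooling, fine fusion."""

import numpy as np
import pytest

from rgbdet.lgem import LocalMLP as BottleneckMLP
from rgbdet.lgem import flatten_tokens
from rgbdet.nn import Tensor
from rgbdet.rfam import (RFAM, TriRFAM, coarse_fuse, cross_attention,
                         directional_pool, fine_fuse, mix_vectors,
                         rfam_forward, rfam_forward_tri, split_vectors)
from tests.test_lgem import brute_force_attention


class TestCrossAttention:
    def test_identical_inputs_give_identical_outputs(self):
        x = np.random.default_rng(0).normal(size=(2, 4, 3, 3))
        a1, a2 = cross_attention(x, x)
        np.testing.assert_array_equal(a1, a2)

    def test_single_position_returns_other_value(self):
        rng = np.random.default_rng(1)
        rgb = rng.normal(size=(1, 3, 1, 1))
        depth = rng.normal(size=(1, 3, 1, 1))
        a1, a2 = cross_attention(rgb, depth)
        np.testing.assert_allclose(a1, flatten_tokens(depth), atol=1e-12)
        np.testing.assert_allclose(a2, flatten_tokens(rgb), atol=1e-12)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(2)
        rgb = rng.normal(size=(1, 2, 1, 3))  # 3 tokens
        depth = rng.normal(size=(1, 2, 1, 3))
        a1, a2 = cross_attention(rgb, depth)
        q1, q2 = flatten_tokens(rgb), flatten_tokens(depth)
        np.testing.assert_allclose(a1, brute_force_attention(q1, q2, q2), atol=1e-6)
        np.testing.assert_allclose(a2, brute_force_attention(q2, q1, q1), atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_attention(np.zeros((1, 2, 3, 3)), np.zeros((1, 2, 3, 4)))


class TestCoarseFuse:
    def test_restores_grid_shape(self):
        mlp = BottleneckMLP(4, 2, 4, rng=np.random.default_rng(0))
        attn = np.random.default_rng(1).normal(size=(2, 1, 4, 12))
        assert coarse_fuse(mlp, attn, 3, 4).shape == (2, 4, 3, 4)

    def test_zero_weights_zero_output(self):
        mlp = BottleneckMLP(4, 2, 4, rng=np.random.default_rng(0))
        for _, p in mlp.named_parameters():
            p.data = np.zeros_like(p.data)
        out = coarse_fuse(mlp, np.random.default_rng(1).normal(size=(1, 1, 4, 6)), 2, 3)
        np.testing.assert_array_equal(out, np.zeros((1, 4, 2, 3)))

    def test_matches_primitive_composition(self):
        rng = np.random.default_rng(2)
        mlp = BottleneckMLP(4, 2, 4, rng=rng)
        attn = rng.normal(size=(1, 1, 4, 6))
        got = coarse_fuse(mlp, attn, 2, 3)
        col = Tensor(attn.reshape(1, 4, 6, 1))
        want = mlp(col).data.reshape(1, 4, 2, 3)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_odd_channels_rejected(self):
        mlp = BottleneckMLP(4, 2, 4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="even"):
            coarse_fuse(mlp, np.zeros((1, 1, 3, 4)), 2, 2)


class TestDirectionalPool:
    def test_constant_grid(self):
        w, h = directional_pool(np.full((1, 2, 3, 4), 5.0))
        np.testing.assert_array_equal(w, np.full((1, 2, 4, 1), 5.0))
        np.testing.assert_array_equal(h, np.full((1, 2, 1, 3), 5.0))

    def test_profile_shapes(self):
        pw, ph = directional_pool(np.zeros((2, 3, 5, 7)))
        assert pw.shape == (2, 3, 7, 1)
        assert ph.shape == (2, 3, 1, 5)

    def test_matches_explicit_max_loops(self):
        g = np.random.default_rng(0).normal(size=(2, 3, 4, 5))
        pw, ph = directional_pool(g)
        for b in range(2):
            for c in range(3):
                for x in range(5):
                    assert pw[b, c, x, 0] == max(g[b, c, y, x] for y in range(4))
                for y in range(4):
                    assert ph[b, c, 0, y] == max(g[b, c, y, x] for x in range(5))


class TestMixSplit:
    def _profiles(self, b=1, c=2, w=4, h=3, seed=0):
        rng = np.random.default_rng(seed)
        return (rng.normal(size=(b, c, w, 1)), rng.normal(size=(b, c, w, 1)),
                rng.normal(size=(b, c, 1, h)), rng.normal(size=(b, c, 1, h)))

    def test_mixed_length_and_ordering(self):
        rgbw, depthw, rgbh, depthh = self._profiles()
        mixed = mix_vectors(rgbw, depthw, rgbh, depthh)
        assert mixed.shape == (1, 2, 14, 1)  # 2*4 + 2*3
        np.testing.assert_array_equal(mixed[:, :, :4], rgbw)

    def test_identity_mlp_round_trip_bit_exact(self):
        profiles = self._profiles(seed=1)
        mixed = mix_vectors(*profiles)
        back = split_vectors(mixed, 4, 3, mlp=None)
        for orig, rec in zip(profiles, back):
            np.testing.assert_array_equal(orig, rec)

    def test_split_with_mlp_matches_mlp_then_slice(self):
        rng = np.random.default_rng(2)
        mlp = BottleneckMLP(2, 1, 2, rng=rng)
        mixed = mix_vectors(*self._profiles(seed=3))
        got = split_vectors(mixed, 4, 3, mlp=mlp)
        y = mlp(Tensor(mixed)).data
        np.testing.assert_allclose(got[0], y[:, :, :4], atol=1e-6)
        np.testing.assert_allclose(got[2], y[:, :, 8:11].transpose(0, 1, 3, 2), atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="2w\\+2h"):
            split_vectors(np.zeros((1, 2, 10, 1)), 4, 4)

    def test_batch_channel_mismatch_rejected(self):
        rgbw, depthw, rgbh, depthh = self._profiles()
        with pytest.raises(ValueError, match="mismatch"):
            mix_vectors(rgbw, depthw, np.zeros((1, 3, 1, 3)), np.zeros((1, 3, 1, 3)))


class TestFineFuse:
    def _grids(self, seed=0, b=1, c=2, h=3, w=4):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(b, c, h, w)), rng.normal(size=(b, c, h, w))

    def test_unit_profiles_sum_streams(self):
        rgbR, depthR = self._grids()
        ones_w, ones_h = np.ones((1, 2, 4, 1)), np.ones((1, 2, 1, 3))
        out = fine_fuse(rgbR, depthR, ones_w, ones_h, ones_w, ones_h)
        np.testing.assert_array_equal(out, rgbR + depthR)

    def test_zero_depth_profiles_leave_rgb_stream(self):
        rgbR, depthR = self._grids(seed=1)
        rng = np.random.default_rng(2)
        rgbw, rgbh = rng.normal(size=(1, 2, 4, 1)), rng.normal(size=(1, 2, 1, 3))
        zw, zh = np.zeros((1, 2, 4, 1)), np.zeros((1, 2, 1, 3))
        out = fine_fuse(rgbR, depthR, rgbw, rgbh, zw, zh)
        only_rgb = fine_fuse(rgbR, np.zeros_like(depthR), rgbw, rgbh, zw, zh)
        np.testing.assert_array_equal(out, only_rgb)

    def test_matches_triple_loop_oracle(self):
        rgbR, depthR = self._grids(seed=3)
        rng = np.random.default_rng(4)
        rgbw, depthw = rng.normal(size=(1, 2, 4, 1)), rng.normal(size=(1, 2, 4, 1))
        rgbh, depthh = rng.normal(size=(1, 2, 1, 3)), rng.normal(size=(1, 2, 1, 3))
        got = fine_fuse(rgbR, depthR, rgbw, rgbh, depthw, depthh)
        want = np.zeros_like(rgbR)
        for c in range(2):
            for i in range(3):
                for j in range(4):
                    want[0, c, i, j] = (
                        rgbR[0, c, i, j] * rgbw[0, c, j, 0] * rgbh[0, c, 0, i]
                        + depthR[0, c, i, j] * depthw[0, c, j, 0] * depthh[0, c, 0, i]
                    )
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_bilinear_in_each_profile(self):
        rgbR, depthR = self._grids(seed=5)
        rng = np.random.default_rng(6)
        rgbw, depthw = rng.normal(size=(1, 2, 4, 1)), rng.normal(size=(1, 2, 4, 1))
        rgbh, depthh = rng.normal(size=(1, 2, 1, 3)), rng.normal(size=(1, 2, 1, 3))
        base_rgb = fine_fuse(rgbR, np.zeros_like(depthR), rgbw, rgbh, depthw, depthh)
        scaled = fine_fuse(rgbR, np.zeros_like(depthR), 3.0 * rgbw, rgbh, depthw, depthh)
        np.testing.assert_allclose(scaled, 3.0 * base_rgb)

    def test_profile_shape_rejected(self):
        rgbR, depthR = self._grids(seed=7)
        with pytest.raises(ValueError, match="shape"):
            fine_fuse(rgbR, depthR, np.zeros((1, 2, 3, 1)), np.zeros((1, 2, 1, 3)),
                      np.zeros((1, 2, 4, 1)), np.zeros((1, 2, 1, 3)))


def chained_rfam_oracle(block: RFAM, rgb, depth):
    """Recompute the full pass from the functional primitives."""
    h, w = rgb.shape[2:]
    a1, a2 = cross_attention(rgb, depth)
    rgbR = coarse_fuse(block.mlp_rgb, a1, h, w)
    depthR = coarse_fuse(block.mlp_depth, a2, h, w)
    rgbw, rgbh = directional_pool(rgbR)
    depthw, depthh = directional_pool(depthR)
    mixed = mix_vectors(rgbw, depthw, rgbh, depthh)
    rgbw, depthw, rgbh, depthh = split_vectors(mixed, w, h, mlp=block.mlp_mixed)
    return fine_fuse(rgbR, depthR, rgbw, rgbh, depthw, depthh,
                     bounded=block.bounded)


class TestRFAMForward:
    def test_shape_contract_and_determinism(self):
        rng = np.random.default_rng(0)
        block = RFAM(8, rng=np.random.default_rng(1))
        rgb, depth = rng.normal(size=(2, 8, 16, 16)), rng.normal(size=(2, 8, 16, 16))
        f1 = rfam_forward(block, rgb, depth)
        f2 = rfam_forward(block, rgb, depth)
        assert f1.shape == rgb.shape
        np.testing.assert_array_equal(f1, f2)

    @pytest.mark.parametrize("bounded", [False, True])
    def test_matches_chained_oracle(self, bounded):
        rng = np.random.default_rng(2)
        block = RFAM(4, bounded=bounded, rng=np.random.default_rng(3))
        rgb, depth = rng.normal(size=(1, 4, 3, 4)), rng.normal(size=(1, 4, 3, 4))
        np.testing.assert_allclose(rfam_forward(block, rgb, depth),
                                   chained_rfam_oracle(block, rgb, depth), atol=1e-6)

    def test_shape_mismatch_rejected(self):
        block = RFAM(4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="mismatch"):
            rfam_forward(block, np.zeros((1, 4, 2, 2)), np.zeros((1, 4, 2, 3)))


class TestTriRFAM:
    def test_shape_and_two_level_oracle(self):
        rng = np.random.default_rng(0)
        block = TriRFAM(4, rng=np.random.default_rng(1))
        x, y, z = (rng.normal(size=(1, 4, 3, 3)) for _ in range(3))
        got = rfam_forward_tri(block, x, y, z)
        assert got.shape == x.shape
        inner1 = rfam_forward(block.inner_xy, x, y)
        inner2 = rfam_forward(block.inner_xz, x, z)
        np.testing.assert_allclose(got, rfam_forward(block.outer, inner1, inner2),
                                   atol=1e-6)

    def test_weight_tied_substitution(self):
        """With all three instances weight-tied and z == y, the result is
        outer(g, g) with g the shared pair fusion."""
        rng = np.random.default_rng(2)
        block = TriRFAM(4, rng=np.random.default_rng(3))
        shared_state = block.inner_xy.state_dict()
        block.inner_xz.load_state_dict(shared_state)
        block.outer.load_state_dict(shared_state)
        x, y = rng.normal(size=(1, 4, 2, 3)), rng.normal(size=(1, 4, 2, 3))
        g = rfam_forward(block.inner_xy, x, y)
        np.testing.assert_allclose(rfam_forward_tri(block, x, y, y),
                                   rfam_forward(block.inner_xy, g, g), atol=1e-10)
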