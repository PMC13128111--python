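"""SDI skip fusion and CBAM attention.

The central oracle re-computes CBAM with explicit scalar loops (no vector
ops) from the module's own weights and must agree to 1e-6 on small inputs.
"""

import numpy as np
import pytest
from scipy.special import expit

from hybridseg import nn
from hybridseg.sdi import (CBAM, ChannelAttention, SDIFusion, SDIReduce,
                           SpatialAttention, concat_level, sdi_resize)


class TestConcat:
    def test_channels_add_cnn_first(self, rng):
        a = nn.Tensor(rng.normal(size=(2, 64, 8, 8)).astype(np.float32))
        b = nn.Tensor(rng.normal(size=(2, 64, 8, 8)).astype(np.float32))
        cat = concat_level(a, b, 1)
        assert cat.shape == (2, 128, 8, 8)
        np.testing.assert_array_equal(cat.data[:, :64], a.data)
        np.testing.assert_array_equal(cat.data[:, 64:], b.data)

    def test_spatial_mismatch_rejected(self, rng):
        a = nn.Tensor(np.zeros((1, 4, 8, 8), np.float32))
        b = nn.Tensor(np.zeros((1, 4, 4, 4), np.float32))
        with pytest.raises(ValueError, match="mismatch"):
            concat_level(a, b, 2)


class TestChannelAttention:
    def test_zero_mlp_gives_half_everywhere(self):
        nn.seed_all(0)
        ca = ChannelAttention(8, reduction=2)
        ca.fc1.weight.data[...] = 0.0
        ca.fc2.weight.data[...] = 0.0
        x = nn.Tensor(np.random.default_rng(0).normal(
            size=(2, 8, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(ca(x).data, 0.5, atol=1e-7)

    def test_identity_mlp_hand_computed_gate(self):
        """Single channel with values {1,2,3,4}: avg 2.5, max 4 -> sigma(6.5)."""
        nn.seed_all(0)
        ca = ChannelAttention(1, reduction=1)
        ca.fc1.weight.data[...] = 1.0
        ca.fc2.weight.data[...] = 1.0
        x = nn.Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32))
        gate = ca(x).data
        assert gate.shape == (1, 1, 1, 1)
        np.testing.assert_allclose(gate[0, 0, 0, 0], expit(2.5 + 4.0),
                                   rtol=1e-6)

    def test_constant_map_pools_agree(self, rng):
        nn.seed_all(1)
        ca = ChannelAttention(4, reduction=2)
        v = rng.normal(size=4).astype(np.float32)
        x = nn.Tensor(np.tile(v[None, :, None, None], (1, 1, 5, 5)))
        # avg == max for spatially constant input, so gate = sigma(2*MLP(v))
        hidden = np.maximum(v @ ca.fc1.weight.data.T, 0.0)
        expected = expit(2.0 * (hidden @ ca.fc2.weight.data.T))
        np.testing.assert_allclose(ca(x).data[0, :, 0, 0], expected, atol=1e-6)

    def test_gate_strictly_inside_unit_interval(self, rng):
        nn.seed_all(2)
        ca = ChannelAttention(16)
        x = nn.Tensor(rng.normal(size=(2, 16, 4, 4)).astype(np.float32))
        g = ca(x).data
        assert (g > 0).all() and (g < 1).all()


class TestSpatialAttention:
    def test_zero_conv_gives_half(self):
        nn.seed_all(3)
        sa = SpatialAttention()
        sa.conv.weight.data[...] = 0.0
        sa.conv.bias.data[...] = 0.0
        x = nn.Tensor(np.random.default_rng(0).normal(
            size=(1, 4, 6, 6)).astype(np.float32))
        np.testing.assert_allclose(sa(x).data, 0.5, atol=1e-7)

    def test_spatial_size_preserved(self, rng):
        nn.seed_all(4)
        sa = SpatialAttention()
        x = nn.Tensor(rng.normal(size=(2, 3, 9, 11)).astype(np.float32))
        assert sa(x).shape == (2, 1, 9, 11)

    def test_channel_constant_input_mean_equals_max(self, rng):
        plane = rng.normal(size=(5, 5)).astype(np.float32)
        x = np.tile(plane[None, None], (1, 4, 1, 1))
        t = nn.Tensor(x)
        mean = nn.tmean(t, axis=1, keepdims=True).data
        mx = nn.tmax(t, axis=1, keepdims=True).data
        np.testing.assert_allclose(mean, mx, atol=1e-7)


def _cbam_oracle(x, cb: CBAM):
    """Scalar-loop recomputation of the channel+spatial gating."""
    b, c, h, w = x.shape
    w1 = cb.channel.fc1.weight.data
    w2 = cb.channel.fc2.weight.data
    conv_w = cb.spatial.conv.weight.data
    conv_b = cb.spatial.conv.bias.data
    out = np.zeros_like(x)
    for bi in range(b):
        # channel attention
        gate_c = np.zeros(c)
        avg = [np.mean([x[bi, ci, i, j] for i in range(h) for j in range(w)])
               for ci in range(c)]
        mx = [max(x[bi, ci, i, j] for i in range(h) for j in range(w))
              for ci in range(c)]

        def mlp(v):
            hid = [max(0.0, sum(w1[r, ci] * v[ci] for ci in range(c)))
                   for r in range(w1.shape[0])]
            return [sum(w2[o, r] * hid[r] for r in range(w1.shape[0]))
                    for o in range(c)]

        ma, mm = mlp(avg), mlp(mx)
        for ci in range(c):
            gate_c[ci] = 1.0 / (1.0 + np.exp(-(ma[ci] + mm[ci])))
        fprime = np.zeros((c, h, w))
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    fprime[ci, i, j] = x[bi, ci, i, j] * gate_c[ci]
        # spatial attention on the gated map
        for i in range(h):
            for j in range(w):
                acc = conv_b[0]
                for di in range(-3, 4):
                    for dj in range(-3, 4):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < h and 0 <= jj < w:
                            mean_v = np.mean([fprime[ci, ii, jj]
                                              for ci in range(c)])
                            max_v = max(fprime[ci, ii, jj] for ci in range(c))
                            acc += conv_w[0, 0, di + 3, dj + 3] * mean_v
                            acc += conv_w[0, 1, di + 3, dj + 3] * max_v
                gate_s = 1.0 / (1.0 + np.exp(-acc))
                for ci in range(c):
                    out[bi, ci, i, j] = fprime[ci, i, j] * gate_s
    return out


class TestCBAM:
    def test_matches_scalar_loop_oracle(self, rng):
        nn.seed_all(5)
        cb = CBAM(4, reduction=2)
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        with nn.no_grad():
            got = cb(nn.Tensor(x)).data
        np.testing.assert_allclose(got, _cbam_oracle(x, cb), atol=1e-6)

    def test_unit_gates_leave_input_unchanged(self, rng):
        nn.seed_all(6)
        cb = CBAM(4, reduction=2)

        class _Ones(nn.Module):
            def forward(self, x):
                return nn.Tensor(np.float32(1.0))

        cb.channel = _Ones()
        cb.spatial = _Ones()
        x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        with nn.no_grad():
            np.testing.assert_array_equal(cb(nn.Tensor(x)).data, x)

    def test_zero_input_maps_to_zero(self):
        nn.seed_all(7)
        cb = CBAM(3)
        x = nn.Tensor(np.zeros((1, 3, 4, 4), np.float32))
        with nn.no_grad():
            np.testing.assert_array_equal(cb(x).data, 0.0)


class TestReduce:
    def test_channel_reduction_shape(self, rng):
        nn.seed_all(8)
        red = SDIReduce(512, 64, use_cbam=True, reduction=16).eval()
        x = nn.Tensor(rng.normal(size=(1, 512, 14, 14)).astype(np.float32))
        with nn.no_grad():
            assert red(x).shape == (1, 64, 14, 14)

    def test_avt_width_96(self, rng):
        nn.seed_all(9)
        red = SDIReduce(128, 96, use_cbam=True, reduction=16).eval()
        x = nn.Tensor(rng.normal(size=(1, 128, 8, 8)).astype(np.float32))
        with nn.no_grad():
            assert red(x).shape == (1, 96, 8, 8)

    def test_cbam_off_is_bare_conv_bn(self, rng):
        nn.seed_all(10)
        red = SDIReduce(32, 16, use_cbam=False, reduction=16).eval()
        x = nn.Tensor(rng.normal(size=(1, 32, 6, 6)).astype(np.float32))
        with nn.no_grad():
            got = red(x).data
            ref = red.bn(red.conv(x)).data
        np.testing.assert_array_equal(got, ref)


class TestResize:
    def test_identity_branch_is_bit_identical(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        assert sdi_resize(x, (8, 8)) is x

    def test_constants_preserved_both_directions(self):
        x = nn.Tensor(np.full((1, 2, 8, 8), 3.25, np.float32))
        np.testing.assert_allclose(sdi_resize(x, (4, 4)).data, 3.25, atol=1e-6)
        np.testing.assert_allclose(sdi_resize(x, (16, 16)).data, 3.25,
                                   atol=1e-6)

    def test_quadrant_pooling_hand_computed(self):
        q = np.zeros((1, 1, 4, 4), np.float32)
        q[0, 0, :2, :2] = 1.0
        q[0, 0, :2, 2:] = 2.0
        q[0, 0, 2:, :2] = 3.0
        q[0, 0, 2:, 2:] = 4.0
        out = sdi_resize(nn.Tensor(q), (2, 2)).data
        np.testing.assert_allclose(out[0, 0], [[1.0, 2.0], [3.0, 4.0]],
                                   atol=1e-7)


class TestFusion:
    def _pyramid(self, rng, c=8):
        return [nn.Tensor(rng.normal(size=(1, 4 * c, 2 ** (4 - j),
                                           2 ** (4 - j))).astype(np.float32))
                for j in range(3)]

    def test_shape_contract(self, rng):
        nn.seed_all(11)
        fusion = SDIFusion((32, 32, 32), c=8).eval()
        with nn.no_grad():
            pyr = fusion(self._pyramid(rng))
        assert pyr.channels == (8, 8, 8)
        assert [l.shape[2] for l in pyr.levels] == [16, 8, 4]
        assert pyr.source == "fused"

    def test_dirac_smoothers_give_plain_product(self, rng):
        nn.seed_all(12)
        fusion = SDIFusion((32, 32, 32), c=8, use_cbam=False).eval()
        for i in range(3):
            for j in range(3):
                conv = getattr(fusion, f"smooth{i + 1}{j + 1}")
                conv.weight.data[...] = 0.0
                for ch in range(8):
                    conv.weight.data[ch, ch, 1, 1] = 1.0
                conv.bias.data[...] = 0.0
        levels = self._pyramid(rng)
        with nn.no_grad():
            pyr = fusion(levels)
            reduced = [getattr(fusion, f"reduce{j + 1}")(levels[j])
                       for j in range(3)]
            for i in range(3):
                hw = (reduced[i].shape[2], reduced[i].shape[3])
                expected = np.ones_like(reduced[i].data)
                for j in range(3):
                    expected = expected * sdi_resize(reduced[j], hw).data
                np.testing.assert_allclose(pyr.levels[i].data, expected,
                                           rtol=1e-4, atol=1e-5)

    def test_zero_factor_annihilates(self, rng):
        nn.seed_all(13)
        fusion = SDIFusion((16, 16, 16), c=4, use_cbam=False).eval()
        # a smoothing conv that is identically zero at one source level
        fusion.smooth21.weight.data[...] = 0.0
        fusion.smooth21.bias.data[...] = 0.0
        levels = [nn.Tensor(rng.normal(size=(1, 16, 2 ** (4 - j),
                                             2 ** (4 - j))).astype(np.float32))
                  for j in range(3)]
        with nn.no_grad():
            pyr = fusion(levels)
        np.testing.assert_array_equal(pyr.levels[1].data, 0.0)

    def test_product_is_order_invariant(self, rng):
        maps = [rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
                for _ in range(3)]
        fwd = maps[0] * maps[1] * maps[2]
        perm = maps[2] * maps[0] * maps[1]
        np.testing.assert_allclose(fwd, perm, rtol=1e-6)

    def test_missing_level_rejected(self, rng):
        nn.seed_all(14)
        fusion = SDIFusion((16, 16, 16), c=4)
        with pytest.raises(ValueError, match="3"):
            fusion(self._pyramid(rng, c=4)[:2])
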