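"""Core-block semantics against brute-force and closed-form oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import correlate2d

from wetbird import nn
from wetbird.nn import Tensor
from wetbird import blocks as B


# ---------------------------------------------------------------------------
# Receptive-field expansion
# ---------------------------------------------------------------------------

class TestReceptiveFieldExpansion:
    def test_constant_input_with_padding(self):
        x = np.ones((1, 1, 3, 3), np.float32)
        rf = B.expand_to_receptive_field(x, 3, 1, 1)
        assert rf.shape == (1, 9, 3, 3)
        assert np.allclose(rf.data[0, :, 1, 1], 1.0)  # center window: nine ones
        # corner window contains the padding zeros
        assert rf.data[0, 0, 0, 0] == 0.0 and rf.data[0, 8, 0, 0] == 1.0

    def test_strided_shape_law(self):
        rf = B.expand_to_receptive_field(np.zeros((1, 1, 4, 4), np.float32), 3, 2, 1)
        assert rf.shape == (1, 9, 2, 2)

    def test_matches_nested_loop_oracle(self, rng):
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        rf = B.expand_to_receptive_field(x, 3, 1, 1).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for c in range(2):
            for ki in range(3):
                for kj in range(3):
                    for i in range(5):
                        for j in range(5):
                            assert rf[0, c * 9 + ki * 3 + kj, i, j] == xp[0, c, i + ki, j + kj]

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(h=st.integers(2, 8), w=st.integers(2, 8), stride=st.integers(1, 2),
           pad=st.integers(0, 2))
    def test_property_matches_oracle(self, h, w, stride, pad):
        rng = np.random.default_rng(h * 100 + w * 10 + stride + pad)
        x = rng.standard_normal((1, 1, h, w)).astype(np.float32)
        ho = (h + 2 * pad - 3) // stride + 1
        wo = (w + 2 * pad - 3) // stride + 1
        if ho < 1 or wo < 1:
            return
        rf = B.expand_to_receptive_field(x, 3, stride, pad).data
        assert rf.shape == (1, 9, ho, wo)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        for i in range(ho):
            for j in range(wo):
                win = xp[0, 0, i * stride:i * stride + 3, j * stride:j * stride + 3]
                assert np.array_equal(rf[0, :, i, j], win.ravel())

    def test_invalid_config_errors(self):
        x = np.zeros((1, 1, 4, 4), np.float32)
        with pytest.raises(ValueError):
            B.expand_to_receptive_field(x, 0, 1, 1)
        with pytest.raises(ValueError):
            B.expand_to_receptive_field(x, 3, 0, 1)
        with pytest.raises(ValueError):
            B.expand_to_receptive_field(x, 4, 1, 1)


# ---------------------------------------------------------------------------
# RFCA convolution
# ---------------------------------------------------------------------------

def _zero_attention_branches(m: B.RFCAConv):
    for conv in (m.conv_h, m.conv_w):
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0


class TestRFCAConv:
    def test_bias_only_attention_is_half(self, rng):
        nn.seed_init(0)
        m = B.RFCAConv(8, 8, 3, 1)
        _zero_attention_branches(m)
        rf = Tensor(rng.standard_normal((2, 8, 9, 9)).astype(np.float32))
        ah, aw = m.attention(rf)
        assert np.allclose(ah.data, 0.5) and np.allclose(aw.data, 0.5)

    def test_attention_in_open_unit_interval(self, rng):
        nn.seed_init(3)
        m = B.RFCAConv(8, 8, 3, 1)
        ah, aw = m.attention(Tensor(rng.standard_normal((1, 8, 12, 12)).astype(np.float32) * 5))
        for a in (ah, aw):
            assert (a.data > 0).all() and (a.data < 1).all()

    def test_constant_rows_give_constant_horizontal_pool(self, rng):
        nn.seed_init(0)
        m = B.RFCAConv(4, 4, 3, 1)
        col = rng.standard_normal((1, 4, 6, 1)).astype(np.float32)
        rf = Tensor(np.repeat(col, 6, axis=3))  # constant across W
        ph, _ = m.pooled_descriptors(rf)
        assert np.allclose(ph.data, col, atol=1e-6)

    def test_resolution_contract(self, rng):
        nn.seed_init(1)
        m = B.RFCAConv(16, 24, 3, 1)
        y = m(Tensor(rng.standard_normal((2, 16, 32, 32)).astype(np.float32)))
        assert y.shape == (2, 24, 32, 32)
        m2 = B.RFCAConv(16, 24, 3, 2)
        y2 = m2(Tensor(rng.standard_normal((2, 16, 33, 33)).astype(np.float32)))
        assert y2.shape == (2, 24, 17, 17)  # ceil(33/2)

    def test_identity_attention_reduces_to_plain_pipeline(self, rng, monkeypatch):
        nn.seed_init(2)
        m = B.RFCAConv(8, 12, 3, 1)
        m.eval()
        x = Tensor(rng.standard_normal((1, 8, 10, 10)).astype(np.float32))
        ref = m.collapse(B.rf_to_spatial(m.generate(x), 8, 3))
        monkeypatch.setattr(m, "attention", lambda rf: (Tensor(1.0), Tensor(1.0)))
        assert np.allclose(m(x).data, ref.data, atol=1e-6)

    def test_half_attention_equals_halved_features(self, rng, monkeypatch):
        # the collapse convolution is linear (conv then BN in eval mode),
        # so scaling its input by 0.5 must follow through linearly up to BN shift
        nn.seed_init(2)
        m = B.RFCAConv(8, 12, 3, 1)
        m.eval()
        x = Tensor(rng.standard_normal((1, 8, 10, 10)).astype(np.float32))
        rs = B.rf_to_spatial(m.generate(x), 8, 3)
        conv_out_half = m.collapse[0](rs * 0.5)
        monkeypatch.setattr(m, "attention", lambda rf: (Tensor(0.5), Tensor(1.0)))
        out = m(x)
        ref = m.collapse[2](m.collapse[1](conv_out_half))
        assert np.allclose(out.data, ref.data, atol=1e-5)

    def test_channel_mismatch_raises(self, rng):
        m = B.RFCAConv(8, 8, 3, 1)
        with pytest.raises(ValueError):
            m(Tensor(np.zeros((1, 4, 8, 8), np.float32)))


class TestC2fRFCA:
    def test_spatial_preservation(self, rng):
        nn.seed_init(0)
        m = B.C2fRFCA(32, 32, 1)
        y = m(Tensor(rng.standard_normal((1, 32, 16, 16)).astype(np.float32)))
        assert y.shape == (1, 32, 16, 16)

    def test_hidden_width_grows_with_bottlenecks(self):
        m1, m2 = B.C2fRFCA(32, 32, 1), B.C2fRFCA(32, 32, 2)
        assert m2.cv2.conv.weight.shape[1] - m1.cv2.conv.weight.shape[1] == m1.c

    def test_parameter_census_matches_hand_sum(self):
        # layer-by-layer audit of c2f_rfca(64->64, n=1)
        nn.seed_init(0)
        m = B.C2fRFCA(64, 64, 1)
        total = sum(p.data.size for p in m.parameters())

        def conv_bn(c1, c2, k):
            return c1 * c2 * k * k + 2 * c2

        c = 32
        mip = max(8, min(48, c // 2))
        rfca = (c * 9 * 9 + 2 * c * 9          # grouped generation + BN
                + c * mip + mip + 2 * mip      # squeeze conv + bias + BN
                + 2 * (mip * c + c)            # two directional branches
                + conv_bn(c, c, 3))            # collapse conv + BN
        expected = (conv_bn(64, 2 * c, 1) + conv_bn(3 * c, 64, 1)
                    + conv_bn(c, c, 3) + rfca)
        assert total == expected

    def test_invalid_bottleneck_count(self):
        with pytest.raises(ValueError):
            B.C2fRFCA(32, 32, 0)


# ---------------------------------------------------------------------------
# LSKA
# ---------------------------------------------------------------------------

class TestLSKA:
    def test_shape_preservation(self, rng):
        nn.seed_init(0)
        m = B.LSKA(8, 11, 3)
        y = m(Tensor(rng.standard_normal((1, 8, 20, 20)).astype(np.float32)))
        assert y.shape == (1, 8, 20, 20)

    def test_separable_pair_equals_rank1_2d_depthwise(self, rng):
        """A 1xk then kx1 depth-wise pair with kernels u, v equals one 2-D
        depth-wise convolution with kernel v u^T."""
        c, k = 3, 5
        u = rng.standard_normal((c, 1, 1, k)).astype(np.float32)
        v = rng.standard_normal((c, 1, k, 1)).astype(np.float32)
        x = rng.standard_normal((1, c, 12, 12)).astype(np.float32)
        h = nn.conv2d(Tensor(x), Tensor(u), None, padding=(0, k // 2), groups=c)
        out = nn.conv2d(h, Tensor(v), None, padding=(k // 2, 0), groups=c)
        xp = np.pad(x, ((0, 0), (0, 0), (k // 2, k // 2), (k // 2, k // 2)))
        for ch in range(c):
            k2d = v[ch, 0] @ u[ch, 0]           # rank-1 outer product
            ref = correlate2d(xp[0, ch], k2d, mode="valid")
            assert np.abs(out.data[0, ch] - ref).max() < 1e-5

    def test_gradient_footprint_matches_kernel_support(self, rng):
        """The receptive field of one output element equals the analytic
        composition of the cascaded kernel supports."""
        K, d = 11, 3
        k0, k1 = 2 * d - 1, -(-K // d)
        nn.seed_init(5)
        m = B.LSKA(1, K, d)
        for conv in (m.conv0h, m.conv0v, m.convsh, m.convsv):
            conv.weight.data[...] = rng.uniform(0.5, 1.0, conv.weight.shape)
        m.conv1.weight.data[...] = 1.0
        size = 41
        x = Tensor(np.zeros((1, 1, size, size), np.float32), True)
        y = m.attention(x)
        g = np.zeros_like(y.data)
        g[0, 0, size // 2, size // 2] = 1.0
        y.backward(g)
        # support composition: plain k0 stage then dilated k1 stage
        half = (k0 - 1) // 2 + ((k1 - 1) * d + 1 - 1) // 2 + ((k1 - 1) * d) % 2
        nz = np.nonzero(x.grad[0, 0])
        for axis in range(2):
            lo, hi = nz[axis].min(), nz[axis].max()
            assert lo >= size // 2 - half - 1 and hi <= size // 2 + half + 1

    def test_invalid_decomposition(self):
        with pytest.raises(ValueError):
            B.LSKA(8, 3, 3)  # K < 2d-1


class TestSPPFLSKA:
    def test_shape_contract(self, rng):
        nn.seed_init(0)
        m = B.SPPFLSKA(64, 64)
        y = m(Tensor(rng.standard_normal((1, 64, 8, 8)).astype(np.float32)))
        assert y.shape == (1, 64, 8, 8)

    def test_serial_pools_equal_single_large_pool(self, rng):
        """Branch i of the serial max-pool chain equals one pool of kernel
        (k-1)*i + k applied to the in-conv output."""
        nn.seed_init(1)
        m = B.SPPF(32, 32, 5)
        m.eval()
        x = Tensor(rng.standard_normal((1, 32, 16, 16)).astype(np.float32))
        branches = m.branches(x)
        y0 = branches[0]
        for i, k in enumerate([5, 9, 13]):  # (5-1)*i+5 for i=0,1,2
            direct = nn.maxpool2d(y0, k, stride=1, padding=k // 2)
            assert np.array_equal(branches[i + 1].data, direct.data)

    def test_identity_lska_reduces_to_plain_sppf(self, rng):
        nn.seed_init(2)
        ref = B.SPPF(32, 48, 5)
        mod = B.SPPFLSKA(32, 48, 5)
        mod.cv1.conv.weight.data[...] = ref.cv1.conv.weight.data
        mod.cv2.conv.weight.data[...] = ref.cv2.conv.weight.data
        mod.lska = nn.Identity()
        ref.eval(); mod.eval()
        x = Tensor(rng.standard_normal((1, 32, 8, 8)).astype(np.float32))
        assert np.allclose(mod(x).data, ref(x).data, atol=1e-6)


# ---------------------------------------------------------------------------
# CARAFE
# ---------------------------------------------------------------------------

class TestCARAFE:
    def test_kernel_field_shape_and_normalisation(self, rng):
        nn.seed_init(0)
        m = B.CARAFE(16, cm=32, k_up=5, sigma=2)
        k = m.predict_kernels(Tensor(rng.standard_normal((1, 16, 6, 6)).astype(np.float32)))
        assert k.shape == (1, 25, 12, 12)
        assert np.abs(k.data.sum(axis=1) - 1).max() < 1e-5
        assert (k.data >= 0).all()

    def test_zero_encoder_gives_uniform_kernels(self, rng):
        nn.seed_init(0)
        m = B.CARAFE(8, cm=16)
        m.encoder.weight.data[...] = 0.0
        m.encoder.bias.data[...] = 0.0
        k = m.predict_kernels(Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32)))
        assert np.allclose(k.data, 1.0 / 25.0, atol=1e-6)

    def test_constant_input_preserved_in_interior(self, rng):
        # convex combination of a constant is the constant wherever the
        # neighborhood avoids the zero border padding
        nn.seed_init(1)
        m = B.CARAFE(4)
        x = Tensor(np.full((1, 4, 8, 8), 3.25, np.float32))
        y = m.reassemble(x, m.predict_kernels(x))
        r = m.k_up // 2 * m.sigma  # border strip influenced by padding
        assert np.allclose(y.data[:, :, r:-r, r:-r], 3.25, atol=1e-5)
        assert (y.data >= -1e-5).all() and (y.data <= 3.25 + 1e-5).all()

    def test_matches_bruteforce_weighted_sum(self, rng):
        """Reassembly equals the quadruple-loop weighted neighborhood sum."""
        nn.seed_init(2)
        x = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
        sigma, kup, r = 2, 5, 2
        kern = rng.random((1, kup * kup, 12, 12)).astype(np.float32)
        kern /= kern.sum(axis=1, keepdims=True)
        y = B.carafe_reassemble(x, kern, sigma, kup).data
        xp = np.pad(x, ((0, 0), (0, 0), (r, r), (r, r)))
        for c in range(4):
            for oi in range(12):
                for oj in range(12):
                    si, sj = oi // sigma, oj // sigma
                    acc = 0.0
                    for ki in range(kup):
                        for kj in range(kup):
                            acc += kern[0, ki * kup + kj, oi, oj] * xp[0, c, si + ki, sj + kj]
                    assert abs(y[0, c, oi, oj] - acc) < 1e-6

    def test_onehot_center_kernel_is_nearest_neighbor(self, rng):
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        kern = np.zeros((1, 25, 8, 8), np.float32)
        kern[:, 12] = 1.0  # center of the 5x5 neighborhood
        y = B.carafe_reassemble(x, kern, 2, 5).data
        assert np.allclose(y, np.repeat(np.repeat(x, 2, 2), 2, 3), atol=1e-7)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(h=st.integers(2, 6), c=st.integers(1, 4), seed=st.integers(0, 10 ** 6))
    def test_convex_combination_bounds(self, h, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((1, c, h, h)).astype(np.float32)
        nn.seed_init(seed % 97)
        m = B.CARAFE(c, cm=8)
        y = m(Tensor(x)).data
        # padding contributes zeros, so bounds include 0
        assert y.max() <= max(x.max(), 0.0) + 1e-5
        assert y.min() >= min(x.min(), 0.0) - 1e-5

    def test_shape_inconsistency_raises(self, rng):
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            B.carafe_reassemble(x, np.zeros((1, 25, 6, 6), np.float32), 2, 5)


# ---------------------------------------------------------------------------
# Differentiability of every block
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("factory,cin", [
    (lambda: B.RFCAConv(8, 8, 3, 1), 8),
    (lambda: B.C2fRFCA(8, 8, 1), 8),
    (lambda: B.LSKA(8, 11, 3), 8),
    (lambda: B.SPPFLSKA(8, 8), 8),
    (lambda: B.CARAFE(8, cm=8), 8),
    (lambda: B.SPPF(8, 8), 8),
    (lambda: B.C2f(8, 8, 1, True), 8),
])
def test_blocks_differentiable_end_to_end(rng, factory, cin):
    nn.seed_init(9)
    m = factory()
    x = Tensor(rng.standard_normal((2, cin, 8, 8)).astype(np.float32), True)
    ((m(x) ** 2).sum()).backward()
    for name, p in m.named_parameters():
        assert p.grad is not None and np.isfinite(p.grad).all(), name
    assert x.grad is not None and np.isfinite(x.grad).all()
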