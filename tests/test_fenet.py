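"""Haar transform, WSPM, FE-RFB and the full network: structural contracts."""

import numpy as np
import pytest

from fenoct import autodiff as ad
from fenoct.fenet import (
    FERFB,
    FERFBConfig,
    NetConfig,
    WSPM,
    WSPMConfig,
    WaveletSubbands,
    build_network,
    haar_dwt2,
    haar_idwt2,
)


class TestHaar:
    def test_constant_block(self):
        s = haar_dwt2(np.full((2, 2), 3.0))
        assert s.LL[0, 0] == pytest.approx(6.0)
        assert s.LH[0, 0] == s.HL[0, 0] == s.HH[0, 0] == 0.0

    def test_worked_block(self):
        s = haar_dwt2(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert (s.LL[0, 0], s.LH[0, 0], s.HL[0, 0], s.HH[0, 0]) == (5.0, 2.0, 1.0, 0.0)

    def test_energy_conservation(self, rng):
        x = rng.normal(size=(32, 32))
        s = haar_dwt2(x)
        e = sum(np.sum(b ** 2) for b in (s.LL, s.LH, s.HL, s.HH))
        assert e == pytest.approx(np.sum(x ** 2), rel=1e-12)

    def test_round_trip(self, rng):
        x = rng.normal(size=(3, 16, 16))
        assert np.abs(haar_idwt2(haar_dwt2(x)) - x).max() < 1e-12

    def test_zero_subbands_give_zero_image(self):
        z = np.zeros((4, 4))
        out = haar_idwt2(WaveletSubbands(z, z, z, z))
        np.testing.assert_array_equal(out, np.zeros((8, 8)))

    def test_ll_only_is_block_average(self, rng):
        x = rng.normal(size=(8, 8))
        s = haar_dwt2(x)
        z = np.zeros_like(s.LL)
        rec = haar_idwt2(WaveletSubbands(s.LL, z, z, z))
        avg = x.reshape(4, 2, 4, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(rec, np.repeat(np.repeat(avg, 2, 0), 2, 1),
                                   atol=1e-12)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError, match="even"):
            haar_dwt2(np.zeros((5, 4)))

    def test_mismatched_subbands_rejected(self):
        with pytest.raises(ValueError):
            WaveletSubbands(np.zeros((2, 2)), np.zeros((2, 2)),
                            np.zeros((2, 2)), np.zeros((3, 2)))


class TestWSPM:
    def test_lambda_zero_identity(self, rng):
        m = WSPM(3, WSPMConfig(lambda_mix=0.0))
        x = rng.normal(size=(2, 3, 16, 16))
        assert np.abs(m.forward_array(x) - x).max() < 1e-5

    def test_lambda_one_block_average(self, rng):
        m = WSPM(2, WSPMConfig(lambda_mix=1.0))
        x = rng.normal(size=(1, 2, 8, 8))
        avg = x.reshape(1, 2, 4, 2, 4, 2).mean(axis=(3, 5))
        expect = np.repeat(np.repeat(avg, 2, axis=2), 2, axis=3)
        assert np.abs(m.forward_array(x) - expect).max() < 1e-12

    def test_detail_energy_attenuation(self, rng):
        """White noise through lambda=0.65: detail energy scaled by (1-l)^2."""
        lam = 0.65
        m = WSPM(1, WSPMConfig(lambda_mix=lam))
        x = rng.normal(size=(1, 1, 128, 128))
        out = m.forward_array(x)

        def detail_energy(arr):
            s = haar_dwt2(arr[0, 0])
            return sum(np.sum(b ** 2) for b in (s.LH, s.HL, s.HH))

        ratio = detail_energy(out) / detail_energy(x)
        assert ratio == pytest.approx((1 - lam) ** 2, rel=0.05)

    def test_linearity(self, rng):
        """wspm(ax + by) == a wspm(x) + b wspm(y): no hidden normalisation in
        the spectral path."""
        m = WSPM(2, WSPMConfig(lambda_mix=0.65))
        # non-trivial linear refiner
        m.refiner_weight.data = rng.normal(size=m.refiner_weight.data.shape)
        m.refiner_bias.data[:] = 0.0
        x = rng.normal(size=(1, 2, 16, 16))
        y = rng.normal(size=(1, 2, 16, 16))
        a, b = 1.7, -0.4
        lhs = m.forward_array(a * x + b * y)
        rhs = a * m.forward_array(x) + b * m.forward_array(y)
        assert np.abs(lhs - rhs).max() < 1e-5

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            WSPMConfig(lambda_mix=1.2)


class TestFERFB:
    def _block(self, channels=8, rng_seed=0):
        return FERFB(channels, FERFBConfig(), WSPMConfig(),
                     use_wspm=True, rng=np.random.default_rng(rng_seed))

    def test_zero_weights_residual_identity(self, rng):
        blk = self._block()
        for name, p in blk.named_parameters():
            p.data[:] = 0.0
        x = rng.normal(size=(1, 8, 16, 16))
        np.testing.assert_allclose(blk.forward_array(x), x, atol=1e-12)

    @pytest.mark.parametrize("hw", [(16, 16), (32, 16), (12, 20)])
    def test_shape_preserved(self, rng, hw):
        blk = self._block()
        x = rng.normal(size=(1, 8) + hw)
        assert blk.forward_array(x).shape == x.shape

    def test_dilated_branch_reaches_distant_pixels(self):
        """A single-pixel perturbation must influence outputs >= 5 px away
        through the dilation-5 branch (11x11 receptive field)."""
        blk = self._block(rng_seed=3)
        x = np.zeros((1, 8, 32, 32))
        base = blk.forward_array(x)
        x2 = x.copy()
        x2[0, 0, 16, 16] = 1.0
        diff = np.abs(blk.forward_array(x2) - base).sum(axis=(0, 1))
        affected = np.argwhere(diff > 1e-10)
        dist = np.abs(affected - np.array([16, 16])).max(axis=1)
        assert dist.max() >= 5

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            FERFB(6, FERFBConfig(), WSPMConfig(), use_wspm=True,
                  rng=np.random.default_rng(0))

    def test_rates_must_increase(self):
        with pytest.raises(ValueError):
            FERFBConfig(n_branches=3, dilation_rates=(1, 3, 2))


class TestFEUNet:
    CFG = NetConfig(base_channels=8)

    @pytest.mark.parametrize("size", [64, 128, 192])
    def test_output_shape_matches_input(self, size):
        net = build_network(self.CFG, seed=0, dtype=np.float32)
        x = np.zeros((1, 1, size, size), dtype=np.float32)
        assert net.forward_array(x).shape == x.shape

    def test_parameter_count_reproducible(self):
        a = build_network(self.CFG, seed=0)
        b = build_network(self.CFG, seed=1)
        assert a.n_parameters() == b.n_parameters()

    def test_indivisible_size_rejected(self):
        net = build_network(self.CFG, seed=0)
        with pytest.raises(ValueError, match="divisible by 16"):
            net.forward_array(np.zeros((1, 1, 40, 40)))

    def test_gradient_reaches_every_parameter(self, rng):
        """One backward pass leaves no parameter with a zero gradient tensor
        (catches broken skip wiring)."""
        net = build_network(self.CFG, seed=2)
        x = ad.tensor(rng.normal(size=(1, 1, 32, 32)))
        loss = net(x).square().mean()
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.any(p.grad != 0.0), f"identically-zero gradient for {name}"

    def test_ablation_variants_change_structure(self):
        full = build_network(NetConfig(base_channels=8), seed=0)
        no_wspm = build_network(NetConfig(base_channels=8, use_wspm=False), seed=0)
        plain = build_network(NetConfig(base_channels=8, use_ferfb=False), seed=0)
        names_full = {n for n, _ in full.named_parameters()}
        assert any("wspm" in n for n in names_full)
        assert not any("wspm" in n for n, _ in no_wspm.named_parameters())
        assert not any("branches" in n for n, _ in plain.named_parameters())

    def test_wavelet_pool_variant_runs(self):
        net = build_network(NetConfig(base_channels=8, wavelet_pool=True), seed=0)
        x = np.zeros((1, 1, 32, 32))
        assert net.forward_array(x).shape == x.shape

    def test_state_dict_round_trip(self, rng):
        net = build_network(self.CFG, seed=4)
        state = net.state_dict()
        other = build_network(self.CFG, seed=5)
        other.load_state_dict(state)
        x = rng.normal(size=(1, 1, 32, 32))
        np.testing.assert_array_equal(net.forward_array(x), other.forward_array(x))

    def test_depth_fixed(self):
        with pytest.raises(ValueError):
            NetConfig(depth=3)


def test_haar_oracle_against_pywavelets(rng):
    """Cross-check the orthonormal Haar analysis against PyWavelets."""
    import pywt

    x = rng.normal(size=(16, 16))
    s = haar_dwt2(x)
    ll, (hl_p, lh_p, hh_p) = pywt.dwt2(x, "haar")
    # pywt: cH = horizontal detail (vertical differences) etc.; signs of
    # detail bands follow the filter convention, compare magnitudes and LL
    np.testing.assert_allclose(s.LL, ll, atol=1e-10)
    np.testing.assert_allclose(np.abs(s.LH), np.abs(hl_p), atol=1e-10)
    np.testing.assert_allclose(np.abs(s.HL), np.abs(lh_p), atol=1e-10)
    np.testing.assert_allclose(np.abs(s.HH), np.abs(hh_p), atol=1e-10)
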