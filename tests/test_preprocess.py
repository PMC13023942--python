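"""Classical preprocessing: stripe removal and notch filtering oracles."""

import numpy as np
import pytest

from fenoct import (
    BScan,
    NotchSpec,
    PhantomConfig,
    StripeRemovalSpec,
    detect_dominant_frequencies,
    make_volume,
    notch_filter,
    remove_stripes,
)
from fenoct.metrics import psnr


@pytest.fixture(scope="module")
def striped_volume():
    cfg = PhantomConfig(size=(64, 64), stripe_count=3, stripe_amplitude=0.35,
                        background_amplitude=0.0, seed=21)
    return cfg, make_volume(cfg, 8)


class TestStripeRemoval:
    def test_clean_volume_untouched_with_high_threshold(self):
        cfg = PhantomConfig(size=(64, 64), stripe_count=0,
                            background_amplitude=0.0, seed=3)
        vol = make_volume(cfg, 4)
        spec = StripeRemovalSpec(stack_depth=4, threshold=10.0)
        out = remove_stripes([t.noisy for t in vol], spec)
        for a, b in zip(out, vol):
            np.testing.assert_array_equal(a.pixels, b.noisy.pixels)

    def test_flagged_rows_match_injected_mask(self, striped_volume):
        cfg, vol = striped_volume
        spec = StripeRemovalSpec(stack_depth=8)
        _, flags = remove_stripes([t.noisy for t in vol], spec, return_flags=True)
        truth = vol[0].stripe_mask.any(axis=1)
        detected = flags[0]
        inter = np.sum(truth & detected)
        union = np.sum(truth | detected)
        assert inter / union >= 0.9

    def test_stripe_contrast_reduced_90_percent(self, striped_volume):
        cfg, vol = striped_volume
        spec = StripeRemovalSpec(stack_depth=8)
        out = remove_stripes([t.noisy for t in vol], spec)
        rows = np.nonzero(vol[0].stripe_mask.any(axis=1))[0]

        def contrast(px):
            vals = []
            for r in rows:
                neigh = [rr for rr in (r - 2, r + 2)
                         if 0 <= rr < px.shape[0] and not vol[0].stripe_mask[rr].any()]
                if neigh:
                    vals.append(abs(px[r].mean() - np.mean([px[rr].mean() for rr in neigh])))
            return np.mean(vals)

        before = np.mean([contrast(t.noisy.pixels) for t in vol])
        after = np.mean([contrast(s.pixels) for s in out])
        assert after <= 0.1 * before

    def test_too_few_scans_rejected(self, striped_volume):
        _, vol = striped_volume
        with pytest.raises(ValueError, match="consecutive"):
            remove_stripes([vol[0].noisy], StripeRemovalSpec(stack_depth=8))

    def test_mixed_shapes_rejected(self):
        a = BScan(np.zeros((16, 16)))
        b = BScan(np.zeros((16, 18)))
        with pytest.raises(ValueError, match="shapes"):
            remove_stripes([a, b], StripeRemovalSpec(stack_depth=2))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            StripeRemovalSpec(stack_depth=1)
        with pytest.raises(ValueError):
            StripeRemovalSpec(replacement="magic")


def _sinusoid(h, w, period_rows, amp=0.1, base=0.5):
    r = np.arange(h)[:, None]
    return base + amp * np.cos(2 * np.pi * r / period_rows) * np.ones((1, w))


class TestDetectDominantFrequencies:
    def test_pure_sinusoid_peak_position(self):
        img = BScan(np.clip(_sinusoid(64, 64, 16.0), 0, 1))
        peaks = detect_dominant_frequencies(img, n_peaks=1)
        assert peaks == [(64 // 16, 0)]

    def test_column_sinusoid_peak_position(self):
        c = np.arange(64)[None, :]
        img = BScan(np.clip(0.5 + 0.1 * np.cos(2 * np.pi * c / 16.0)
                            * np.ones((64, 1)), 0, 1))
        assert detect_dominant_frequencies(img, n_peaks=1) == [(0, 64 // 16)]

    def test_constant_image_no_peaks(self):
        img = BScan(np.full((64, 64), 0.5))
        assert detect_dominant_frequencies(img, n_peaks=3) == []

    def test_two_sinusoids_amplitude_order(self):
        r = np.arange(64)[:, None]
        px = 0.5 + 0.12 * np.cos(2 * np.pi * r / 8.0) \
            + 0.05 * np.cos(2 * np.pi * r / 16.0)
        img = BScan(np.clip(px * np.ones((1, 64)), 0, 1))
        peaks = detect_dominant_frequencies(img, n_peaks=2)
        assert peaks == [(8, 0), (4, 0)]

    def test_full_exclusion_rejected(self):
        with pytest.raises(ValueError, match="whole spectrum"):
            detect_dominant_frequencies(BScan(np.zeros((16, 16))), 1,
                                        exclude_radius=8)


class TestNotchFilter:
    def test_no_op_round_trip(self, rng):
        img = BScan(rng.random((32, 32)))
        spec = NotchSpec(notches=((4, 0, 2.0, 0.0),), gaussian_sigma=0.0)
        out = notch_filter(img, spec)
        assert np.abs(out.pixels - img.pixels).max() < 1e-6

    def test_sinusoid_suppressed_and_psnr_improves(self):
        clean = np.full((64, 64), 0.5)
        noisy = _sinusoid(64, 64, 16.0, amp=0.1)
        img = BScan(np.clip(noisy, 0, 1))
        spec = NotchSpec(notches=((4, 0, 1.5, 1.0),))
        out = notch_filter(img, spec)
        resid_amp = np.abs(np.fft.fft2(out.pixels)[4, 0]) / (64 * 64) * 2
        assert resid_amp < 0.05 * 0.1
        assert psnr(out.pixels, clean, 1.0) > psnr(img.pixels, clean, 1.0)

    def test_notched_bin_power_down_20db(self, rng):
        px = np.clip(_sinusoid(64, 64, 16.0) + 0.02 * rng.normal(size=(64, 64)), 0, 1)
        img = BScan(px)
        out = notch_filter(img, NotchSpec(notches=((4, 0, 1.5, 1.0),)))
        p_in = np.abs(np.fft.fftshift(np.fft.fft2(img.pixels))[32 + 4, 32]) ** 2
        p_out = np.abs(np.fft.fftshift(np.fft.fft2(out.pixels))[32 + 4, 32]) ** 2
        assert 10 * np.log10(p_in / p_out) >= 20.0

    def test_gaussian_blur_applied(self, rng):
        img = BScan(rng.random((32, 32)))
        out = notch_filter(img, NotchSpec(notches=(), gaussian_sigma=2.0))
        assert out.pixels.std() < img.pixels.std()

    def test_out_of_bounds_notch_rejected(self):
        img = BScan(np.zeros((16, 16)))
        with pytest.raises(ValueError, match="bounds"):
            notch_filter(img, NotchSpec(notches=((20, 0, 1.0, 1.0),)))

    def test_non_finite_rejected(self):
        px = np.zeros((16, 16))
        img = BScan(px)
        object.__setattr__(img, "pixels", px * np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            notch_filter(img, NotchSpec())

    def test_spec_serialization_round_trip(self):
        spec = NotchSpec(notches=((4, 0, 1.5, 1.0), (0, 8, 2.0, 0.5)),
                         gaussian_sigma=1.0)
        assert NotchSpec.from_dict(spec.to_dict()) == spec

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NotchSpec(notches=((1, 1, 0.0, 1.0),))
        with pytest.raises(ValueError):
            NotchSpec(notches=((1, 1, 1.0, 1.5),))
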