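"""Phantom generator: structure, noise statistics, compositional exactness."""

import numpy as np
import pytest

from fenoct import (
    PhantomConfig,
    add_periodic_background,
    add_speckle,
    add_stripes,
    make_clean_phantom,
    make_dataset,
    make_volume,
)


def test_single_flat_layer_is_constant():
    cfg = PhantomConfig(size=(32, 32), n_layers=1,
                        layer_intensity_range=(0.5, 0.5), air_fraction=0.0)
    img = make_clean_phantom(cfg)
    np.testing.assert_array_equal(img.pixels, np.full((32, 32), 0.5))


def test_clean_phantom_deterministic_under_seed():
    cfg = PhantomConfig(size=(64, 64), seed=5)
    a = make_clean_phantom(cfg)
    b = make_clean_phantom(cfg)
    np.testing.assert_array_equal(a.pixels, b.pixels)


def test_layered_phantom_has_distinct_plateaus():
    """n_layers=4 at 256x256: the row-wise mean must show >= 3 plateaus."""
    cfg = PhantomConfig(size=(256, 256), n_layers=4, seed=3)
    img = make_clean_phantom(cfg)
    row_mean = img.pixels.mean(axis=1)
    deriv = np.abs(np.diff(row_mean))
    flat = deriv < 1e-3
    # count runs of >= 5 consecutive flat rows
    plateaus = 0
    run = 0
    for f in flat:
        run = run + 1 if f else 0
        if run == 5:
            plateaus += 1
    assert plateaus >= 3


def test_odd_size_rejected():
    with pytest.raises(ValueError, match="even"):
        PhantomConfig(size=(65, 64))


@pytest.mark.parametrize("bad", [dict(n_layers=0), dict(speckle_shape_parameter=0.0),
                                 dict(background_amplitude=-0.1),
                                 dict(background_periods=((3.0, np.inf),))])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        PhantomConfig(size=(32, 32), **bad)


class TestSpeckle:
    def test_degenerate_shape_limit_is_identity(self):
        clean = make_clean_phantom(PhantomConfig(size=(64, 64), seed=1))
        noisy, field = add_speckle(clean, shape=1e9, seed=2)
        assert np.abs(noisy.pixels - clean.pixels).max() < 1e-3

    def test_unit_mean_field(self):
        clean = make_clean_phantom(PhantomConfig(size=(512, 512), seed=1))
        _, field = add_speckle(clean, shape=1.0, seed=3)
        assert 0.98 <= field.mean() <= 1.02

    def test_variance_is_inverse_shape(self):
        clean = make_clean_phantom(PhantomConfig(size=(512, 512), seed=1))
        _, field = add_speckle(clean, shape=4.0, seed=4)
        assert 0.23 <= field.var() <= 0.27

    def test_nonpositive_shape_rejected(self):
        clean = make_clean_phantom(PhantomConfig(size=(32, 32), seed=1))
        with pytest.raises(ValueError):
            add_speckle(clean, shape=0.0, seed=0)


class TestBackground:
    def test_zero_amplitude_is_identity(self):
        clean = make_clean_phantom(PhantomConfig(size=(64, 64), seed=1))
        out, _ = add_periodic_background(clean, 0.0, [(64, np.inf)], seed=5)
        np.testing.assert_array_equal(out.pixels, clean.pixels)

    def test_row_only_period_constant_along_columns(self):
        clean = make_clean_phantom(PhantomConfig(size=(64, 64), seed=1))
        _, field = add_periodic_background(clean, 0.1, [(64, np.inf)], seed=5)
        # bit-identical along columns (std of a constant row is 0)
        assert (field.max(axis=1) - field.min(axis=1)).max() == 0.0

    def test_spectral_peak_at_stated_frequency(self):
        clean = make_clean_phantom(PhantomConfig(size=(128, 128), seed=1))
        _, field = add_periodic_background(clean, 0.1, [(16.0, np.inf)], seed=6)
        spec = np.abs(np.fft.fftshift(np.fft.fft2(field)))
        spec[64, 64] = 0.0  # ignore DC
        r, c = np.unravel_index(spec.argmax(), spec.shape)
        assert abs(r - 64) == 128 // 16 and c == 64

    def test_band_limited(self):
        """>= 95% of spectral energy below 0.3 cycles/px (periods >= 4 px)."""
        clean = make_clean_phantom(PhantomConfig(size=(128, 128), seed=1))
        _, field = add_periodic_background(
            clean, 0.1, [(16.0, np.inf), (8.0, 8.0), (np.inf, 4.0)], seed=6)
        spec = np.abs(np.fft.fft2(field)) ** 2
        fr = np.fft.fftfreq(128)[:, None]
        fc = np.fft.fftfreq(128)[None, :]
        low = np.hypot(fr, fc) <= 0.3
        assert spec[low].sum() / spec.sum() >= 0.95

    def test_short_period_rejected(self):
        clean = make_clean_phantom(PhantomConfig(size=(64, 64), seed=1))
        with pytest.raises(ValueError, match="low-frequency"):
            add_periodic_background(clean, 0.1, [(3.0, np.inf)], seed=0)


class TestStripes:
    def test_zero_count_identity(self):
        clean = make_clean_phantom(PhantomConfig(size=(64, 64), seed=1))
        out, mask = add_stripes(clean, 0, 0.3, "horizontal", seed=0)
        np.testing.assert_array_equal(out.pixels, clean.pixels)
        assert mask.sum() == 0

    def test_three_horizontal_stripes_make_three_row_bands(self):
        clean = make_clean_phantom(PhantomConfig(size=(64, 64), seed=1))
        _, mask = add_stripes(clean, 3, 0.3, "horizontal", seed=9)
        rows = mask.any(axis=1).astype(int)
        n_bands = int(np.sum(np.diff(np.concatenate([[0], rows])) == 1))
        assert n_bands == 3

    def test_seed_reuse_gives_identical_masks(self):
        clean = make_clean_phantom(PhantomConfig(size=(64, 64), seed=1))
        _, m1 = add_stripes(clean, 4, 0.3, "vertical", seed=11)
        _, m2 = add_stripes(clean, 4, 0.3, "vertical", seed=11)
        np.testing.assert_array_equal(m1, m2)

    def test_excessive_count_rejected(self):
        clean = make_clean_phantom(PhantomConfig(size=(32, 32), seed=1))
        with pytest.raises(ValueError, match="too large"):
            add_stripes(clean, 30, 0.3, "horizontal", seed=0)


class TestDataset:
    def test_single_image(self):
        assert len(make_dataset(PhantomConfig(size=(32, 32)), 1)) == 1

    def test_compositional_invariant_exact(self):
        for t in make_dataset(PhantomConfig(size=(64, 64), seed=2), 3):
            expect = np.clip(
                t.clean.pixels * t.speckle_field + t.background_field
                + t.stripe_contribution, 0.0, 1.0)
            np.testing.assert_array_equal(t.noisy.pixels, expect)

    def test_split_ratio_8_1_1(self):
        from fenoct import split_dataset

        items = list(range(10))
        tr, va, te = split_dataset(items, seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)
        assert sorted(tr + va + te) == items

    def test_dataset_io_roundtrip(self, tmp_path):
        from fenoct import read_bscan

        truths = make_dataset(PhantomConfig(size=(32, 32), seed=4), 2,
                              out_dir=tmp_path)
        back = read_bscan(tmp_path / "phantom_0000_noisy.tiff")
        assert back.pixels.shape == (32, 32)
        assert np.abs(back.pixels - truths[0].noisy.pixels).max() < 1e-4


def test_volume_shares_stripes_but_not_speckle():
    vol = make_volume(PhantomConfig(size=(64, 64), seed=8), 4)
    masks = [t.stripe_mask for t in vol]
    for m in masks[1:]:
        np.testing.assert_array_equal(masks[0], m)
    assert not np.array_equal(vol[0].speckle_field, vol[1].speckle_field)
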