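"""Synthetic layered-tissue OCT phantoms with the three MEMS-OCT noise types.

Real MEMS-OCT B-scans are corrupted by (i) multiplicative speckle from the
coherent interference of backscattered light, (ii) smooth periodic background
bias from swept-source instability and scanner vibration, and (iii) coherent
stripe artifacts from Fresnel reflections, which are spatially consistent
across consecutive B-scans.  This module generates piecewise-smooth layered
phantoms and applies exactly those corruptions, keeping every per-component
noise field so that oracle tests (and true-clean evaluation) can compare
against ground truth the real pipeline never sees.

Speckle is modelled as unit-mean Gamma(k, 1/k) multiplicative noise — the
standard fully-developed-speckle intensity model — with variance 1/k; the
background is a sum of 2D sinusoids with periods >= 4 px (band-limited by
construction); stripes are full-length constant lines 1-2 px wide.
Clipping to the dynamic range happens once, after all corruptions, so the
stored component fields remain exact pre-clip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .bscan import BScan, write_bscan

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "make_clean_phantom",
    "add_speckle",
    "add_periodic_background",
    "add_stripes",
    "make_phantom",
    "make_dataset",
    "make_volume",
    "default_roi_masks",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom family.

    Defaults emulate the study regime: 256x256 scans, speckle shape k=4
    (variance 0.25), background amplitude 10% of the dynamic range, three
    horizontal stripes, and a dark air band above the tissue for ROI-based
    SNR evaluation.
    """

    size: tuple[int, int] = (256, 256)
    n_layers: int = 4
    layer_intensity_range: tuple[float, float] = (0.25, 0.8)
    speckle_shape_parameter: float = 4.0
    background_amplitude: float = 0.1
    background_periods: Sequence[tuple[float, float]] = ((64.0, math.inf),)
    stripe_count: int = 3
    stripe_amplitude: float = 0.35
    stripe_orientation: str = "horizontal"
    seed: int = 0
    air_fraction: float = 0.15
    air_intensity: float = 0.03
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        h, w = self.size
        if h % 2 or w % 2:
            raise ValueError(f"phantom size must be even, got {self.size}")
        if h < 16 or w < 16:
            raise ValueError(f"phantom size must be >= 16, got {self.size}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.speckle_shape_parameter <= 0:
            raise ValueError("speckle_shape_parameter must be > 0")
        if self.background_amplitude < 0 or self.stripe_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        for pr, pc in self.background_periods:
            for p in (pr, pc):
                if math.isfinite(p) and p < 4:
                    raise ValueError(
                        f"background period {p} < 4 px is not low-frequency"
                    )
        if self.stripe_orientation not in ("horizontal", "vertical"):
            raise ValueError("stripe_orientation must be horizontal|vertical")
        if not 0 <= self.air_fraction < 1:
            raise ValueError("air_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class PhantomTruth:
    """A clean phantom with its exact per-component corruption fields."""

    clean: BScan
    speckle_field: np.ndarray
    background_field: np.ndarray
    stripe_mask: np.ndarray
    noisy: BScan
    seed: int
    config: PhantomConfig | None = None

    @property
    def stripe_contribution(self) -> np.ndarray:
        amp = self.config.stripe_amplitude if self.config is not None else 0.0
        return amp * self.stripe_mask


# ---------------------------------------------------------------------------
# clean phantom
# ---------------------------------------------------------------------------

def make_clean_phantom(config: PhantomConfig) -> BScan:
    """Piecewise-smooth image of horizontal tissue bands with smoothly curved
    boundaries; optionally a dark air band above the tissue.

    Per-layer base intensities are evenly spaced over
    ``layer_intensity_range`` and shuffled, so bands are mutually distinct
    whenever the range is non-degenerate.  Deterministic under a fixed seed.
    """
    h, w = config.size
    rng = np.random.default_rng(config.seed)
    lo, hi = config.layer_intensity_range
    n = config.n_layers
    if n == 1:
        intensities = np.array([0.5 * (lo + hi)])
    else:
        intensities = np.linspace(lo, hi, n)
        rng.shuffle(intensities)

    air_rows = int(round(config.air_fraction * h))
    tissue_top = air_rows
    # smoothly curved boundaries between consecutive bands
    cols = np.arange(w)
    base = np.linspace(tissue_top, h, n + 1)
    img = np.empty((h, w))
    img[:tissue_top, :] = config.air_intensity
    rows = np.arange(h)[:, None]
    boundary_prev = np.full(w, float(tissue_top))
    for i in range(n):
        if i < n - 1:
            amp = 0.02 * h * (0.5 + rng.random())
            phase = rng.uniform(0, 2 * math.pi)
            period = w / rng.uniform(1.0, 2.5)
            boundary = base[i + 1] + amp * np.sin(2 * math.pi * cols / period + phase)
        else:
            boundary = np.full(w, float(h))
        band = (rows >= boundary_prev[None, :]) & (rows < boundary[None, :])
        img[band] = intensities[i]
        boundary_prev = np.maximum(boundary, boundary_prev)
    vlo, vhi = config.value_range
    return BScan(np.clip(img, vlo, vhi), config.value_range)


# ---------------------------------------------------------------------------
# corruptions
# ---------------------------------------------------------------------------

def _speckle_field(shape: tuple[int, int], k: float, rng: np.random.Generator) -> np.ndarray:
    if k <= 0:
        raise ValueError(f"speckle shape parameter must be > 0, got {k}")
    return rng.gamma(shape=k, scale=1.0 / k, size=shape)


def add_speckle(clean: BScan, shape: float, seed: int) -> tuple[BScan, np.ndarray]:
    """Multiply by i.i.d. unit-mean Gamma(k, 1/k) speckle; Var(field)=1/k."""
    rng = np.random.default_rng(seed)
    fld = _speckle_field(clean.pixels.shape, shape, rng)
    return BScan.clipped(clean.pixels * fld, clean.value_range), fld


def _background_field(shape: tuple[int, int], amplitude: float,
                      periods: Sequence[tuple[float, float]],
                      rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    fld = np.zeros(shape)
    if amplitude == 0:
        return fld
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    for pr, pc in periods:
        for p in (pr, pc):
            if math.isfinite(p) and p < 4:
                raise ValueError(f"background period {p} < 4 px is not low-frequency")
        fr = 1.0 / pr if math.isfinite(pr) else 0.0
        fc = 1.0 / pc if math.isfinite(pc) else 0.0
        phase = rng.uniform(0, 2 * math.pi)
        # illumination bias is non-negative: each component rides on its own
        # pedestal, A (1 + cos), so dark image regions are not clipped into
        # harmonic-rich waveforms a notch cannot remove.  Axis-aligned
        # components broadcast a 1D cosine so the field is bit-exactly
        # constant along the other axis.
        if fc == 0.0:
            fld += amplitude * (1.0 + np.cos(2 * math.pi * fr * r + phase)) * np.ones((1, w))
        elif fr == 0.0:
            fld += amplitude * np.ones((h, 1)) * (1.0 + np.cos(2 * math.pi * fc * c + phase))
        else:
            fld += amplitude * (1.0 + np.cos(2 * math.pi * (fr * r + fc * c) + phase))
    return fld


def add_periodic_background(img: BScan, amplitude: float,
                            periods: Sequence[tuple[float, float]],
                            seed: int) -> tuple[BScan, np.ndarray]:
    """Add a sum of 2D sinusoids at the stated (row, col) periods with random
    phases; a period of ``inf`` means constant along that axis."""
    rng = np.random.default_rng(seed)
    fld = _background_field(img.pixels.shape, amplitude, periods, rng)
    if amplitude == 0:
        return img, fld
    return BScan.clipped(img.pixels + fld, img.value_range), fld


def _stripe_mask(shape: tuple[int, int], count: int, orientation: str,
                 rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    extent = h if orientation == "horizontal" else w
    if count < 0:
        raise ValueError("stripe count must be >= 0")
    if count > extent // 4:
        raise ValueError(
            f"stripe count {count} too large for image extent {extent}"
        )
    mask = np.zeros(shape)
    if count == 0:
        return mask
    # random non-adjacent line positions, width 1 or 2 px
    positions = rng.choice(np.arange(2, extent - 3, 4), size=count, replace=False)
    widths = rng.integers(1, 3, size=count)
    for pos, wd in zip(positions, widths):
        if orientation == "horizontal":
            mask[pos:pos + wd, :] = 1.0
        else:
            mask[:, pos:pos + wd] = 1.0
    return mask


def add_stripes(img: BScan, count: int, amplitude: float, orientation: str,
                seed: int) -> tuple[BScan, np.ndarray]:
    """Add full-length constant-intensity lines (width 1-2 px) at random but
    seed-stable positions, emulating Fresnel-reflection stripes that are
    consistent across consecutive B-scans when the same seed is reused."""
    rng = np.random.default_rng(seed)
    mask = _stripe_mask(img.pixels.shape, count, orientation, rng)
    if count == 0:
        return img, mask
    return BScan.clipped(img.pixels + amplitude * mask, img.value_range), mask


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def make_phantom(config: PhantomConfig) -> PhantomTruth:
    """One clean/noisy pair with exact component fields.

    noisy = clip(clean * speckle + background + stripe_amplitude * mask),
    clipped once to value_range after all corruptions.
    """
    clean = make_clean_phantom(config)
    rng = np.random.default_rng(config.seed + 1)
    speckle = _speckle_field(config.size, config.speckle_shape_parameter, rng)
    background = _background_field(config.size, config.background_amplitude,
                                   config.background_periods, rng)
    stripe_rng = np.random.default_rng(config.seed + 2)
    mask = _stripe_mask(config.size, config.stripe_count,
                        config.stripe_orientation, stripe_rng)
    raw = clean.pixels * speckle + background + config.stripe_amplitude * mask
    noisy = BScan.clipped(raw, config.value_range)
    return PhantomTruth(clean=clean, speckle_field=speckle,
                        background_field=background, stripe_mask=mask,
                        noisy=noisy, seed=config.seed, config=config)


def make_dataset(config: PhantomConfig, n_images: int,
                 out_dir: str | Path | None = None) -> list[PhantomTruth]:
    """n phantoms with per-image derived seeds (seed + index); optionally
    writes clean/noisy 16-bit TIFF pairs with JSON sidecars."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    truths = [make_phantom(replace(config, seed=config.seed + i))
              for i in range(n_images)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(truths):
            meta = {"seed": t.seed, "index": i,
                    "clean_file": f"phantom_{i:04d}_clean.tiff",
                    "noisy_file": f"phantom_{i:04d}_noisy.tiff"}
            write_bscan(out_dir / meta["clean_file"], t.clean)
            write_bscan(out_dir / meta["noisy_file"], t.noisy, sidecar=meta)
    return truths


def make_volume(config: PhantomConfig, n_scans: int,
                consistent_stripes: bool = True) -> list[PhantomTruth]:
    """A stack of consecutive B-scans of the same structure.

    Speckle decorrelates between scans (per-scan seed) while stripes keep the
    same positions when ``consistent_stripes`` — the property the stripe
    remover exploits.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    clean = make_clean_phantom(config)
    bg_rng = np.random.default_rng(config.seed + 1)
    background = _background_field(config.size, config.background_amplitude,
                                   config.background_periods, bg_rng)
    out = []
    for i in range(n_scans):
        sp_rng = np.random.default_rng(config.seed + 100 + i)
        speckle = _speckle_field(config.size, config.speckle_shape_parameter, sp_rng)
        stripe_seed = config.seed + 2 if consistent_stripes else config.seed + 200 + i
        mask = _stripe_mask(config.size, config.stripe_count,
                            config.stripe_orientation,
                            np.random.default_rng(stripe_seed))
        raw = clean.pixels * speckle + background + config.stripe_amplitude * mask
        out.append(PhantomTruth(clean=clean, speckle_field=speckle,
                                background_field=background, stripe_mask=mask,
                                noisy=BScan.clipped(raw, config.value_range),
                                seed=config.seed, config=config))
    return out


def default_roi_masks(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Default SNR ROIs: signal = the top tissue band, background = the air
    region above it (with small safety margins)."""
    h, w = config.size
    air_rows = int(round(config.air_fraction * h))
    if air_rows < 6:
        raise ValueError("phantom has no usable air band for the default ROI")
    band = max(4, (h - air_rows) // max(config.n_layers, 1) // 2)
    signal = np.zeros((h, w), dtype=bool)
    background = np.zeros((h, w), dtype=bool)
    background[2:air_rows - 2, :] = True
    signal[air_rows + 2:air_rows + 2 + band, :] = True
    return signal, background
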