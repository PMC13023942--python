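"""Image-quality metrics and the pseudo-clean evaluation protocol.

Three metrics are reported:

* **PSNR** ``10 log10(data_range^2 / MSE)`` — the declared dynamic range is
  used, never the per-image min/max, so values are comparable across images.
* **SSIM** — mean local structural similarity with an 11x11 Gaussian window
  (sigma 1.5) and the canonical stabilisers K1=0.01, K2=0.03.
* **SNR** ``20 log10(mean(signal ROI) / std(background ROI))`` — an
  ROI-based protocol with explicit signal/background masks (phantom
  default: top tissue band vs. the air region above it).

Because clean references do not exist for real data, evaluation follows the
pseudo-clean protocol: each noisy image is split by the fixed neighbour
subsampling into (g1, g2), the model denoises g1, and g2 serves as the
reference.  On phantoms the true-clean variant is also available, which is
the package's primary success criterion: PSNR(denoised, clean) must exceed
PSNR(noisy, clean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .bscan import BScan
from .sampler import subsample_pair

__all__ = ["MetricReport", "psnr", "ssim", "snr",
           "evaluate_pseudo_clean", "evaluate_true_clean"]

PSNR_INFINITE = math.inf


@dataclass(frozen=True)
class MetricReport:
    snr_db: float
    psnr_db: float
    ssim: float
    reference_kind: str  # pseudo_clean | true_clean
    n_images: int

    def __post_init__(self):
        if self.reference_kind not in ("pseudo_clean", "true_clean"):
            raise ValueError("reference_kind must be pseudo_clean|true_clean")
        if math.isfinite(self.ssim) and not -1.0 <= self.ssim <= 1.0 + 1e-12:
            raise ValueError(f"SSIM {self.ssim} outside [-1, 1]")

    @property
    def psnr_infinite(self) -> bool:
        return math.isinf(self.psnr_db)

    def as_dict(self) -> dict:
        return {"snr_db": self.snr_db, "psnr_db": self.psnr_db,
                "ssim": self.ssim, "psnr_infinite": self.psnr_infinite,
                "reference_kind": self.reference_kind, "n_images": self.n_images}


def _pixels(x) -> np.ndarray:
    return x.pixels if isinstance(x, BScan) else np.asarray(x, dtype=np.float64)


def psnr(a, b, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB; identical images yield the infinite
    sentinel rather than an exception."""
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((pa - pb) ** 2))
    if mse == 0.0:
        return PSNR_INFINITE
    return 10.0 * math.log10(data_range ** 2 / mse)


_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius 5 -> 11x11 window
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03


def ssim(a, b, data_range: float) -> float:
    """Mean local SSIM, 11x11 Gaussian window (sigma 1.5), K1/K2 = 0.01/0.03,
    sample-covariance normalisation, averaged over the interior where the
    window fits entirely."""
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    if min(pa.shape) < 11:
        raise ValueError(f"images smaller than the 11x11 SSIM window: {pa.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")

    def filt(x):
        return ndimage.gaussian_filter(x, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE,
                                       mode="nearest")

    win = 2 * int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5) + 1
    np_pix = win * win
    cov_norm = np_pix / (np_pix - 1.0)
    ux, uy = filt(pa), filt(pb)
    uxx, uyy, uxy = filt(pa * pa), filt(pb * pb), filt(pa * pb)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    num = (2 * ux * uy + c1) * (2 * vxy + c2)
    den = (ux * ux + uy * uy + c1) * (vx + vy + c2)
    smap = num / den
    pad = (win - 1) // 2
    return float(smap[pad:-pad, pad:-pad].mean())


def snr(img, signal_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """ROI signal-to-noise ratio: 20 log10(mean(signal) / std(background))."""
    px = _pixels(img)
    sm = np.asarray(signal_mask, dtype=bool)
    bm = np.asarray(background_mask, dtype=bool)
    if not sm.any() or not bm.any():
        raise ValueError("both ROI masks must be non-empty")
    if (sm & bm).any():
        raise ValueError("signal and background ROIs must be disjoint")
    sd = float(px[bm].std())
    if sd == 0.0:
        return math.inf
    return 20.0 * math.log10(abs(float(px[sm].mean())) / sd)


def _aggregate(per_image: list[tuple[float, float, float]], kind: str) -> MetricReport:
    snrs = [m[0] for m in per_image]
    psnrs = [m[1] for m in per_image]
    ssims = [m[2] for m in per_image]
    psnr_mean = math.inf if any(math.isinf(p) for p in psnrs) else float(np.mean(psnrs))
    snr_mean = (math.nan if all(math.isnan(s) for s in snrs)
                else float(np.nanmean([s for s in snrs])))
    return MetricReport(snr_db=snr_mean, psnr_db=psnr_mean,
                        ssim=float(np.mean(ssims)), reference_kind=kind,
                        n_images=len(per_image))


def evaluate_pseudo_clean(model: Callable[[BScan], BScan],
                          test_set: Sequence[BScan], pattern_id: str = "A",
                          roi: tuple[np.ndarray, np.ndarray] | None = None
                          ) -> MetricReport:
    """Pseudo-clean protocol: denoise g1(y) and score it against g2(y).

    ``model`` maps a (half-resolution) BScan to a BScan.  ``roi`` supplies
    half-resolution SNR masks; without it SNR is reported as NaN.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    rows = []
    for y in test_set:
        pair = subsample_pair(y, pattern_id)
        pred = model(pair.g1)
        dr = y.data_range
        p = psnr(pred, pair.g2, dr)
        s = ssim(pred, pair.g2, dr)
        sn = snr(pred, *roi) if roi is not None else math.nan
        rows.append((sn, p, s))
    return _aggregate(rows, "pseudo_clean")


def evaluate_true_clean(model: Callable[[BScan], BScan],
                        pairs: Sequence[tuple[BScan, BScan]],
                        roi: tuple[np.ndarray, np.ndarray] | None = None
                        ) -> MetricReport:
    """Oracle protocol on phantoms: denoise the full noisy scan and score it
    against the true clean image (never available for real data)."""
    if len(pairs) == 0:
        raise ValueError("empty test set")
    rows = []
    for noisy, clean in pairs:
        pred = model(noisy)
        dr = clean.data_range
        p = psnr(pred, clean, dr)
        s = ssim(pred, clean, dr)
        sn = snr(pred, *roi) if roi is not None else math.nan
        rows.append((sn, p, s))
    return _aggregate(rows, "true_clean")
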