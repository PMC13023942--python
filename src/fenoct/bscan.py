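"""The B-scan container and single-channel image I/O.

A B-scan is one grayscale OCT cross-section: rows are axial depth, columns
lateral position.  Pixel values are carried as floating point together with
the declared ``value_range`` (the dynamic range of the acquisition, e.g.
(0, 255) for 8-bit data); metrics always use the declared range rather than
recomputing it from pixel extremes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["BScan", "read_bscan", "write_bscan"]

_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class BScan:
    """One grayscale OCT cross-section image with its dynamic range."""

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError(f"B-scan must be a 2D array, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("B-scan contains non-finite pixels")
        lo, hi = self.value_range
        if not hi > lo:
            raise ValueError(f"invalid value_range {self.value_range}")
        if px.size and (px.min() < lo - _RANGE_TOL or px.max() > hi + _RANGE_TOL):
            raise ValueError(
                f"pixel values [{px.min():.6g}, {px.max():.6g}] outside "
                f"declared value_range {self.value_range}"
            )

    @classmethod
    def clipped(cls, pixels: np.ndarray, value_range: tuple[float, float] = (0.0, 1.0)) -> "BScan":
        lo, hi = value_range
        return cls(np.clip(np.asarray(pixels, dtype=np.float64), lo, hi), value_range)

    @property
    def H(self) -> int:
        return self.pixels.shape[0]

    @property
    def W(self) -> int:
        return self.pixels.shape[1]

    @property
    def data_range(self) -> float:
        return float(self.value_range[1] - self.value_range[0])

    def with_pixels(self, pixels: np.ndarray) -> "BScan":
        return BScan(pixels, self.value_range)

    def require_even(self) -> "BScan":
        if self.H % 2 or self.W % 2:
            raise ValueError(
                f"operation requires even dimensions, got {self.H}x{self.W}; "
                "crop or pad the image first"
            )
        return self


def write_bscan(path: str | Path, scan: BScan, sidecar: dict | None = None) -> None:
    """Write a B-scan as 16-bit TIFF or 8-bit PNG, scaled from value_range.

    An optional JSON sidecar (same stem, ``.json``) records metadata.
    """
    path = Path(path)
    lo, hi = scan.value_range
    norm = (scan.pixels - lo) / (hi - lo)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.round(norm * 65535.0).astype(np.uint16))
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, np.round(norm * 255.0).astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    if sidecar is not None:
        meta = dict(sidecar)
        meta.setdefault("value_range", list(scan.value_range))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_bscan(path: str | Path, value_range: tuple[float, float] | None = None) -> BScan:
    """Read a single-channel TIFF/PNG as a BScan.

    Integer images are mapped back to the value_range recorded in the JSON
    sidecar when present, else to (0, 1).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        raw = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if raw.shape[2] not in (1,):
            raise ValueError("expected a single-channel image")
        raw = raw[..., 0]
    if value_range is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            value_range = tuple(meta.get("value_range", (0.0, 1.0)))
        else:
            value_range = (0.0, 1.0)
    lo, hi = value_range
    if raw.dtype == np.uint16:
        norm = raw.astype(np.float64) / 65535.0
    elif raw.dtype == np.uint8:
        norm = raw.astype(np.float64) / 255.0
    else:
        norm = raw.astype(np.float64)
        span = hi - lo
        return BScan(np.clip(norm, lo, hi), (lo, hi)) if span else BScan(norm)
    return BScan(lo + norm * (hi - lo), (lo, hi))
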