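"""Deterministic neighbour subsampling of a noisy B-scan.

One noisy image y is split into two complementary half-resolution images
(g1(y), g2(y)) by a *fixed*, non-random partition of its 2x2 cells: every
cell contributes exactly one pixel to each sub-image, and the two chosen
pixels are always spatially adjacent (Chebyshev distance <= 1), realising
the stride-2 noise-consistency constraint.  Because the rule is a pure
function of shape and pattern id, the mapping is identical across training,
validation and test — the property that makes the complementary sub-image a
stable pseudo-clean reference.

The default pattern "A" pairs the top-left and top-right pixel of each
cell: the split direction is lateral, so axial (depth) tissue-layer
boundaries — the anatomy OCT cares about — are never separated between the
two sub-images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bscan import BScan

__all__ = ["SubsampledPair", "PATTERNS", "subsample_pair",
           "noise_consistency_gap", "upsample_to_full", "pseudo_clean"]

# (row, col) offsets inside each 2x2 cell for (g1, g2); all pairs adjacent
PATTERNS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "A": ((0, 0), (0, 1)),  # top-left / top-right (lateral split, default)
    "B": ((0, 0), (1, 0)),  # top-left / bottom-left (axial split)
    "C": ((1, 0), (1, 1)),  # bottom-left / bottom-right
    "D": ((0, 1), (1, 1)),  # top-right / bottom-right
}


@dataclass(frozen=True)
class SubsampledPair:
    g1: BScan
    g2: BScan
    pattern_id: str
    source_shape: tuple[int, int]


def subsample_pair(y: BScan, pattern_id: str = "A") -> SubsampledPair:
    """Split y into the complementary pair (g1, g2) with the fixed pattern."""
    if pattern_id not in PATTERNS:
        raise KeyError(f"unknown pattern_id {pattern_id!r}; choose from {sorted(PATTERNS)}")
    y.require_even()
    (r1, c1), (r2, c2) = PATTERNS[pattern_id]
    g1 = y.pixels[r1::2, c1::2]
    g2 = y.pixels[r2::2, c2::2]
    return SubsampledPair(
        g1=BScan(np.ascontiguousarray(g1), y.value_range),
        g2=BScan(np.ascontiguousarray(g2), y.value_range),
        pattern_id=pattern_id,
        source_shape=(y.H, y.W),
    )


def noise_consistency_gap(g1: BScan, g2: BScan) -> float:
    """|mean(g2) - mean(g1)|: empirical estimate of the conditional-mean gap
    between the two sub-images (diagnostic; shrinks ~ n^{-1/2})."""
    if g1.pixels.shape != g2.pixels.shape:
        raise ValueError(
            f"shape mismatch: {g1.pixels.shape} vs {g2.pixels.shape}"
        )
    return float(abs(g2.pixels.mean() - g1.pixels.mean()))


def upsample_to_full(sub: BScan, target_shape: tuple[int, int]) -> BScan:
    """Nearest-neighbour replication of each pixel into its 2x2 cell."""
    h, w = sub.pixels.shape
    if target_shape != (2 * h, 2 * w):
        raise ValueError(
            f"target shape {target_shape} must be exactly twice {sub.pixels.shape}"
        )
    up = np.repeat(np.repeat(sub.pixels, 2, axis=0), 2, axis=1)
    return BScan(up, sub.value_range)


def pseudo_clean(y: BScan, pattern_id: str = "A") -> BScan:
    """Pseudo-clean full-size image: the complementary pair averaged (halving
    independent-noise variance) and replicated back to full resolution."""
    pair = subsample_pair(y, pattern_id)
    avg = 0.5 * (pair.g1.pixels + pair.g2.pixels)
    return upsample_to_full(BScan(avg, y.value_range), (y.H, y.W))
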