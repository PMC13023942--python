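"""The self-supervised training objective.

The total loss is a weighted sum of four terms

    L_total = lambda1 * L1 + lambda2 * L2 + lambda3 * L_freq + gamma * L_reg

* **L1 — sub-image prediction** ``mean |f(g1(y)) - g2(y)|``: the denoised
  first sub-image must match its complementary sibling pixel-wise.
* **L2 — noise-distribution consistency** ``mean (f(g1(y)) - f(g2(y)))^2``:
  the network must denoise both sub-images to the same estimate, which
  counteracts over-smoothing of either branch.
* **L_freq — frequency-domain consistency** ``mean |F(f(y)) - F(x_pseudo)|^2``
  with F the orthonormal 2D Fourier transform and ``x_pseudo`` the
  pseudo-clean image (the averaged complementary pair replicated to full
  size); normalised by pixel count so its value is resolution independent.
* **L_reg — the neighbour-subsampling regulariser**
  ``mean ((f(g1(y)) - g2(y)) - (g1(f(y)) - g2(f(y))))^2``: the residual of
  the sub-then-denoise path must match the residual of the
  denoise-then-sub path, vanishing identically for the identity network.

Default weights (0.8, 0.1, 0.1) and gamma = 0.01.

All functions accept either tape tensors (used during training, gradients
flow) or bare arrays/B-scans (used for diagnostics, a float is returned).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .bscan import BScan

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "sub_image_prediction_loss",
    "noise_consistency_loss",
    "frequency_consistency_loss",
    "n2n_regularizer",
    "total_loss",
    "grid_search_weights",
]


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 0.8
    lambda2: float = 0.1
    lambda3: float = 0.1
    gamma: float = 0.01

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    """The four loss components and their weighted total for one step."""

    l1_pred: float
    l2_consistency: float
    l_freq: float
    l_reg: float
    total: float

    def as_row(self) -> dict:
        return {"l1_pred": self.l1_pred, "l2_consistency": self.l2_consistency,
                "l_freq": self.l_freq, "l_reg": self.l_reg, "total": self.total}


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    if isinstance(x, BScan):
        return ad.tensor(x.pixels), False
    return ad.tensor(np.asarray(x, dtype=np.float64)), False


def _pairwise(a, b, fn) -> Tensor | float:
    ta, grad_a = _as_tensor(a)
    tb, grad_b = _as_tensor(b)
    if ta.data.shape != tb.data.shape:
        raise ValueError(f"shape mismatch: {ta.data.shape} vs {tb.data.shape}")
    out = fn(ta, tb)
    if grad_a or grad_b:
        return out
    return out.item()


def sub_image_prediction_loss(pred_g1, g2) -> Tensor | float:
    """Mean absolute difference between the denoised first sub-image and its
    complementary sibling."""
    return _pairwise(pred_g1, g2, ad.mean_abs)


def noise_consistency_loss(pred_g1, pred_g2) -> Tensor | float:
    """Mean squared difference between the two denoised sub-images."""
    return _pairwise(pred_g1, pred_g2, ad.mean_square)


def frequency_consistency_loss(denoised_full, x_pseudo) -> Tensor | float:
    """Mean squared modulus of the difference of orthonormal centered 2D
    Fourier spectra (resolution-independent by the pixel-count
    normalisation; equal to the spatial MSE by Parseval's theorem)."""
    return _pairwise(denoised_full, x_pseudo, ad.freq_mse)


def n2n_regularizer(model: Callable[[Tensor], Tensor], y,
                    pattern_id: str = "A") -> Tensor | float:
    """Residual-consistency regulariser of the neighbour-subsampling scheme.

    Penalises the mismatch between sub-then-denoise and denoise-then-sub
    residuals; zero for the identity model by exact cancellation.
    """
    from .sampler import PATTERNS

    arr, keep_grad = _as_tensor(y)
    if arr.data.ndim == 2:
        arr = ad.tensor(arr.data[None, None])
    (r1, c1), (r2, c2) = PATTERNS[pattern_id]
    g1 = ad.strided_sub(arr, r1, c1)
    g2 = ad.strided_sub(arr, r2, c2)
    f_g1 = model(g1)
    f_y = model(arr)
    g1_fy = ad.strided_sub(f_y, r1, c1)
    g2_fy = ad.strided_sub(f_y, r2, c2)
    diff = (f_g1 - g2) - (g1_fy - g2_fy)
    out = diff.square().mean()
    return out if keep_grad else out.item()


def total_loss(parts: Sequence, weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Weighted sum of the four components; parts may be floats or tensors
    (a tensor total keeps the gradient tape alive)."""
    if len(parts) != 4:
        raise ValueError("expected (l1_pred, l2_consistency, l_freq, l_reg)")
    names = ("l1_pred", "l2_consistency", "l_freq", "l_reg")
    vals = []
    for name, p in zip(names, parts):
        v = p.item() if isinstance(p, Tensor) else float(p)
        if not math.isfinite(v):
            raise ValueError(f"non-finite loss component {name}: {v}")
        vals.append(v)
    w = (weights.lambda1, weights.lambda2, weights.lambda3, weights.gamma)
    if any(isinstance(p, Tensor) for p in parts):
        total = None
        for wi, p in zip(w, parts):
            term = (p if isinstance(p, Tensor) else ad.tensor(np.float64(p))) * wi
            total = term if total is None else total + term
    else:
        total = vals[0] * w[0] + vals[1] * w[1] + vals[2] * w[2] + vals[3] * w[3]
    total_val = total.item() if isinstance(total, Tensor) else total
    bd = LossBreakdown(l1_pred=vals[0], l2_consistency=vals[1],
                       l_freq=vals[2], l_reg=vals[3], total=total_val)
    # keep the differentiable total reachable for training callers
    object.__setattr__(bd, "total_tensor", total if isinstance(total, Tensor) else None)
    return bd


def grid_search_weights(score_fn: Callable[[float, float, float], float],
                        step: float = 0.1,
                        bounds: tuple[float, float] = (0.0, 1.0)
                        ) -> tuple[tuple[float, float, float], list[dict]]:
    """Exhaustive grid over (lambda1, lambda2, lambda3) in ``bounds`` with
    the given step, maximising ``score_fn`` (validation SSIM).

    Returns the argmax tuple and the full score table, so callers can audit
    that the returned optimum is the argmax of the recorded scores.
    """
    lo, hi = bounds
    n = int(round((hi - lo) / step))
    values = [round(lo + i * step, 10) for i in range(n + 1)]
    table: list[dict] = []
    best = None
    for l1, l2, l3 in itertools.product(values, repeat=3):
        s = float(score_fn(l1, l2, l3))
        table.append({"lambda1": l1, "lambda2": l2, "lambda3": l3, "score": s})
        if best is None or s > best[0]:
            best = (s, (l1, l2, l3))
    return best[1], table
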