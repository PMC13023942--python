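"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core for the frequency-enhanced UNet: a small tape-based
engine with exactly the operators the network and its losses need (dense and
dilated 2D convolution, 2x2 max pooling, bilinear x2 upsampling, orthonormal
Haar analysis/synthesis, group normalisation, leaky ReLU, channel
concatenation/slicing, stride-2 subsampling and the usual arithmetic
reductions), plus an Adam optimiser.  All operators preserve the dtype of
their inputs, so float64 is available for numerical tests while training can
run in float32.

Gradients of every primitive are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import contextlib
import functools
import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "tensor",
    "no_grad",
    "is_grad_enabled",
    "conv2d",
    "max_pool2",
    "bilinear_up2",
    "leaky_relu",
    "concat",
    "narrow",
    "strided_sub",
    "haar_analysis",
    "haar_synthesis",
    "group_norm",
    "mean_abs",
    "mean_square",
    "freq_mse",
    "Adam",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array with an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: np.ndarray, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return _add(self, _wrap(other, self.dtype))

    __radd__ = __add__

    def __sub__(self, other):
        return _add(self, _scale(_wrap(other, self.dtype), -1.0))

    def __rsub__(self, other):
        return _add(_wrap(other, self.dtype), _scale(self, -1.0))

    def __neg__(self):
        return _scale(self, -1.0)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return _scale(self, float(other))
        return _mul(self, other)

    __rmul__ = __mul__

    def square(self):
        return _mul(self, self)

    def abs(self):
        return _abs(self)

    def mean(self):
        return _mean(self)

    def sum(self):
        return _sum(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that always participates in gradient computation."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data), requires_grad=True)
        # parameters keep requires_grad even if created under no_grad
        self.requires_grad = True


def tensor(data, dtype=None) -> Tensor:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype, copy=False)
    return Tensor(arr)


def _wrap(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _make(data, parents: tuple, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    out = Tensor(data, requires_grad=True, parents=tuple(p for p in parents if p.requires_grad))
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / reductions
# ---------------------------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    nextra = g.ndim - len(shape)
    if nextra:
        g = g.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        a._accumulate(g * s)

    return _make(a.data * s, (a,), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def _abs(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def backward(g):
        a._accumulate(g * sign)

    return _make(np.abs(a.data), (a,), backward)


def _mean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        a._accumulate(np.full_like(a.data, float(g) / n))

    return _make(np.asarray(a.data.mean(), dtype=a.dtype), (a,), backward)


def _sum(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(np.full_like(a.data, float(g)))

    return _make(np.asarray(a.data.sum(), dtype=a.dtype), (a,), backward)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        x._accumulate(np.where(mask, g, slope * g))

    return _make(out_data, (x,), backward)


def mean_abs(a: Tensor, b: Tensor) -> Tensor:
    """mean(|a - b|) — the L1 objective."""
    return (a - b).abs().mean()


def mean_square(a: Tensor, b: Tensor) -> Tensor:
    """mean((a - b)^2) — the MSE objective."""
    return (a - b).square().mean()


def freq_mse(a: Tensor, b: Tensor) -> Tensor:
    """Mean squared modulus of the difference of orthonormal 2D Fourier
    transforms over the trailing two axes.

    The forward pass is computed in the frequency domain; the gradient is the
    exact analytic one (the orthonormal DFT is unitary, so the derivative of
    the spectral mean-square difference with respect to the real inputs is
    ``2 (a-b) / size``).
    """
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    delta = a.data - b.data
    spec = np.fft.fft2(delta, norm="ortho")
    val = np.asarray((spec.real ** 2 + spec.imag ** 2).mean(), dtype=a.dtype)
    n = delta.size

    def backward(g):
        gd = (2.0 * float(g) / n) * delta
        if a.requires_grad:
            a._accumulate(gd)
        if b.requires_grad:
            b._accumulate(-gd)

    return _make(val, (a, b), backward)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def narrow(x: Tensor, start: int, length: int, axis: int = 1) -> Tensor:
    """Contiguous slice along one axis (channel slicing)."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accumulate(full)

    return _make(x.data[idx].copy(), (x,), backward)


def strided_sub(x: Tensor, row0: int, col0: int) -> Tensor:
    """Stride-2 spatial subsampling starting at (row0, col0) in each 2x2 cell."""
    def backward(g):
        full = np.zeros_like(x.data)
        full[..., row0::2, col0::2] = g
        x._accumulate(full)

    return _make(np.ascontiguousarray(x.data[..., row0::2, col0::2]), (x,), backward)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 on NCHW tensors."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2 requires even spatial dimensions")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    arg = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=x.data.dtype)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(n, c, h, w))

    return _make(np.ascontiguousarray(out_data), (x,), backward)


@functools.lru_cache(maxsize=64)
def _bilinear_matrix(n: int, dtype_str: str) -> np.ndarray:
    """(2n, n) interpolation matrix for x2 bilinear upsampling, half-pixel
    centres with edge clamping (the convention used by image resamplers)."""
    a = np.zeros((2 * n, n))
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        i0 = int(math.floor(src))
        f = src - i0
        i0c = min(max(i0, 0), n - 1)
        i1c = min(max(i0 + 1, 0), n - 1)
        a[i, i0c] += 1.0 - f
        a[i, i1c] += f
    return a.astype(dtype_str)


def bilinear_up2(x: Tensor) -> Tensor:
    """Bilinear x2 spatial upsampling of an NCHW tensor (separable)."""
    n, c, h, w = x.data.shape
    ar = _bilinear_matrix(h, str(x.data.dtype))
    ac = _bilinear_matrix(w, str(x.data.dtype))
    tmp = np.einsum("ph,nchw->ncpw", ar, x.data, optimize=True)
    out_data = np.einsum("qw,ncpw->ncpq", ac, tmp, optimize=True)

    def backward(g):
        gt = np.einsum("qw,ncpq->ncpw", ac, g, optimize=True)
        x._accumulate(np.einsum("ph,ncpw->nchw", ar, gt, optimize=True))

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, dil: int, ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c * kh * kw, ho * wo), dtype=xp.dtype)
    idx = 0
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i * dil:i * dil + ho, j * dil:j * dil + wo]
            cols[:, idx * c:(idx + 1) * c, :] = patch.reshape(n, c, ho * wo)
            idx += 1
    return cols


def _col2im(gcols: np.ndarray, shape: tuple, kh: int, kw: int, dil: int,
            ho: int, wo: int) -> np.ndarray:
    n, c = shape[:2]
    gx = np.zeros(shape, dtype=gcols.dtype)
    idx = 0
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i * dil:i * dil + ho, j * dil:j * dil + wo] += \
                gcols[:, idx * c:(idx + 1) * c, :].reshape(n, c, ho, wo)
            idx += 1
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           dilation: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation), stride 1, zero padding, NCHW."""
    n, cin, h, wdt = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    ho = h + 2 * padding - dilation * (kh - 1)
    wo = wdt + 2 * padding - dilation * (kw - 1)
    if ho <= 0 or wo <= 0:
        raise ValueError("input too small for kernel/dilation")

    if kh == 1 and kw == 1 and padding == 0:
        wmat = w.data.reshape(cout, cin)
        out = np.matmul(wmat, x.data.reshape(n, cin, h * wdt))
        out_data = out.reshape(n, cout, h, wdt)
        if b is not None:
            out_data = out_data + b.data.reshape(1, cout, 1, 1)

        def backward(g):
            gm = g.reshape(n, cout, h * wdt)
            if w.requires_grad:
                gw = np.einsum("nop,ncp->oc", gm, x.data.reshape(n, cin, h * wdt),
                               optimize=True)
                w._accumulate(gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gx = np.matmul(wmat.T, gm)
                x._accumulate(gx.reshape(x.data.shape))

        parents = (x, w) if b is None else (x, w, b)
        return _make(out_data, parents, backward)

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, dilation, ho, wo)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols)  # (n, cout, ho*wo)
    out_data = out.reshape(n, cout, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        gm = g.reshape(n, cout, ho * wo)
        if w.requires_grad:
            gw = np.einsum("nop,ncp->oc", gm, cols, optimize=True)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gm)
            gxp = _col2im(gcols, xp.shape, kh, kw, dilation, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# orthonormal Haar transform
# ---------------------------------------------------------------------------

def _haar_fwd(x: np.ndarray) -> np.ndarray:
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (c + d - a - b) * 0.5
    hl = (b + d - a - c) * 0.5
    hh = (a + d - b - c) * 0.5
    return np.concatenate([ll, lh, hl, hh], axis=-3)


def _haar_inv(s: np.ndarray) -> np.ndarray:
    c4 = s.shape[-3]
    if c4 % 4:
        raise ValueError("subband tensor must have 4k channels")
    c = c4 // 4
    ll, lh, hl, hh = (s[..., i * c:(i + 1) * c, :, :] for i in range(4))
    h2, w2 = ll.shape[-2:]
    out = np.empty(s.shape[:-3] + (c, 2 * h2, 2 * w2), dtype=s.dtype)
    out[..., 0::2, 0::2] = (ll - lh - hl + hh) * 0.5
    out[..., 0::2, 1::2] = (ll - lh + hl - hh) * 0.5
    out[..., 1::2, 0::2] = (ll + lh - hl - hh) * 0.5
    out[..., 1::2, 1::2] = (ll + lh + hl + hh) * 0.5
    return out


def haar_analysis(x: Tensor) -> Tensor:
    """Single-level orthonormal 2D Haar analysis on NCHW tensors.

    Returns an (N, 4C, H/2, W/2) tensor whose channel blocks are
    [LL, LH, HL, HH].  Orthonormality makes the adjoint equal to the inverse,
    so the backward pass is the synthesis transform.
    """
    if x.data.shape[-1] % 2 or x.data.shape[-2] % 2:
        raise ValueError("Haar analysis requires even spatial dimensions")

    def backward(g):
        x._accumulate(_haar_inv(g))

    return _make(_haar_fwd(x.data), (x,), backward)


def haar_synthesis(s: Tensor) -> Tensor:
    """Inverse of :func:`haar_analysis`."""
    def backward(g):
        s._accumulate(_haar_fwd(g))

    return _make(_haar_inv(s.data), (s,), backward)


# ---------------------------------------------------------------------------
# group normalisation
# ---------------------------------------------------------------------------

def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    n, c, h, w = x.data.shape
    if c % groups:
        raise ValueError("channels not divisible by groups")
    xg = x.data.reshape(n, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    out_data = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)
    m = xg.shape[2]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gamma.data.reshape(1, c, 1, 1)).reshape(n, groups, m)
            xh = xhat.reshape(n, groups, m)
            t1 = dxhat - dxhat.mean(axis=2, keepdims=True)
            t2 = xh * (dxhat * xh).mean(axis=2, keepdims=True)
            x._accumulate(((t1 - t2) * inv).reshape(n, c, h, w))

    return _make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimiser over a list of Parameters."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
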