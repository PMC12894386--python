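"""Reverse-mode autodiff over numpy arrays, NCHW layout.

Tensors form a DAG; calling :meth:`Tensor.backward` on a scalar output
topologically sorts the graph and accumulates gradients into every tensor
that (transitively) requires them.  Gradients are retained on intermediate
tensors as well — class-activation mapping reads them directly.

Ops are free functions so the graph-building policy lives in one place
(:func:`_make`).  Under :func:`no_grad` no closures are created, which keeps
pure inference cheap.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special

from ..errors import DimensionError, UsageError
from .haar import dwt2_raw, idwt2_raw

_GRAD_ENABLED = True
_MAC_COUNTER: Optional[dict] = None

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


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


def grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def count_macs():
    """Count multiply-accumulates of all ops run inside the block.

    Convention: conv2d counts ``N*Ho*Wo*Cout*(Cin/groups)*kh*kw``, linear
    counts ``N*in*out``, DWT/IDWT count 4 MACs per produced coefficient
    (each output is a 4-tap dot product); pooling, normalization and
    activations are not counted.
    """
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    counter = {"macs": 0}
    _MAC_COUNTER = counter
    try:
        yield counter
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER["macs"] += int(n)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- convenience ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return smul(self, float(other))
        return mul(self, other)

    def __rmul__(self, other):
        return self.__mul__(other)

    def __neg__(self):
        return smul(self, -1.0)

    def __sub__(self, other):
        return add(self, smul(_as_tensor(other), -1.0))

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise UsageError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A learnable tensor (always requires a gradient)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _acc(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = np.asarray(g, dtype=t.data.dtype)
    if t.grad is None:
        t.grad = np.array(g, copy=True)  # own the buffer
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise / shape ops ----------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        _acc(a, _unbroadcast(g * b.data, a.data.shape))
        _acc(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def smul(a: Tensor, s: float) -> Tensor:
    data = a.data * s

    def backward(g):
        _acc(a, g * s)

    return _make(data, (a,), backward)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    old = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        _acc(a, g.reshape(old))

    return _make(data, (a,), backward)


def tsum(a: Tensor) -> Tensor:
    data = np.asarray(a.data.sum(), dtype=a.data.dtype)

    def backward(g):
        _acc(a, np.broadcast_to(g, a.data.shape))

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _acc(t, g[tuple(idx)])

    return _make(data, tensors, backward)


def narrow(a: Tensor, start: int, length: int, axis: int = 1) -> Tensor:
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = a.data[idx].copy()

    def backward(g):
        gx = np.zeros_like(a.data)
        gx[idx] = g
        _acc(a, gx)

    return _make(data, (a,), backward)


def pad2d(a: Tensor, pads: tuple) -> Tensor:
    """Zero-pad the two trailing axes by (top, bottom, left, right)."""
    t, b, l, r = pads
    width = [(0, 0)] * (a.data.ndim - 2) + [(t, b), (l, r)]
    data = np.pad(a.data, width)
    h, w = a.data.shape[-2:]

    def backward(g):
        _acc(a, g[..., t : t + h, l : l + w])

    return _make(data, (a,), backward)


def crop2d(a: Tensor, pads: tuple) -> Tensor:
    """Inverse of :func:`pad2d`: drop (top, bottom, left, right) margins."""
    t, b, l, r = pads
    h, w = a.data.shape[-2:]
    sl = (..., slice(t, h - b or None), slice(l, w - r or None))
    data = a.data[sl].copy()

    def backward(g):
        gx = np.zeros_like(a.data)
        gx[sl] = g
        _acc(a, gx)

    return _make(data, (a,), backward)


# -- activations -----------------------------------------------------------


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        _acc(a, g * mask)

    return _make(data, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    # exact (erf) form; derivative is Phi(x) + x * phi(x)
    x = a.data
    phi_cdf = 0.5 * (1.0 + special.erf(x * _INV_SQRT2))
    data = x * phi_cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        _acc(a, g * (phi_cdf + x * pdf))

    return _make(data, (a,), backward)


# -- linear algebra --------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data
    _add_macs(a.data.shape[0] * a.data.shape[1] * b.data.shape[1])

    def backward(g):
        _acc(a, g @ b.data.T)
        _acc(b, a.data.T @ g)

    return _make(data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """``x (N, in) @ w.T + b`` with ``w`` of shape (out, in)."""
    data = x.data @ w.data.T
    _add_macs(x.data.shape[0] * w.data.shape[0] * w.data.shape[1])
    if b is not None:
        data = data + b.data

    def backward(g):
        _acc(x, g @ w.data)
        _acc(w, g.T @ x.data)
        if b is not None:
            _acc(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


# -- convolution and pooling ----------------------------------------------


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2D cross-correlation, NCHW.  ``w``: (Cout, Cin/groups, kh, kw).

    Supports the two cases the network uses: groups == 1 (dense) and
    groups == Cin == Cout (depthwise).
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    n, c, h, wd = x.data.shape
    co, cg, kh, kw = w.data.shape
    if c != cg * groups:
        raise DimensionError(
            f"conv2d: input has {c} channels but weight expects {cg * groups}"
        )
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    if ho <= 0 or wo <= 0:
        raise DimensionError(f"conv2d: spatial input {h}x{wd} too small for kernel")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    depthwise = groups == c and cg == 1 and co == c

    _add_macs(n * ho * wo * co * cg * kh * kw)

    if depthwise:
        wdat = w.data
        out = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
        for ki in range(kh):
            for kj in range(kw):
                out += (
                    xp[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw]
                    * wdat[None, :, 0, ki, kj, None, None]
                )
        cols = None
    elif groups == 1:
        patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        out = (cols @ w.data.reshape(co, -1).T).reshape(n, ho, wo, co)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    else:
        raise DimensionError("conv2d supports groups == 1 or depthwise groups only")

    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        if b is not None:
            _acc(b, g.sum(axis=(0, 2, 3)))
        if depthwise:
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for ki in range(kh):
                    for kj in range(kw):
                        sl = xp[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw]
                        gw[:, 0, ki, kj] = (sl * g).sum(axis=(0, 2, 3))
                _acc(w, gw)
            if x.requires_grad:
                gx = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        gx[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw] += (
                            g * w.data[None, :, 0, ki, kj, None, None]
                        )
                _acc(x, gx[:, :, ph : ph + h, pw : pw + wd])
        else:
            gflat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
            if w.requires_grad:
                _acc(w, (gflat.T @ cols).reshape(w.data.shape))
            if x.requires_grad:
                gx = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        tmp = (gflat @ w.data[:, :, ki, kj]).reshape(n, ho, wo, c)
                        gx[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw] += (
                            tmp.transpose(0, 3, 1, 2)
                        )
                _acc(x, gx[:, :, ph : ph + h, pw : pw + wd])

    parents = [x, w] + ([b] if b is not None else [])
    return _make(out, parents, backward)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    n, c, h, w = x.data.shape
    neg = np.array(-np.inf, dtype=x.data.dtype)
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=neg
    )
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    out = patches.max(axis=(-1, -2))

    def backward(g):
        if not x.requires_grad:
            return
        # ties share the gradient equally
        cnt = (patches == out[..., None, None]).sum(axis=(-1, -2))
        gn = g / cnt
        gx = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                m = patches[..., ki, kj] == out
                gx[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw] += gn * m
        _acc(x, gx[:, :, ph : ph + h, pw : pw + w])

    return _make(out, (x,), backward)


def avgpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Average pooling whose divisor counts only in-bounds cells."""
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    ones = np.pad(np.ones((h, w), dtype=x.data.dtype), ((ph, ph), (pw, pw)))
    cnt = sliding_window_view(ones, (kh, kw))[::sh, ::sw].sum(axis=(-1, -2))
    out = patches.sum(axis=(-1, -2)) / cnt

    def backward(g):
        if not x.requires_grad:
            return
        gn = g / cnt
        gx = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                gx[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw] += gn
        _acc(x, gx[:, :, ph : ph + h, pw : pw + w])

    return _make(out, (x,), backward)


# -- normalization ---------------------------------------------------------


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]
        unbiased = var * (m / (m - 1)) if m > 1 else var
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu = running_mean.astype(xd.dtype, copy=False)
        var = running_var.astype(xd.dtype, copy=False)
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * ivstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        _acc(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _acc(beta, g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        if training:
            m = xd.shape[0] * xd.shape[2] * xd.shape[3]
            dxhat = g * gamma.data[None, :, None, None]
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = ivstd[None, :, None, None] * (dxhat - s1 / m - xhat * s2 / m)
            _acc(x, dx)
        else:
            _acc(x, g * (gamma.data * ivstd)[None, :, None, None])

    return _make(out, (x, gamma, beta), backward)


# -- wavelet transform ------------------------------------------------------


def dwt2(x: Tensor) -> Tensor:
    """Differentiable Haar analysis step, (N, C, H, W) -> (N, 4C, H/2, W/2).

    The transform is orthogonal, so its adjoint (the gradient) is the
    synthesis step applied to the incoming gradient.
    """
    data = dwt2_raw(x.data)
    _add_macs(4 * data.size)

    def backward(g):
        _acc(x, idwt2_raw(g))

    return _make(data, (x,), backward)


def idwt2(s: Tensor) -> Tensor:
    """Differentiable Haar synthesis step, (N, 4C, h, w) -> (N, C, 2h, 2w)."""
    data = idwt2_raw(s.data)
    _add_macs(4 * data.size)

    def backward(g):
        _acc(s, dwt2_raw(g))

    return _make(data, (s,), backward)


# -- pooling to vector / heads ----------------------------------------------


def gap(x: Tensor) -> Tensor:
    """Global average pooling, (N, C, H, W) -> (N, C)."""
    n, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def backward(g):
        _acc(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _make(data, (x,), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    data = z - lse

    def backward(g):
        p = np.exp(data)
        _acc(x, g - p * g.sum(axis=axis, keepdims=True))

    return _make(data, (x,), backward)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax for probability outputs (no graph)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between logits (N, C) and integer labels (N,)."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    if labels.shape != (n,):
        raise DimensionError(f"labels shape {labels.shape} != ({n},)")
    m = logits.data.max(axis=1, keepdims=True)
    z = logits.data - m
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    data = np.asarray(-logp[np.arange(n), labels].mean(), dtype=logits.data.dtype)

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        _acc(logits, g * p / n)

    return _make(data, (logits,), backward)
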