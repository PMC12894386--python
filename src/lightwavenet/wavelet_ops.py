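"""2D Haar wavelet transform and the wavelet-transform convolution (WTConv).

The orthonormal Haar filter bank (2x2 filters with coefficients +-0.5)
splits a feature map into a low-frequency approximation (LL) and three
high-frequency detail subbands (LH, HL, HH), each at half resolution.
Because the filters are orthonormal the transform conserves energy and is
exactly invertible.

WTConv enlarges the receptive field of a depthwise convolution cheaply:
the input is recursively decomposed for ``l`` levels, a small depthwise
convolution (with bias) is applied to the four stacked subbands of every
level, each level's response is rescaled per channel, and the results are
folded back through the inverse transform and added to a plain depthwise
convolution of the input.  A k x k kernel at level ``i`` then acts on a
``2^i``-times coarser grid, i.e. over a ``2^i * k`` spatial extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from . import _engine as E
from ._engine.haar import dwt2_raw, idwt2_raw
from .errors import ConfigError, DimensionError

__all__ = [
    "SubbandSet",
    "WaveletPyramid",
    "WtConvWeights",
    "WTConv2d",
    "haar_dwt2",
    "haar_idwt2",
    "wtconv2d",
]


@dataclass
class SubbandSet:
    """The four Haar subbands of one decomposition level.

    Each array is ``C x H/2 x W/2``.  ``lh`` responds to vertical edges
    (horizontal detail filter) and ``hl`` to horizontal edges.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def __post_init__(self):
        shapes = {a.shape for a in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise DimensionError(f"subbands must share one shape, got {sorted(shapes)}")

    @property
    def shape(self):
        return self.ll.shape

    def stack(self) -> np.ndarray:
        """Stack as ``4C x H/2 x W/2`` in [LL, LH, HL, HH] order."""
        return np.concatenate([self.ll, self.lh, self.hl, self.hh], axis=0)

    def energy(self) -> float:
        return float(sum(np.sum(np.square(a)) for a in (self.ll, self.lh, self.hl, self.hh)))


@dataclass
class WaveletPyramid:
    """Ordered subband sets; level ``i+1`` decomposes level ``i``'s LL map."""

    levels: List[SubbandSet]

    @classmethod
    def decompose(cls, x: np.ndarray, depth: int) -> "WaveletPyramid":
        if depth < 1:
            raise ConfigError(f"decomposition depth must be >= 1, got {depth}")
        levels = []
        current = x
        for _ in range(depth):
            s = haar_dwt2(current)
            levels.append(s)
            current = s.ll
        return cls(levels)


def haar_dwt2(x: np.ndarray) -> SubbandSet:
    """One orthonormal Haar analysis step on a ``C x H x W`` map.

    H and W must be even; each subband comes out as ``C x H/2 x W/2``.
    A constant map of value ``c`` yields an LL map of value ``2c`` and
    zero detail subbands.
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise DimensionError(f"expected a C x H x W map, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    stacked = dwt2_raw(x)  # (4C, H/2, W/2); raises DimensionError on odd sides
    c = x.shape[0]
    return SubbandSet(*(stacked[i * c : (i + 1) * c] for i in range(4)))


def haar_idwt2(s: SubbandSet) -> np.ndarray:
    """Exact inverse of :func:`haar_dwt2` (doubles both spatial sides)."""
    return idwt2_raw(s.stack())


@dataclass
class WtConvWeights:
    """Explicit weight container for the functional :func:`wtconv2d`.

    ``base_kernel``: depthwise ``C x k x k`` kernel applied in the spatial
    domain.  Per level: a depthwise ``4C x k x k`` kernel over the stacked
    subbands, a ``4C`` bias, and a ``4C`` per-channel fusion scale applied
    to the convolved subbands before reconstruction.
    """

    base_kernel: np.ndarray
    subband_kernels: Sequence[np.ndarray]
    subband_bias: Sequence[np.ndarray]
    channel_scales: Sequence[np.ndarray]

    def __post_init__(self):
        k = self.base_kernel.shape[-1]
        if k % 2 == 0:
            raise ConfigError(f"kernel size must be odd, got {k}")
        c = self.base_kernel.shape[0]
        if self.base_kernel.shape != (c, k, k):
            raise DimensionError("base_kernel must be C x k x k (one kernel per channel)")
        n = len(self.subband_kernels)
        if not (len(self.subband_bias) == len(self.channel_scales) == n):
            raise ConfigError("per-level weight lists must have equal length")
        for w, b, s in zip(self.subband_kernels, self.subband_bias, self.channel_scales):
            if w.shape != (4 * c, k, k):
                raise DimensionError("each subband kernel must be 4C x k x k")
            if b.shape != (4 * c,) or s.shape != (4 * c,):
                raise DimensionError("bias and scales must have 4C entries")

    @property
    def levels(self) -> int:
        return len(self.subband_kernels)

    @property
    def channels(self) -> int:
        return int(self.base_kernel.shape[0])

    @property
    def kernel_size(self) -> int:
        return int(self.base_kernel.shape[-1])


class WTConv2d(E.Module):
    """Depthwise wavelet-transform convolution preserving the input shape.

    Forward = depthwise base convolution of the input, plus the recursive
    branch: decompose the running LL per level, convolve the four stacked
    subbands depthwise (with bias), rescale per channel, and reconstruct
    bottom-up with the inverse transform.  Odd spatial sides are zero-padded
    to even before each analysis step and cropped after synthesis.
    """

    def __init__(
        self,
        channels: int,
        kernel_size: int = 5,
        levels: int = 1,
        *,
        rng: np.random.Generator,
    ):
        super().__init__()
        if levels < 1:
            raise ConfigError(f"wavelet level count must be >= 1, got {levels}")
        if kernel_size % 2 == 0:
            raise ConfigError(f"kernel size must be odd, got {kernel_size}")
        self.channels = channels
        self.kernel_size = kernel_size
        self.levels = levels
        pad = kernel_size // 2
        self.base = E.Conv2d(
            channels, channels, kernel_size, padding=pad, groups=channels, bias=False, rng=rng
        )
        self.subband_convs = E.ModuleList(
            [
                E.Conv2d(
                    4 * channels,
                    4 * channels,
                    kernel_size,
                    padding=pad,
                    groups=4 * channels,
                    bias=True,
                    rng=rng,
                )
                for _ in range(levels)
            ]
        )
        self.scales = E.ParameterList(
            [E.Parameter(np.ones(4 * channels, dtype=np.float32)) for _ in range(levels)]
        )

    def load_weights(self, w: WtConvWeights) -> None:
        if w.channels != self.channels or w.kernel_size != self.kernel_size:
            raise ConfigError("weight container does not match this operator")
        if w.levels != self.levels:
            raise ConfigError(f"expected {self.levels} levels of weights, got {w.levels}")
        self.base.weight.data = np.asarray(w.base_kernel, dtype=np.float32)[:, None]
        for conv, kw, b in zip(self.subband_convs, w.subband_kernels, w.subband_bias):
            conv.weight.data = np.asarray(kw, dtype=np.float32)[:, None]
            conv.bias.data = np.asarray(b, dtype=np.float32)
        for p, s in zip(self.scales, w.channel_scales):
            p.data = np.asarray(s, dtype=np.float32)

    def forward(self, x: E.Tensor) -> E.Tensor:
        c = self.channels
        base = self.base(x)
        convolved = []  # (scaled subband tensor, (pad_bottom, pad_right)) per level
        current = x
        for i in range(self.levels):
            h, w = current.shape[2], current.shape[3]
            if h < 2 or w < 2:
                raise DimensionError(
                    f"spatial size {h}x{w} cannot be decomposed at level {i + 1}"
                )
            pb, pr = h % 2, w % 2
            if pb or pr:
                current = E.pad2d(current, (0, pb, 0, pr))
            sub = E.dwt2(current)
            y = self.subband_convs[i](sub)
            scale = E.reshape(self.scales[i], (1, 4 * c, 1, 1))
            y = E.mul(y, scale)
            convolved.append((y, (pb, pr)))
            current = E.narrow(sub, 0, c)  # raw LL feeds the next level

        rec = None
        for y, (pb, pr) in reversed(convolved):
            if rec is not None:
                ll = E.add(E.narrow(y, 0, c), rec)
                y = E.concat([ll, E.narrow(y, c, 3 * c)], axis=1)
            up = E.idwt2(y)
            if pb or pr:
                up = E.crop2d(up, (0, pb, 0, pr))
            rec = up
        return E.add(base, rec)


def wtconv2d(x: np.ndarray, weights: WtConvWeights, levels: int | None = None) -> np.ndarray:
    """Functional WTConv on a ``C x H x W`` array with explicit weights.

    ``levels`` defaults to the number of per-level weight sets; when given
    it must agree with them.  Output shape equals input shape.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise DimensionError(f"expected a C x H x W map, got ndim={x.ndim}")
    if levels is None:
        levels = weights.levels
    if levels < 1:
        raise ConfigError(f"wavelet level count must be >= 1, got {levels}")
    if levels != weights.levels:
        raise ConfigError(
            f"levels={levels} but weight container holds {weights.levels} level(s)"
        )
    op = WTConv2d(
        weights.channels,
        weights.kernel_size,
        levels,
        rng=np.random.default_rng(0),
    )
    op.load_weights(weights)
    op.eval()
    with E.no_grad():
        out = op(E.Tensor(x[None]))
    return out.data[0]
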