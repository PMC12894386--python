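"""Straight-line loop oracles, written independently of the vectorized code.

Everything here works on small 2D arrays with explicit Python loops so it
can be read and checked by hand; the tests compare the package's vectorized
implementations against these.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def dwt_block(x: np.ndarray):
    """Orthonormal Haar analysis of one 2D array via per-patch dot products."""
    h, w = x.shape
    ll = np.zeros((h // 2, w // 2))
    lh = np.zeros_like(ll)
    hl = np.zeros_like(ll)
    hh = np.zeros_like(ll)
    for i in range(h // 2):
        for j in range(w // 2):
            a, b = x[2 * i, 2 * j], x[2 * i, 2 * j + 1]
            c, d = x[2 * i + 1, 2 * j], x[2 * i + 1, 2 * j + 1]
            ll[i, j] = 0.5 * (a + b + c + d)
            lh[i, j] = 0.5 * (a - b + c - d)
            hl[i, j] = 0.5 * (a + b - c - d)
            hh[i, j] = 0.5 * (a - b - c + d)
    return ll, lh, hl, hh


def idwt_block(ll, lh, hl, hh):
    h, w = ll.shape
    out = np.zeros((2 * h, 2 * w))
    for i in range(h):
        for j in range(w):
            out[2 * i, 2 * j] = 0.5 * (ll[i, j] + lh[i, j] + hl[i, j] + hh[i, j])
            out[2 * i, 2 * j + 1] = 0.5 * (ll[i, j] - lh[i, j] + hl[i, j] - hh[i, j])
            out[2 * i + 1, 2 * j] = 0.5 * (ll[i, j] + lh[i, j] - hl[i, j] - hh[i, j])
            out[2 * i + 1, 2 * j + 1] = 0.5 * (ll[i, j] - lh[i, j] - hl[i, j] + hh[i, j])
    return out


def conv_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same' 2D cross-correlation by explicit loops with zero padding."""
    k = kernel.shape[0]
    p = k // 2
    h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for ki in range(k):
                for kj in range(k):
                    ii, jj = i + ki - p, j + kj - p
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += x[ii, jj] * kernel[ki, kj]
            out[i, j] = acc
    return out


def wtconv_oracle(x: np.ndarray, weights) -> np.ndarray:
    """Single-channel wavelet-convolution by explicit composition.

    ``x`` is 1 x H x W; ``weights`` is a WtConvWeights for one channel.
    Forms the wavelet pyramid of the raw LL chain, convolves each level's
    four subbands depthwise (bias, then per-band scale), adds the deeper
    reconstruction into the LL band, and inverts level by level.
    """
    levels = len(weights.subband_kernels)
    plane = x[0].astype(float)

    def recurse(arr: np.ndarray, level: int) -> np.ndarray:
        pb, pr = arr.shape[0] % 2, arr.shape[1] % 2
        if pb or pr:
            arr = np.pad(arr, ((0, pb), (0, pr)))
        ll, lh, hl, hh = dwt_block(arr)
        bands = [ll, lh, hl, hh]
        conv = []
        for band_idx, band in enumerate(bands):
            kern = weights.subband_kernels[level][band_idx]
            bias = weights.subband_bias[level][band_idx]
            scale = weights.channel_scales[level][band_idx]
            conv.append((conv_same(band, kern) + bias) * scale)
        if level + 1 < levels:
            conv[0] = conv[0] + recurse(ll, level + 1)
        rec = idwt_block(*conv)
        h, w = rec.shape
        return rec[: h - pb if pb else h, : w - pr if pr else w]

    base = conv_same(plane, weights.base_kernel[0])
    return (base + recurse(plane, 0))[None]


def mcnemar_exact_oracle(b: int, c: int) -> float:
    """Two-sided exact binomial p-value by full enumeration over k = 0..b+c.

    Under the symmetric null each discordant pair is a fair coin; the
    p-value sums the probability of every outcome at most as likely as the
    observed one.  Exact rational arithmetic, no statistics library.
    """
    n = b + c
    if n == 0:
        return 1.0
    probs = [Fraction(comb(n, k), 2**n) for k in range(n + 1)]
    observed = probs[b]
    p = sum(pk for pk in probs if pk <= observed)
    return float(min(1, p))
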