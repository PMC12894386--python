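"""Raw (non-differentiable) 2D Haar analysis/synthesis on numpy arrays.

The orthonormal convention is used throughout: every 2x2 filter has
coefficients +-0.5, so the transform is an orthogonal map — it conserves
energy and its inverse equals its transpose.  Subband order along the
channel axis is [LL, LH, HL, HH] where, for a 2x2 patch [[a, b], [c, d]]:

    ll = (a + b + c + d) / 2      approximation
    lh = (a - b + c - d) / 2      vertical-edge response (horizontal detail)
    hl = (a + b - c - d) / 2      horizontal-edge response (vertical detail)
    hh = (a - b - c + d) / 2      diagonal detail
"""

from __future__ import annotations

import numpy as np

from ..errors import DimensionError


def _check_even(h: int, w: int) -> None:
    if h % 2:
        raise DimensionError(f"height must be even for a Haar analysis step, got {h}")
    if w % 2:
        raise DimensionError(f"width must be even for a Haar analysis step, got {w}")


def dwt2_raw(x: np.ndarray) -> np.ndarray:
    """One Haar analysis step on the trailing two axes.

    ``(..., C, H, W) -> (..., 4C, H/2, W/2)`` with subbands stacked along
    the channel axis in [LL, LH, HL, HH] order.
    """
    h, w = x.shape[-2], x.shape[-1]
    _check_even(h, w)
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5
    hl = (a + b - c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    return np.concatenate([ll, lh, hl, hh], axis=-3)


def idwt2_raw(s: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dwt2_raw`: ``(..., 4C, h, w) -> (..., C, 2h, 2w)``."""
    c4 = s.shape[-3]
    if c4 % 4:
        raise DimensionError(
            f"subband axis must hold 4 stacked subbands per channel, got {c4}"
        )
    c = c4 // 4
    ll, lh, hl, hh = (s[..., i * c : (i + 1) * c, :, :] for i in range(4))
    a = (ll + lh + hl + hh) * 0.5
    b = (ll - lh + hl - hh) * 0.5
    cc = (ll + lh - hl - hh) * 0.5
    d = (ll - lh - hl + hh) * 0.5
    out_shape = s.shape[:-3] + (c, s.shape[-2] * 2, s.shape[-1] * 2)
    out = np.empty(out_shape, dtype=s.dtype)
    out[..., 0::2, 0::2] = a
    out[..., 0::2, 1::2] = b
    out[..., 1::2, 0::2] = cc
    out[..., 1::2, 1::2] = d
    return out
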