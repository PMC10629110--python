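"""Fused depth-wise convolution kernels.

The straightforward vectorised implementation touches the whole array
once per kernel tap, so a k-tap strip convolution moves k full copies
through memory.  These numba kernels fuse the tap loop per output pixel,
reading the input once.  If numba is unavailable the callers fall back
to the tap-loop numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True, fastmath=True)
def dw_forward(xp, w, stride, ho, wo):
    """xp (n,c,hp,wp) padded input, w (c,kh,kw) -> out (n,c,ho,wo)."""
    n, c = xp.shape[0], xp.shape[1]
    kh, kw = w.shape[1], w.shape[2]
    out = np.zeros((n, c, ho, wo), dtype=xp.dtype)
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ki in range(kh):
                        xi = i * stride + ki
                        for kj in range(kw):
                            acc += w[ci, ki, kj] * xp[ni, ci, xi, j * stride + kj]
                    out[ni, ci, i, j] = acc
    return out


@njit(cache=True, fastmath=True)
def dw_input_grad(g, w, stride, hp, wp):
    """g (n,c,ho,wo), w (c,kh,kw) -> dxp (n,c,hp,wp) (padded-input grad)."""
    n, c, ho, wo = g.shape
    kh, kw = w.shape[1], w.shape[2]
    dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    gv = g[ni, ci, i, j]
                    for ki in range(kh):
                        xi = i * stride + ki
                        for kj in range(kw):
                            dxp[ni, ci, xi, j * stride + kj] += gv * w[ci, ki, kj]
    return dxp


@njit(cache=True, fastmath=True)
def dw_weight_grad(xp, g, stride, kh, kw):
    """xp (n,c,hp,wp), g (n,c,ho,wo) -> dw (c,kh,kw)."""
    n, c, ho, wo = g.shape
    dw = np.zeros((c, kh, kw), dtype=g.dtype)
    for ni in range(n):
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    acc = 0.0
                    for i in range(ho):
                        xi = i * stride + ki
                        for j in range(wo):
                            acc += xp[ni, ci, xi, j * stride + kj] * g[ni, ci, i, j]
                    dw[ci, ki, kj] += acc
    return dw
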