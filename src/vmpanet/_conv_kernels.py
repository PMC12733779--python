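"""Numba kernels for depthwise 2-D convolution (forward and backward)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def dw_conv_fwd(xp, w, out, stride):
    N, C, Ho, Wo = out.shape
    kh, kw = w.shape[1], w.shape[2]
    for n in range(N):
        for c in range(C):
            for ho in range(Ho):
                hi = ho * stride
                for wo in range(Wo):
                    wi = wo * stride
                    acc = 0.0
                    for i in range(kh):
                        for j in range(kw):
                            acc += w[c, i, j] * xp[n, c, hi + i, wi + j]
                    out[n, c, ho, wo] = acc


@njit(cache=True)
def dw_conv_bwd(xp, w, gy, gxp, gw, stride):
    """Accumulates input grad (on the padded image) and weight grad."""
    N, C, Ho, Wo = gy.shape
    kh, kw = w.shape[1], w.shape[2]
    for n in range(N):
        for c in range(C):
            for ho in range(Ho):
                hi = ho * stride
                for wo in range(Wo):
                    wi = wo * stride
                    g = gy[n, c, ho, wo]
                    for i in range(kh):
                        for j in range(kw):
                            gxp[n, c, hi + i, wi + j] += w[c, i, j] * g
                            gw[c, i, j] += xp[n, c, hi + i, wi + j] * g
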