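"""Cross-attention fusion (CAF) of deep decoder and same-stage encoder features.

The twice-coarser decoder output is upsampled and projected to the query Q;
the encoder feature is projected to the key K (both C×N token matrices with
N = H·W).  A single-head channel-affinity attention (C×C, hence linear in N)
is applied twice — once with V = Q (semantic guidance) and once with V the
flattened encoder feature (texture detail) — and the summed result goes
through a pointwise convolution with a ReLU.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, Module, upsample2x


def scaled_attention(Q: Tensor, K: Tensor, V: Tensor, tau: float) -> Tensor:
    """Row-stochastic attention over the channel axis.

    Q, K, V are (batch, C, N); the affinity Q·Kᵀ is C×C, softmax is taken
    along each row, and the output is weights·V.  Every softmax row sums
    to one.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    affinity = ag.matmul(Q, ag.transpose(K, (0, 2, 1)))
    if not np.all(np.isfinite(affinity.data)):
        raise FloatingPointError("non-finite attention affinities")
    inv_tau = np.asarray(1.0 / tau, dtype=Q.dtype)
    weights = ag.softmax(affinity * Tensor(inv_tau), axis=-1)
    return ag.matmul(weights, V)


class CAF(Module):
    def __init__(self, ch, ch_deep, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.ch, self.ch_deep = ch, ch_deep
        self.q_proj = Conv2d(ch_deep, ch, 1, rng=rng, dtype=dtype)
        self.q_bn = BatchNorm2d(ch, dtype=dtype)
        self.k_proj = Conv2d(ch, ch, 1, rng=rng, dtype=dtype)
        self.k_bn = BatchNorm2d(ch, dtype=dtype)
        self.out = Conv2d(ch, ch, 1, rng=rng, dtype=dtype)

    def project_qk(self, f_m_next: Tensor, f_pt: Tensor):
        n, c, h, w = f_pt.shape
        nh, nc, hh, ww = f_m_next.shape
        if (hh * 2, ww * 2) != (h, w):
            raise ValueError(f"decoder feature {hh}x{ww} is not exactly half of {h}x{w}")
        Q = self.q_bn(self.q_proj(upsample2x(f_m_next)))
        K = self.k_bn(self.k_proj(f_pt))
        Q = ag.reshape(Q, (n, c, h * w))
        K = ag.reshape(K, (n, c, h * w))
        tau = float(np.sqrt(h * w))  # d_k is the token length N
        return Q, K, tau

    def forward(self, f_m_next: Tensor, f_pt: Tensor) -> Tensor:
        n, c, h, w = f_pt.shape
        Q, K, tau = self.project_qk(f_m_next, f_pt)
        V2 = ag.reshape(f_pt, (n, c, h * w))
        f_a = scaled_attention(Q, K, Q, tau) + scaled_attention(Q, K, V2, tau)
        return ag.relu(self.out(ag.reshape(f_a, (n, c, h, w))))

    def flops(self, h, w):
        N = h * w
        c = self.ch
        f = self.q_proj.flops(h, w) + self.k_proj.flops(h, w) + self.out.flops(h, w)
        f += c * c * N          # affinity Q·Kᵀ (shared by both branches)
        f += 2 * c * c * N      # weights·V for the two value branches
        return f
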