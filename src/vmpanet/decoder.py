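"""Context-enhanced decoder stages (MCA) with the EASC gate chain.

A stage runs a vision-Mamba pre-pass, four parallel depthwise-separable
convolutions at kernel sizes 3/5/7/9 (each reduced to a quarter of the
channels and re-concatenated), a 3x3 context-embedding step, and then the
EASC chain: edge enhancement (difference against a local average), spatial
attention (7 -> 3 -> 1 kernel schedule) and channel attention (adaptive max
pool squeeze), each acting as sigmoid-gate · x + x, closed by a residual
skip from the Mamba pre-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, Module
from .ss2d import VisionMambaBlock


@dataclass
class McaConfig:
    channels: int
    branch_kernels: tuple = (3, 5, 7, 9)
    eta: str = "relu"             # activation before the spatial gate sigmoid
    ca_hidden: int | None = None  # hidden width of the channel-gate MLP
    use_ee: bool = True
    use_sa: bool = True
    use_ca: bool = True
    ss2d: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.channels % 4:
            raise ValueError(f"channels ({self.channels}) must be divisible by 4")


def _eta(name: str, x: Tensor) -> Tensor:
    if name == "relu":
        return ag.relu(x)
    if name == "identity":
        return x
    raise ValueError(f"unknown eta activation '{name}'")


class MultiScaleDWConv(Module):
    """Four parallel depthwise convs (3/5/7/9) each followed by a pointwise
    conv to C/4 channels; the branches are concatenated back to C."""

    def __init__(self, cfg: McaConfig, rng, dtype=np.float32):
        super().__init__()
        c = cfg.channels
        self.branches = len(cfg.branch_kernels)
        for i, k in enumerate(cfg.branch_kernels):
            setattr(self, f"dw{i}", Conv2d(c, c, k, groups=c, rng=rng, dtype=dtype))
            setattr(self, f"pw{i}", Conv2d(c, c // 4, 1, rng=rng, dtype=dtype))

    def forward(self, x):
        outs = [getattr(self, f"pw{i}")(getattr(self, f"dw{i}")(x))
                for i in range(self.branches)]
        return ag.concat(outs, axis=1)

    def flops(self, h, w):
        return sum(getattr(self, f"dw{i}").flops(h, w) + getattr(self, f"pw{i}").flops(h, w)
                   for i in range(self.branches))


class ContextEmbed(Module):
    """BN(1x1(DWConv3x3(x))) — shape-preserving contextual mixing."""

    def __init__(self, ch, rng, dtype=np.float32):
        super().__init__()
        self.dw = Conv2d(ch, ch, 3, groups=ch, rng=rng, dtype=dtype)
        self.pw = Conv2d(ch, ch, 1, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(ch, dtype=dtype)

    def forward(self, x):
        return self.bn(self.pw(self.dw(x)))

    def flops(self, h, w):
        return self.dw.flops(h, w) + self.pw.flops(h, w)


class EdgeEnhance(Module):
    """x̄ = BN(x − AvgPool3x3(DWConv7x7(x))); out = sigmoid(1x1(x̄)) ⊙ x + x.

    The local-average subtraction isolates high-frequency edge structure;
    the single-channel sigmoid score reweights it multiplicatively with an
    identity residual, so zero input maps to zero and positive input x
    satisfies x < out < 2x elementwise.
    """

    def __init__(self, ch, rng, dtype=np.float32):
        super().__init__()
        self.dw = Conv2d(ch, ch, 7, groups=ch, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(ch, dtype=dtype)
        self.score = Conv2d(ch, 1, 1, rng=rng, dtype=dtype)

    def gate(self, x):
        xbar = self.bn(x - ag.avg_pool2d(self.dw(x), 3, 1, 1))
        return ag.sigmoid(self.score(xbar))

    def forward(self, x):
        return self.gate(x) * x + x

    def flops(self, h, w):
        return self.dw.flops(h, w) + self.score.flops(h, w)


class SpatialAttention(Module):
    """Kernel schedule 7 -> 3 -> 1: two BN'd depthwise convs then a pointwise
    projection to a single-channel saliency score in (0,1)."""

    def __init__(self, ch, eta, rng, dtype=np.float32):
        super().__init__()
        self.eta = eta
        self.dw7 = Conv2d(ch, ch, 7, groups=ch, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(ch, dtype=dtype)
        self.dw3 = Conv2d(ch, ch, 3, groups=ch, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(ch, dtype=dtype)
        self.score = Conv2d(ch, 1, 1, rng=rng, dtype=dtype)

    def gate(self, x):
        s1 = self.bn1(self.dw7(x))
        s2 = self.bn2(self.dw3(s1))
        return ag.sigmoid(_eta(self.eta, self.score(s2)))

    def forward(self, x):
        return self.gate(x) * x + x

    def flops(self, h, w):
        return self.dw7.flops(h, w) + self.dw3.flops(h, w) + self.score.flops(h, w)


class ChannelAttention(Module):
    """Squeeze (adaptive max pool to 1x1) -> ReLU'd pointwise -> sigmoid
    pointwise, giving a per-channel C×1×1 gate broadcast spatially."""

    def __init__(self, ch, hidden, rng, dtype=np.float32):
        super().__init__()
        hidden = hidden or ch
        self.fc1 = Conv2d(ch, hidden, 1, rng=rng, dtype=dtype)
        self.fc2 = Conv2d(hidden, ch, 1, rng=rng, dtype=dtype)

    def gate(self, x):
        wv = ag.relu(self.fc1(ag.global_max_pool2d(x)))
        return ag.sigmoid(self.fc2(wv))

    def forward(self, x):
        return self.gate(x) * x + x

    def flops(self, h, w):
        # the squeeze-excite MLP acts on a 1x1 footprint
        return self.fc1.flops(1, 1) + self.fc2.flops(1, 1)


class MCAStage(Module):
    def __init__(self, cfg: McaConfig, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c = cfg.channels
        self.mamba = VisionMambaBlock(c, v1=1.0, v2=1.0, rng=rng, dtype=dtype, **cfg.ss2d)
        self.multiscale = MultiScaleDWConv(cfg, rng, dtype)
        self.embed = ContextEmbed(c, rng, dtype)
        if cfg.use_ee:
            self.ee = EdgeEnhance(c, rng, dtype)
        if cfg.use_sa:
            self.sa = SpatialAttention(c, cfg.eta, rng, dtype)
        if cfg.use_ca:
            self.ca = ChannelAttention(c, cfg.ca_hidden, rng, dtype)

    def easc(self, x: Tensor) -> Tensor:
        if self.cfg.use_ee:
            x = self.ee(x)
        if self.cfg.use_sa:
            x = self.sa(x)
        if self.cfg.use_ca:
            x = self.ca(x)
        return x

    def forward(self, f_in: Tensor) -> Tensor:
        f_vmt = self.mamba(f_in)
        f_cf = self.multiscale(f_vmt)
        f_hat = self.embed(f_cf)
        return self.easc(f_hat) + f_vmt

    def flops(self, h, w):
        f = self.mamba.flops(h, w) + self.multiscale.flops(h, w) + self.embed.flops(h, w)
        if self.cfg.use_ee:
            f += self.ee.flops(h, w)
        if self.cfg.use_sa:
            f += self.sa.flops(h, w)
        if self.cfg.use_ca:
            f += self.ca.flops(h, w)
        return f
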