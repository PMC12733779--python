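"""Context-prompt encoder stages (PCM).

Each stage runs an inverted-pyramid convolution (large kernel, stride for
downsampling, then a small kernel, then pointwise aggregation), blends the
convolutional feature with a vision-Mamba global path, distils two
single-channel sigmoid prompt masks — p1 from the local path, p2 from the
global path — and adds them back onto the fused feature as additive cues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, MapNorm, Module
from .ss2d import VisionMambaBlock


@dataclass
class PcmConfig:
    in_channels: int
    out_channels: int
    stride: int = 2
    large_kernel: int = 7
    small_kernel: int = 3
    lambda1: float = 0.5          # weight of the global (Mamba) path
    lambda2: float = 0.5          # weight of the local (conv) path
    prompt_lambda1: float = 1.0   # weight of p1 in the prompt fusion
    prompt_lambda2: float = 1.0   # weight of p2
    use_mamba: bool = True
    use_prompts: bool = True
    ss2d: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.large_kernel % 2 == 0 or self.small_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd for symmetric padding")
        if not (0.0 <= self.lambda1 <= 1.0 and 0.0 < self.lambda2 <= 1.0):
            raise ValueError("lambda weights must lie in (0, 1] (lambda1 may be 0 for ablation)")


class InvertedPyramidConv(Module):
    """Coarse-to-fine convolution: depthwise large kernel (with the stage
    stride) -> full small kernel -> pointwise aggregation, each followed by
    batch norm, with ReLU between stages."""

    def __init__(self, cfg: PcmConfig, rng, dtype=np.float32):
        super().__init__()
        cin, cout = cfg.in_channels, cfg.out_channels
        self.large = Conv2d(cin, cin, cfg.large_kernel, stride=cfg.stride,
                            groups=cin, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cin, dtype=dtype)
        self.small = Conv2d(cin, cout, cfg.small_kernel, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.point = Conv2d(cout, cout, 1, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(cout, dtype=dtype)

    def forward(self, x):
        x = ag.relu(self.bn1(self.large(x)))
        x = ag.relu(self.bn2(self.small(x)))
        return self.bn3(self.point(x))

    def flops(self, h, w):
        f = self.large.flops(h, w)
        ho, wo = self.large.out_hw(h, w)
        f += self.small.flops(ho, wo) + self.point.flops(ho, wo)
        return f


class PromptHead(Module):
    """Many-to-one channel mapping: learnable 1x1 projection to a single
    channel, normalisation (BN for the local path, LN over the map's spatial
    extent for the global path — channel LN would be degenerate on one
    channel), then a sigmoid — the output is a (0,1) prompt mask."""

    def __init__(self, ch, norm: str, rng, dtype=np.float32):
        super().__init__()
        self.proj = Conv2d(ch, 1, 1, rng=rng, dtype=dtype)
        self.norm = BatchNorm2d(1, dtype=dtype) if norm == "bn" else MapNorm(1, dtype=dtype)

    def forward(self, x):
        return ag.sigmoid(self.norm(self.proj(x)))

    def flops(self, h, w):
        return self.proj.flops(h, w)


class PCMStage(Module):
    def __init__(self, cfg: PcmConfig, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        cout = cfg.out_channels
        self.ipc = InvertedPyramidConv(cfg, rng, dtype)
        if cfg.use_mamba:
            # the lambda blend lives in the fuse step, so the block here
            # computes the bare Mamba path
            self.mamba = VisionMambaBlock(cout, v1=1.0, v2=0.0, rng=rng,
                                          dtype=dtype, **cfg.ss2d)
        self.fuse = Conv2d(cout, cout, 1, rng=rng, dtype=dtype)
        if cfg.use_prompts:
            self.prompt1 = PromptHead(cout, "bn", rng, dtype)
            self.prompt2 = PromptHead(cout, "ln", rng, dtype)

    # -- the four stage operations, exposed for oracle tests ------------
    def inverted_pyramid_conv(self, x: Tensor) -> Tensor:
        return self.ipc(x)

    def fuse_global_local(self, f_ipc: Tensor):
        """f_m = VisionMamba(f_ipc); f_et = 1x1(λ1·f_m + λ2·f_ipc)."""
        cfg = self.cfg
        if cfg.use_mamba and cfg.lambda1 != 0.0:
            f_m = self.mamba.mamba_path(f_ipc)
            f_et = self.fuse(cfg.lambda1 * f_m + cfg.lambda2 * f_ipc)
        else:
            f_m = f_ipc
            f_et = self.fuse(cfg.lambda2 * f_ipc)
        return f_m, f_et

    def make_prompts(self, f_ipc: Tensor, f_m: Tensor):
        return self.prompt1(f_ipc), self.prompt2(f_m)

    def apply_prompts(self, f_et: Tensor, p1: Tensor, p2: Tensor) -> Tensor:
        if p1.shape[2:] != f_et.shape[2:]:
            raise ValueError(f"prompt spatial dims {p1.shape[2:]} != feature {f_et.shape[2:]}")
        return f_et + self.cfg.prompt_lambda1 * p1 + self.cfg.prompt_lambda2 * p2

    def forward(self, x: Tensor) -> Tensor:
        f_ipc = self.inverted_pyramid_conv(x)
        f_m, f_et = self.fuse_global_local(f_ipc)
        if self.cfg.use_prompts:
            p1, p2 = self.make_prompts(f_ipc, f_m)
            return self.apply_prompts(f_et, p1, p2)
        return f_et

    def flops(self, h, w):
        f = self.ipc.flops(h, w)
        ho, wo = self.ipc.large.out_hw(h, w)
        if self.cfg.use_mamba and self.cfg.lambda1 != 0.0:
            f += self.mamba.flops(ho, wo)
        f += self.fuse.flops(ho, wo)
        if self.cfg.use_prompts:
            f += self.prompt1.flops(ho, wo) + self.prompt2.flops(ho, wo)
        return f

    def out_hw(self, h, w):
        return self.ipc.large.out_hw(h, w)
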