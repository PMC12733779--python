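"""Full network assembly: 5 encoder stages, 5 decoder stages, 4 cross-attention
fusions, and per-stage segmentation heads with deep supervision.

The stage schedule is C_i = 8·i channels at spatial size S/2^{i-1} for a
square input of side S (the reference configuration uses S = 256, giving
(8,256,256) … (40,16,16)).  The decoder runs deepest-first: stage 5 consumes
the deepest encoder output directly; stages 4..1 fuse the deeper decoder
output with the same-stage encoder output through CAF before their MCA pass.
Every stage head emits a one-channel logit map, bilinearly upsampled to the
input size; the stage-1 head provides the final probability map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .caf import CAF
from .decoder import MCAStage, McaConfig
from .encoder import PCMStage, PcmConfig
from .nn import BilinearResize, Conv2d, Module


def _default_enc_ss2d():
    # free scan hyperparameters, calibrated once against the published
    # parameter/FLOP budget and then frozen (see docs/methods.md)
    return [
        dict(d_state=1, dt_rank=3, expand=1.0, conv_branch=True, gate=False),
        dict(d_state=2, dt_rank=4, expand=1.0, conv_branch=True, gate=False),
        dict(d_state=5, dt_rank=3, expand=1.0, conv_branch=True, gate=False),
        dict(d_state=16, dt_rank=31, expand=2.0, conv_branch=True, gate=False),
        dict(d_state=32, dt_rank=32, expand=2.0, conv_branch=True, gate=False),
    ]


def _default_dec_ss2d():
    return [
        dict(d_state=2, dt_rank=3, expand=1.0, conv_branch=True, gate=False),
        dict(d_state=4, dt_rank=8, expand=1.0, conv_branch=True, gate=False),
        dict(d_state=9, dt_rank=16, expand=2.0, conv_branch=True, gate=False),
        dict(d_state=34, dt_rank=36, expand=2.0, conv_branch=True, gate=False),
        dict(d_state=66, dt_rank=67, expand=2.0, conv_branch=True, gate=False),
    ]


@dataclass
class ModelConfig:
    in_channels: int = 3
    stage_channels: tuple = (8, 16, 24, 32, 40)
    large_kernel: int = 7
    small_kernel: int = 3
    lambda1: float = 0.5
    lambda2: float = 0.5
    prompt_lambda1: float = 1.0
    prompt_lambda2: float = 1.0
    eta: str = "relu"
    enc_ss2d: list = field(default_factory=_default_enc_ss2d)
    dec_ss2d: list = field(default_factory=_default_dec_ss2d)
    head_hidden: tuple = (5, 4, 10, 18, 91)
    ca_hidden: tuple | None = (16, 30, 22, 64, 34)  # per-stage channel-gate widths
    # ablation switches
    use_mamba_in_pcm: bool = True
    use_prompts: bool = True
    use_ee: bool = True
    use_sa: bool = True
    use_ca: bool = True
    use_caf: bool = True
    seed: int = 0

    def to_dict(self):
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["head_hidden"] = list(self.head_hidden)
        if self.ca_hidden is not None:
            d["ca_hidden"] = list(self.ca_hidden)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for k in ("stage_channels", "head_hidden"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        if d.get("ca_hidden") is not None:
            d["ca_hidden"] = tuple(d["ca_hidden"])
        return cls(**d)


class SegHead(Module):
    """Per-stage prediction head: depthwise 3x3, pointwise C -> hidden,
    ReLU, pointwise hidden -> 1 logit channel."""

    def __init__(self, ch, hidden, rng, dtype=np.float32):
        super().__init__()
        self.dw = Conv2d(ch, ch, 3, groups=ch, rng=rng, dtype=dtype)
        self.fc1 = Conv2d(ch, hidden, 1, rng=rng, dtype=dtype)
        self.fc2 = Conv2d(hidden, 1, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.fc2(ag.relu(self.fc1(self.dw(x))))

    def flops(self, h, w):
        return self.dw.flops(h, w) + self.fc1.flops(h, w) + self.fc2.flops(h, w)


class VMPANet(Module):
    def __init__(self, cfg: ModelConfig | None = None, dtype=np.float32):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chans = cfg.stage_channels
        ins = (cfg.in_channels,) + tuple(chans[:-1])
        for i in range(5):
            pcm_cfg = PcmConfig(
                in_channels=ins[i], out_channels=chans[i],
                stride=1 if i == 0 else 2,
                large_kernel=cfg.large_kernel, small_kernel=cfg.small_kernel,
                lambda1=cfg.lambda1, lambda2=cfg.lambda2,
                prompt_lambda1=cfg.prompt_lambda1, prompt_lambda2=cfg.prompt_lambda2,
                use_mamba=cfg.use_mamba_in_pcm, use_prompts=cfg.use_prompts,
                ss2d=cfg.enc_ss2d[i])
            setattr(self, f"enc{i + 1}", PCMStage(pcm_cfg, rng, dtype))
        for i in range(5):
            mca_cfg = McaConfig(
                channels=chans[i], eta=cfg.eta,
                ca_hidden=None if cfg.ca_hidden is None else cfg.ca_hidden[i],
                use_ee=cfg.use_ee, use_sa=cfg.use_sa, use_ca=cfg.use_ca,
                ss2d=cfg.dec_ss2d[i])
            setattr(self, f"dec{i + 1}", MCAStage(mca_cfg, rng, dtype))
        if cfg.use_caf:
            for i in range(4):  # fuses stage t with decoder stage t+1
                setattr(self, f"caf{i + 1}", CAF(chans[i], chans[i + 1], rng, dtype))
        for i in range(5):
            setattr(self, f"head{i + 1}", SegHead(chans[i], cfg.head_hidden[i], rng, dtype))

    # ------------------------------------------------------------------
    def forward(self, image: Tensor) -> dict:
        """Run the network; returns stage logits (upsampled), the final
        probability map, and the per-stage feature shapes."""
        n, c, h, w = image.shape
        if h % 16 or w % 16:
            raise ValueError(f"input side must be divisible by 16, got {h}x{w}")
        enc_feats = []
        x = image
        for i in range(5):
            x = getattr(self, f"enc{i + 1}")(x)
            enc_feats.append(x)
        dec_feats = [None] * 5
        dec_feats[4] = self.dec5(enc_feats[4])
        for t in range(3, -1, -1):  # stages 4..1
            if self.cfg.use_caf:
                f_ct = getattr(self, f"caf{t + 1}")(dec_feats[t + 1], enc_feats[t])
            else:
                f_ct = enc_feats[t]
            dec_feats[t] = getattr(self, f"dec{t + 1}")(f_ct)
        resize = BilinearResize(h, w)
        logits = [resize(getattr(self, f"head{t + 1}")(dec_feats[t])) for t in range(5)]
        return {
            "logits": logits,
            "prob": ag.sigmoid(logits[0]),
            "encoder_shapes": [f.shape[1:] for f in enc_feats],
            "decoder_shapes": [f.shape[1:] for f in dec_feats],
        }

    def predict(self, image: Tensor, threshold: float = 0.5) -> np.ndarray:
        with ag.no_grad():
            out = self.forward(image)
        return (out["prob"].data >= threshold).astype(np.uint8)

    # ------------------------------------------------------------------
    def save(self, path):
        state = self.state_dict()
        np.savez_compressed(path, __config__=json.dumps(self.cfg.to_dict()),
                            **{k: v for k, v in state.items()})

    @classmethod
    def load(cls, path, dtype=np.float32):
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig.from_dict(json.loads(str(z["__config__"])))
            model = cls(cfg, dtype=dtype)
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model
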