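"""Layer primitives: parameters, modules, conv/norm layers, bilinear resize.

FLOP accounting convention (see docs/methods.md): one multiply–accumulate is
one FLOP; convolutions, linear projections and matrix products are counted;
normalisation layers, activations, elementwise arithmetic, pooling and
interpolation are not.  Each layer exposes ``flops(h, w)`` returning the MACs
of one forward pass at that spatial size.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters ignore no_grad at creation


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value)
        object.__setattr__(self, name, self._buffers[name])

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_params(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # checkpointing -----------------------------------------------------
    def state_dict(self, prefix=""):
        out = {}
        for k, p in self._params.items():
            out[f"{prefix}{k}"] = p.data
        for k, b in self._buffers.items():
            out[f"{prefix}{k}"] = b
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix=f"{prefix}{k}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for k, p in self._params.items():
            p.data = np.asarray(state[f"{prefix}{k}"], dtype=p.data.dtype).reshape(p.data.shape)
        for k in list(self._buffers):
            arr = np.asarray(state[f"{prefix}{k}"])
            self._buffers[k][...] = arr.reshape(self._buffers[k].shape)
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix=f"{prefix}{k}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def flops(self, h: int, w: int) -> int:  # pragma: no cover - overridden
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _kaiming(rng, shape, fan_in, dtype):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, k, stride=1, padding=None, groups=1,
                 bias=True, rng=None, dtype=np.float32):
        super().__init__()
        if k % 2 == 0:
            raise ValueError(f"even kernel size {k} breaks symmetric padding")
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (in_ch // groups) * k * k
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch // groups, k, k), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)

    def out_hw(self, h, w):
        return ((h + 2 * self.padding - self.k) // self.stride + 1,
                (w + 2 * self.padding - self.k) // self.stride + 1)

    def flops(self, h, w):
        ho, wo = self.out_hw(h, w)
        return ho * wo * self.out_ch * (self.in_ch // self.groups) * self.k * self.k


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, ch, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float64))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float64))

    def forward(self, x):
        g = self.gamma.reshape(1, self.ch, 1, 1)
        b = self.beta.reshape(1, self.ch, 1, 1)
        if self.training:
            out, mean, var = ag.norm_affine(x, g, b, (0, 2, 3), self.eps)
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mean.ravel()
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var.ravel()
        else:
            dt = x.dtype
            out, _, _ = ag.norm_affine(
                x, g, b, (0, 2, 3), self.eps,
                mean=self.running_mean.astype(dt).reshape(1, self.ch, 1, 1),
                var=self.running_var.astype(dt).reshape(1, self.ch, 1, 1))
        return out

    def flops(self, h, w):
        return 0


class LayerNorm2d(Module):
    """Layer normalisation over the channel axis of NCHW maps (per pixel)."""

    def __init__(self, ch, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.ch, self.eps = ch, eps
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))

    def forward(self, x):
        shape = (1, self.ch) + (1,) * (x.ndim - 2)
        g = self.gamma.reshape(*shape)
        b = self.beta.reshape(*shape)
        out, _, _ = ag.norm_affine(x, g, b, (1,), self.eps)
        return out

    def flops(self, h, w):
        return 0


def bilinear_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """1-D bilinear interpolation operator (align_corners=False convention)."""
    M = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        M[i, lo_c] += 1.0 - frac
        M[i, hi_c] += frac
    return M.astype(dtype)


class BilinearResize(Module):
    """Bilinear resize of NCHW maps, expressed as two constant matmuls."""

    def __init__(self, out_h, out_w):
        super().__init__()
        self.out_h, self.out_w = out_h, out_w
        self._cache = {}

    def forward(self, x):
        n, c, h, w = x.shape
        if (h, w) == (self.out_h, self.out_w):
            return x
        key = (h, w, x.dtype.str)
        if key not in self._cache:
            self._cache[key] = (
                Tensor(bilinear_matrix(self.out_h, h, x.dtype)),
                Tensor(bilinear_matrix(self.out_w, w, x.dtype).T),
            )
        R, CT = self._cache[key]
        return ag.matmul(ag.matmul(R, x), CT)

    def flops(self, h, w):
        return 0  # interpolation is not counted under the pinned convention


def upsample2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    return BilinearResize(h * 2, w * 2)(x)


class MapNorm(Module):
    """Layer normalisation over the spatial extent of each map (per sample,
    per channel).  Used where a normalisation must act on a single-channel
    map — normalising such a map across its one channel would be degenerate
    (every pixel maps to the affine offset)."""

    def __init__(self, ch, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.ch, self.eps = ch, eps
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))

    def forward(self, x):
        g = self.gamma.reshape(1, self.ch, 1, 1)
        b = self.beta.reshape(1, self.ch, 1, 1)
        out, _, _ = ag.norm_affine(x, g, b, (2, 3), self.eps)
        return out

    def flops(self, h, w):
        return 0
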