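"""MCA decoder stage: multi-scale branches, the EASC gate chain, residual
bounds, and straight-line oracles."""

import numpy as np
import pytest

from vmpanet.autograd import Tensor
from vmpanet.decoder import (ChannelAttention, ContextEmbed, EdgeEnhance,
                             MCAStage, McaConfig, MultiScaleDWConv,
                             SpatialAttention)
from test_ss2d import ss2d_core_oracle

SS2D_SMALL = dict(d_state=2, dt_rank=2, expand=1.0, conv_branch=True, gate=False)


def np_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def np_dwconv(x, w, b, k):
    """Depthwise conv, stride 1, same padding, explicit loops."""
    n, c, h, wd = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros_like(x)
    for i in range(k):
        for j in range(k):
            out += w[:, 0, i, j][None, :, None, None] * xp[:, :, i:i + h, j:j + wd]
    return out + b[None, :, None, None]


def np_pointwise(x, w, b):
    return np.einsum("oc,nchw->nohw", w.reshape(w.shape[0], w.shape[1]), x) \
        + b[None, :, None, None]


def np_bn_eval(x, bn):
    m = bn.running_mean[None, :, None, None]
    v = bn.running_var[None, :, None, None]
    xhat = (x - m) / np.sqrt(v + bn.eps)
    return xhat * bn.gamma.data[None, :, None, None] + bn.beta.data[None, :, None, None]


# ---------------------------------------------------------------------------
# multi-scale depthwise branches
# ---------------------------------------------------------------------------

def test_multiscale_shape_and_kernels(rng):
    cfg = McaConfig(channels=8, ss2d=SS2D_SMALL)
    ms = MultiScaleDWConv(cfg, np.random.default_rng(0))
    assert [getattr(ms, f"dw{i}").k for i in range(4)] == [3, 5, 7, 9]
    x = Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
    out = ms(x)
    assert out.shape == (2, 8, 6, 6)
    assert all(getattr(ms, f"pw{i}").out_ch == 2 for i in range(4))


def test_multiscale_rejects_bad_channels():
    with pytest.raises(ValueError):
        McaConfig(channels=6)


def test_multiscale_passthrough_weights(rng):
    """Delta depthwise kernels + identity-selecting pointwise maps make the
    concat a channel-reordered copy of the input."""
    cfg = McaConfig(channels=8, ss2d=SS2D_SMALL)
    ms = MultiScaleDWConv(cfg, np.random.default_rng(0), dtype=np.float64)
    for i, k in enumerate(cfg.branch_kernels):
        dw = getattr(ms, f"dw{i}")
        dw.weight.data[:] = 0.0
        dw.weight.data[:, 0, k // 2, k // 2] = 1.0   # delta kernel
        dw.bias.data[:] = 0.0
        pw = getattr(ms, f"pw{i}")
        pw.weight.data[:] = 0.0
        for j in range(2):                            # select channels 2i, 2i+1
            pw.weight.data[j, 2 * i + j, 0, 0] = 1.0
        pw.bias.data[:] = 0.0
    x = rng.standard_normal((1, 8, 5, 5))
    np.testing.assert_allclose(ms(Tensor(x)).data, x, atol=1e-12)


def test_context_embed_shape_and_oracle(rng):
    ce = ContextEmbed(8, np.random.default_rng(2), dtype=np.float64)
    ce.eval()
    x = rng.standard_normal((1, 8, 5, 5))
    out = ce(Tensor(x))
    assert out.shape == x.shape
    ref = np_bn_eval(np_pointwise(np_dwconv(x, ce.dw.weight.data, ce.dw.bias.data, 3),
                                  ce.pw.weight.data, ce.pw.bias.data), ce.bn)
    np.testing.assert_allclose(out.data, ref, atol=1e-10)
    # zero input, zero biases -> zero output through the affine chain
    ce.dw.bias.data[:] = 0.0
    ce.pw.bias.data[:] = 0.0
    ce.bn.beta.data[:] = 0.0
    np.testing.assert_allclose(ce(Tensor(np.zeros((1, 8, 4, 4)))).data, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# EASC gates
# ---------------------------------------------------------------------------

def test_edge_enhance_zero_and_bounds(rng):
    ee = EdgeEnhance(4, np.random.default_rng(1), dtype=np.float64)
    ee.eval()
    ee.bn.beta.data[:] = 0.0
    ee.dw.bias.data[:] = 0.0
    ee.score.bias.data[:] = 0.0
    np.testing.assert_allclose(ee(Tensor(np.zeros((1, 4, 5, 5)))).data, 0.0, atol=1e-12)
    x = rng.uniform(0.1, 2.0, (1, 4, 6, 6))
    out = ee(Tensor(x)).data
    assert np.all(out > x) and np.all(out < 2 * x)


def test_edge_enhance_matches_loop_oracle(rng):
    ee = EdgeEnhance(4, np.random.default_rng(5), dtype=np.float64)
    ee.eval()
    x = rng.standard_normal((1, 4, 6, 6))
    conv = np_dwconv(x, ee.dw.weight.data, ee.dw.bias.data, 7)
    pooled = np.zeros_like(conv)
    cp = np.pad(conv, ((0, 0), (0, 0), (1, 1), (1, 1)))
    for i in range(3):
        for j in range(3):
            pooled += cp[:, :, i:i + 6, j:j + 6]
    pooled /= 9.0
    xbar = np_bn_eval(x - pooled, ee.bn)
    gate = np_sigmoid(np_pointwise(xbar, ee.score.weight.data, ee.score.bias.data))
    np.testing.assert_allclose(ee(Tensor(x)).data, gate * x + x, atol=1e-10)


def test_spatial_attention_gate_range_schedule_and_oracle(rng):
    sa = SpatialAttention(4, "relu", np.random.default_rng(3), dtype=np.float64)
    sa.eval()
    assert (sa.dw7.k, sa.dw3.k, sa.score.k) == (7, 3, 1)
    x = rng.standard_normal((2, 4, 6, 6))
    g = sa.gate(Tensor(x)).data
    assert g.shape == (2, 1, 6, 6)
    assert g.min() > 0.0 and g.max() < 1.0
    s1 = np_bn_eval(np_dwconv(x, sa.dw7.weight.data, sa.dw7.bias.data, 7), sa.bn1)
    s2 = np_bn_eval(np_dwconv(s1, sa.dw3.weight.data, sa.dw3.bias.data, 3), sa.bn2)
    gate = np_sigmoid(np.maximum(np_pointwise(s2, sa.score.weight.data,
                                              sa.score.bias.data), 0.0))
    np.testing.assert_allclose(sa(Tensor(x)).data, gate * x + x, atol=1e-10)


def test_channel_attention_constant_input_and_oracle(rng):
    ca = ChannelAttention(8, None, np.random.default_rng(4), dtype=np.float64)
    # constant-per-channel input: the max-pool descriptor is exactly v_c
    v = rng.standard_normal(8)
    x = np.broadcast_to(v[None, :, None, None], (1, 8, 4, 4)).copy()
    w = np.maximum(np_pointwise(v[None, :, None, None].copy(),
                                ca.fc1.weight.data, ca.fc1.bias.data), 0.0)
    gate = np_sigmoid(np_pointwise(w, ca.fc2.weight.data, ca.fc2.bias.data))
    np.testing.assert_allclose(ca(Tensor(x)).data, gate * x + x, atol=1e-10)
    # zero input -> zero output (gate acts multiplicatively, residual is x)
    np.testing.assert_allclose(ca(Tensor(np.zeros((1, 8, 3, 3)))).data, 0.0, atol=1e-12)


def test_channel_attention_random_oracle(rng):
    ca = ChannelAttention(8, 4, np.random.default_rng(9), dtype=np.float64)
    x = rng.standard_normal((2, 8, 4, 4))
    pooled = x.max(axis=(2, 3), keepdims=True)
    w = np.maximum(np_pointwise(pooled, ca.fc1.weight.data, ca.fc1.bias.data), 0.0)
    gate = np_sigmoid(np_pointwise(w, ca.fc2.weight.data, ca.fc2.bias.data))
    np.testing.assert_allclose(ca(Tensor(x)).data, gate * x + x, atol=1e-10)


@pytest.mark.parametrize("mod", ["ee", "sa", "ca"])
def test_gate_residual_bounds_positive_input(mod, rng):
    """Every gate stage maps positive x to x < out < 2x (sigmoid in (0,1))."""
    maker = {"ee": lambda r: EdgeEnhance(4, r),
             "sa": lambda r: SpatialAttention(4, "relu", r),
             "ca": lambda r: ChannelAttention(4, None, r)}[mod]
    m = maker(np.random.default_rng(0))
    m.eval()
    x = rng.uniform(0.05, 3.0, (1, 4, 5, 5)).astype(np.float32)
    out = m(Tensor(x)).data
    assert np.all(out > x) and np.all(out < 2 * x)


# ---------------------------------------------------------------------------
# assembled stage
# ---------------------------------------------------------------------------

def test_mca_stage_shape_preserving(rng):
    for c, hw in [(8, 16), (16, 8), (40, 4)]:
        stage = MCAStage(McaConfig(channels=c, ss2d=SS2D_SMALL),
                         np.random.default_rng(0))
        x = Tensor(rng.standard_normal((1, c, hw, hw)).astype(np.float32))
        assert stage(x).shape == x.shape


def test_mca_ablation_switches(rng):
    x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
    outs = []
    for kw in [{}, {"use_ee": False}, {"use_sa": False}, {"use_ca": False}]:
        stage = MCAStage(McaConfig(channels=8, ss2d=SS2D_SMALL, **kw),
                         np.random.default_rng(2))
        stage.eval()
        outs.append(stage(x).data)
    for other in outs[1:]:
        assert not np.allclose(outs[0], other)


def test_mca_stage_composition_oracle(rng):
    """Full stage against the composition of the per-module oracles."""
    stage = MCAStage(McaConfig(channels=8, ss2d=SS2D_SMALL),
                     np.random.default_rng(8), dtype=np.float64)
    stage.eval()
    x = rng.standard_normal((1, 8, 6, 6))
    # mamba pre-pass: LN -> core + residual
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    xn = (x - mu) / np.sqrt(var + stage.mamba.norm.eps)
    xn = xn * stage.mamba.norm.gamma.data[None, :, None, None] \
        + stage.mamba.norm.beta.data[None, :, None, None]
    f_vmt = ss2d_core_oracle(stage.mamba.core, xn) + x
    f_cf = stage.multiscale(Tensor(f_vmt)).data
    f_hat = stage.embed(Tensor(f_cf)).data
    f = stage.ee(Tensor(f_hat)).data
    f = stage.sa(Tensor(f)).data
    f = stage.ca(Tensor(f)).data
    np.testing.assert_allclose(stage(Tensor(x)).data, f + f_vmt, atol=1e-8)
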