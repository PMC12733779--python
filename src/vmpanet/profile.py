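"""Parameter and FLOP accounting, partitioned into encoder / decoder / heads.

Counting convention (documented in docs/methods.md): one multiply–accumulate
is one FLOP.  Convolutions, linear projections, attention matrix products and
the selective-scan recurrence (9·L·D·N per scan direction, the usual analytic
count for S6 kernels) are counted; normalisation, activations, elementwise
arithmetic, pooling and interpolation are not.  Parameters are exact trainable
counts read from the instantiated arrays.
"""

from __future__ import annotations

from .model import VMPANet


def _stage_sizes(model: VMPANet, h: int, w: int):
    """Input and output spatial sizes of each encoder stage."""
    sizes = []
    for i in range(5):
        stage = getattr(model, f"enc{i + 1}")
        ho, wo = stage.out_hw(h, w)
        sizes.append(((h, w), (ho, wo)))
        h, w = ho, wo
    return sizes


def count_budget(model: VMPANet, input_hw=(256, 256)) -> dict:
    """Exact trainable-parameter counts and analytic FLOPs for one forward
    pass at the given input size, partitioned into the PCM encoder stack,
    the MCA decoder plus CAF fusion, and the segmentation heads."""
    h, w = input_hw
    sizes = _stage_sizes(model, h, w)

    enc_params = sum(getattr(model, f"enc{i + 1}").num_params() for i in range(5))
    dec_params = sum(getattr(model, f"dec{i + 1}").num_params() for i in range(5))
    if model.cfg.use_caf:
        dec_params += sum(getattr(model, f"caf{i + 1}").num_params() for i in range(4))
    head_params = sum(getattr(model, f"head{i + 1}").num_params() for i in range(5))

    enc_flops = sum(getattr(model, f"enc{i + 1}").flops(*sizes[i][0]) for i in range(5))
    dec_flops = sum(getattr(model, f"dec{i + 1}").flops(*sizes[i][1]) for i in range(5))
    if model.cfg.use_caf:
        dec_flops += sum(getattr(model, f"caf{i + 1}").flops(*sizes[i][1]) for i in range(4))
    head_flops = sum(getattr(model, f"head{i + 1}").flops(*sizes[i][1]) for i in range(5))

    report = {
        "input_hw": list(input_hw),
        "params": {
            "encoder": enc_params,
            "decoder": dec_params,
            "head": head_params,
            "total": enc_params + dec_params + head_params,
        },
        "flops": {
            "encoder": enc_flops,
            "decoder": dec_flops,
            "head": head_flops,
            "total": enc_flops + dec_flops + head_flops,
        },
    }
    report["params_M"] = {k: v / 1e6 for k, v in report["params"].items()}
    report["flops_G"] = {k: v / 1e9 for k, v in report["flops"].items()}
    return report
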