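"""Walk one synthetic image through the network's building blocks.

Shows the four-direction cross-scan on a tiny grid, the encoder stage
schedule, and the two self-prompt masks the first encoder stage distils
from its local (convolutional) and global (Mamba) paths.
"""

import numpy as np

import vmpanet.autograd as ag
from vmpanet import ModelConfig, Tensor, VMPANet
from vmpanet.ss2d import cross_scan
from vmpanet.synthetic import LesionParams, generate_pair

# four-direction scan of a 2x2 grid: row/col forward and backward
grid = Tensor(np.array([[1., 2.], [3., 4.]]).reshape(1, 1, 2, 2))
names = ("row_fwd", "row_bwd", "col_fwd", "col_bwd")
for name, seq in zip(names, cross_scan(grid)):
    print(f"{name}: {seq.data.ravel().astype(int).tolist()}")

img, _ = generate_pair(LesionParams(seed=3, image_size=64))
x = Tensor((img.astype(np.float32).transpose(2, 0, 1) / 255.0 - 0.5)[None])

model = VMPANet(ModelConfig())
model.eval()
with ag.no_grad():
    out = model(x)
    print("encoder stages (C,H,W):", out["encoder_shapes"])

    f_ipc = model.enc1.inverted_pyramid_conv(x)
    f_m, _ = model.enc1.fuse_global_local(f_ipc)
    p1, p2 = model.enc1.make_prompts(f_ipc, f_m)
print(f"prompt p1 (local detail cue): range [{p1.data.min():.3f}, {p1.data.max():.3f}]")
print(f"prompt p2 (global saliency cue): range [{p2.data.min():.3f}, {p2.data.max():.3f}]")

# Both prompts are single-channel sigmoid maps strictly inside (0,1); they
# are added back onto the fused feature so later stages inherit an explicit
# saliency hint rather than having to rediscover the lesion each stage.
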