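"""Learning sanity: memorise a handful of synthetic pairs on the CPU.

Trains the default model on 4 fixed 64x64 synthetic images with AdamW
(lr 1e-3) and prints the deep-supervised loss and training Dice every few
steps.  Loss should fall steadily and Dice climb well past 0.9 — evidence
that gradients flow through scan, gates, fusion, and heads alike.
"""

import numpy as np

import vmpanet.autograd as ag
from vmpanet import ModelConfig, Tensor, VMPANet, total_loss
from vmpanet.metrics import evaluate_pair
from vmpanet.optim import AdamW
from vmpanet.synthetic import LesionParams, generate_pair

imgs, masks = [], []
for i in range(4):
    img, m = generate_pair(LesionParams(seed=50 + i, image_size=64))
    imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
    masks.append((m > 127).astype(np.float32)[None])
X, Y = np.stack(imgs), np.stack(masks)
mean, std = X.mean(axis=(0, 2, 3)), X.std(axis=(0, 2, 3)) + 1e-6
x = Tensor(((X - mean[None, :, None, None]) / std[None, :, None, None]).astype(np.float32))
y = Tensor(Y)

model = VMPANet(ModelConfig(seed=0))
opt = AdamW(model.parameters(), lr=1e-3)
for step in range(60):
    opt.zero_grad()
    loss = total_loss(model(x), y)
    loss.backward()
    opt.step()
    if (step + 1) % 15 == 0:
        model.eval()
        with ag.no_grad():
            prob = model(x)["prob"].data
        model.train()
        dsc = np.mean([evaluate_pair((prob[i, 0] >= 0.5).astype(np.uint8),
                                     Y[i, 0].astype(np.uint8))["dsc"]
                       for i in range(4)])
        print(f"step {step + 1:3d}  loss {loss.item():6.3f}  train DSC {dsc:.3f}")

# The loss starts around 12-13 (five supervised stages, each contributing
# BCE + Dice near their untrained values) and drops by an order of magnitude
# as the masks are memorised.
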