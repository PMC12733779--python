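"""Training driver: AdamW + cosine schedule + deep supervision, with
checkpoint selection by validation Dice."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data import SegmentationFolder, augment_pair, normalize
from .losses import LossConfig, total_loss
from .metrics import evaluate_pair
from .model import ModelConfig, VMPANet
from .optim import AdamW, CosineAnnealingLR

log = logging.getLogger("vmpanet")


@dataclass
class TrainConfig:
    lr: float = 0.001
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 1e-2
    amsgrad: bool = False          # kept for config completeness; off
    t_max: int = 50                # cosine cycle length, epochs
    eta_min: float = 1e-5
    epochs: int = 200
    batch_size: int = 8
    input_size: int = 256
    flip_p: float = 0.5
    max_rotation: float = 30.0
    augment: bool = True
    val_fraction: float = 0.2      # sub-split of the training set
    seed: int = 0
    stage_weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)

    def to_dict(self):
        d = asdict(self)
        d["betas"] = list(self.betas)
        d["stage_weights"] = list(self.stage_weights)
        return d


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _val_dice(model, images, masks, mean, std):
    model.eval()
    scores = []
    with ag.no_grad():
        for img, msk in zip(images, masks):
            x = Tensor(normalize(img, mean, std)[None])
            pred = (model(x)["prob"].data[0, 0] >= 0.5).astype(np.uint8)
            scores.append(evaluate_pair(pred, msk[0].astype(np.uint8))["dsc"])
    model.train()
    return float(np.mean(scores))


def train(dataset_dir, run_dir, model_cfg: ModelConfig | None = None,
          train_cfg: TrainConfig | None = None, split: str | None = None):
    """Train on ``dataset_dir`` (images/ + masks/); writes config, per-epoch
    log, and best/last checkpoints into ``run_dir``.  Returns a summary."""
    tc = train_cfg or TrainConfig()
    mc = model_cfg or ModelConfig()
    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    with open(run / "config.json", "w") as fh:
        json.dump({"model": mc.to_dict(), "train": tc.to_dict()}, fh, indent=2)

    ds = SegmentationFolder(dataset_dir, size=tc.input_size, split=split)
    rng = np.random.default_rng(tc.seed)
    n_val = int(round(len(ds) * tc.val_fraction)) if len(ds) > 1 else 0
    order = rng.permutation(len(ds))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx = order
    if len(val_idx) == 0:
        val_idx = tr_idx  # checkpoint selection falls back to training DSC
    tr_imgs = [ds.images[i] for i in tr_idx]
    tr_masks = [ds.masks[i] for i in tr_idx]
    va_imgs = [ds.images[i] for i in val_idx]
    va_masks = [ds.masks[i] for i in val_idx]
    mean, std = np.stack(tr_imgs).mean(axis=(0, 2, 3)), \
        np.stack(tr_imgs).std(axis=(0, 2, 3)) + 1e-6
    np.save(run / "norm_stats.npy", np.stack([mean, std]))

    model = VMPANet(mc)
    model.save(run / "init.npz")   # initial weights, for replay/resume checks
    opt = AdamW(model.parameters(), lr=tc.lr, betas=tc.betas, eps=tc.eps,
                weight_decay=tc.weight_decay)
    sched = CosineAnnealingLR(opt, t_max=tc.t_max, eta_min=tc.eta_min)
    loss_cfg = LossConfig(stage_weights=tc.stage_weights)

    history = []
    best_dsc = -1.0
    logf = open(run / "train.log", "a")
    for epoch in range(tc.epochs):
        t0 = time.time()
        epoch_loss, nb = 0.0, 0
        for idx in _batches(len(tr_imgs), tc.batch_size, rng):
            xs, ys = [], []
            for i in idx:
                img, msk = tr_imgs[i], tr_masks[i]
                if tc.augment:
                    img, msk = augment_pair(img, msk, rng, tc.flip_p, tc.max_rotation)
                xs.append(normalize(img, mean, std))
                ys.append(msk)
            x = Tensor(np.stack(xs))
            y = Tensor(np.stack(ys))
            opt.zero_grad()
            loss = total_loss(model(x), y, loss_cfg)
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            nb += 1
        sched.step()
        val_dsc = _val_dice(model, va_imgs, va_masks, mean, std)
        rec = {"epoch": epoch + 1, "loss": epoch_loss / max(nb, 1),
               "val_dsc": val_dsc, "lr": opt.lr, "sec": time.time() - t0}
        history.append(rec)
        line = (f"epoch {rec['epoch']:3d}  loss {rec['loss']:.4f}  "
                f"val_dsc {val_dsc:.4f}  lr {opt.lr:.2e}  {rec['sec']:.1f}s")
        log.info(line)
        print(line, file=logf, flush=True)
        if val_dsc >= best_dsc:
            best_dsc = val_dsc
            model.save(run / "best.npz")
        model.save(run / "last.npz")
    logf.close()
    with open(run / "history.json", "w") as fh:
        json.dump(history, fh, indent=2)
    return {"run_dir": str(run), "best_val_dsc": best_dsc, "history": history}


def evaluate(checkpoint, dataset_dir, out_csv=None, size: int = 256,
             split: str | None = None, norm_stats=None):
    """Per-image and aggregate metrics of a checkpoint on a dataset."""
    from .metrics import write_metrics_csv

    model = VMPANet.load(checkpoint)
    model.eval()
    ds = SegmentationFolder(dataset_dir, size=size, split=split)
    if norm_stats is not None:
        mean, std = np.load(norm_stats)
    else:
        mean, std = ds.channel_stats()
    rows = []
    with ag.no_grad():
        for name, img, msk in zip(ds.names, ds.images, ds.masks):
            x = Tensor(normalize(img, mean, std)[None])
            pred = (model(x)["prob"].data[0, 0] >= 0.5).astype(np.uint8)
            rows.append((name, evaluate_pair(pred, msk[0].astype(np.uint8))))
    if out_csv:
        write_metrics_csv(out_csv, rows)
    agg = {k: float(np.mean([m[k] for _, m in rows]))
           for k in rows[0][1]} if rows else {}
    return rows, agg
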