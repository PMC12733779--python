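"""Dataset loading (images/ masks/ folder layout) and paired augmentation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class SegmentationFolder:
    """A directory with images/ and masks/ holding same-named PNG/JPEG pairs.

    Images are resized to ``size``×``size`` (bilinear; nearest for masks) and
    kept in memory as float arrays in [0,1] (C,H,W) with {0,1} masks.
    """

    def __init__(self, root, size: int = 256, split: str | None = None):
        self.root = Path(root)
        img_dir, mask_dir = self.root / "images", self.root / "masks"
        if not img_dir.is_dir() or not mask_dir.is_dir():
            raise FileNotFoundError(f"{self.root} must contain images/ and masks/")
        imgs = sorted(p for p in img_dir.iterdir()
                      if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        names = {p.name for p in imgs}
        mask_names = {p.name for p in mask_dir.iterdir()
                      if p.suffix.lower() in (".png", ".jpg", ".jpeg")}
        if names != mask_names:
            missing = sorted(names ^ mask_names)[:10]
            raise ValueError(f"image/mask mismatch; unmatched files: {missing}")
        if split is not None:
            manifest = self.root / "manifest.json"
            if not manifest.exists():
                raise FileNotFoundError(f"split='{split}' requires {manifest}")
            with open(manifest) as fh:
                entries = json.load(fh)["entries"]
            keep = {e["name"] for e in entries if e["split"] == split}
            imgs = [p for p in imgs if p.name in keep]
        self.names = [p.name for p in imgs]
        self.images, self.masks = [], []
        for name in self.names:
            img = Image.open(img_dir / name).convert("RGB")
            msk = Image.open(mask_dir / name).convert("L")
            if img.size != (size, size):
                img = img.resize((size, size), Image.BILINEAR)
            if msk.size != (size, size):
                msk = msk.resize((size, size), Image.NEAREST)
            self.images.append(np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0)
            self.masks.append((np.asarray(msk) > 127).astype(np.float32)[None])
        self.size = size

    def __len__(self):
        return len(self.names)

    def channel_stats(self):
        """Per-channel mean/std over this split (for normalisation)."""
        stack = np.stack(self.images)
        return stack.mean(axis=(0, 2, 3)), stack.std(axis=(0, 2, 3)) + 1e-6


def augment_pair(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 flip_p: float = 0.5, max_rotation: float = 30.0):
    """Horizontal/vertical flips and a random rotation, applied identically
    to image and mask (nearest-neighbour for the mask)."""
    if rng.random() < flip_p:
        img, mask = img[:, :, ::-1], mask[:, :, ::-1]
    if rng.random() < flip_p:
        img, mask = img[:, ::-1, :], mask[:, ::-1, :]
    angle = rng.uniform(-max_rotation, max_rotation)
    if abs(angle) > 1e-3:
        img = ndimage.rotate(img, angle, axes=(1, 2), reshape=False,
                             order=1, mode="reflect")
        mask = ndimage.rotate(mask, angle, axes=(1, 2), reshape=False,
                              order=0, mode="constant")
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def normalize(img: np.ndarray, mean, std):
    return (img - np.asarray(mean, dtype=img.dtype)[:, None, None]) \
        / np.asarray(std, dtype=img.dtype)[:, None, None]
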