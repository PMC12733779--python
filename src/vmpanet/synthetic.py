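"""Seeded synthetic dermoscopy generator.

Emulates the structure a lesion-segmentation network is trained on — a
skin-tone background with a smooth illumination gradient, one irregular
low-contrast lesion blob with a fuzzy boundary, and optional dark hair-like
occluders — while staying fully analytic: the lesion is a star-convex region
r(θ) = r0·(1 + Σ_k a_k sin(kθ + φ_k)), so at zero boundary perturbation the
mask equals an exact ellipse rasterisation that tests can check per pixel.
Images emulate dermoscopy geometry and contrast statistics, not photorealism
(no gel, rulers, or colour calibration targets).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["LesionParams", "generate_pair", "generate_dataset", "load_pair"]


@dataclass
class LesionParams:
    seed: int = 0
    image_size: int = 256
    area_fraction_range: tuple = (0.05, 0.40)
    n_harmonics: int = 4                 # polar boundary perturbations
    harmonic_amplitude: float = 0.15     # per-harmonic max |a_k|
    blur_sigma: float = 2.0              # boundary fuzziness, pixels
    contrast: float = 0.25               # lesion/skin intensity gap in [0,1]
    hair_count: int = 3
    axis_ratio_range: tuple = (0.6, 1.0)

    def __post_init__(self):
        lo, hi = self.area_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("area_fraction_range must satisfy 0 < lo < hi < 1")
        if self.harmonic_amplitude * self.n_harmonics >= 1.0:
            raise ValueError("total harmonic amplitude must stay below 1 "
                             "to keep the radius positive")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")


def _lesion_mask(p: LesionParams, rng: np.random.Generator) -> np.ndarray:
    """Rasterise one star-convex lesion; rejection-samples centre/size until
    the area fraction lands in range and the region is a single component."""
    s = p.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    target = rng.uniform(*p.area_fraction_range)
    for _ in range(200):
        cy = rng.uniform(0.3 * s, 0.7 * s)
        cx = rng.uniform(0.3 * s, 0.7 * s)
        ratio = rng.uniform(*p.axis_ratio_range)
        angle = rng.uniform(0, np.pi)
        # r0 for an ellipse of the target area: pi * r0 * (r0*ratio) = A
        r0 = np.sqrt(target * s * s / (np.pi * ratio))
        amps = rng.uniform(-p.harmonic_amplitude, p.harmonic_amplitude, p.n_harmonics)
        phases = rng.uniform(0, 2 * np.pi, p.n_harmonics)
        ca, sa = np.cos(angle), np.sin(angle)
        dx, dy = xx - cx, yy - cy
        u = ca * dx + sa * dy
        v = (-sa * dx + ca * dy) / ratio      # stretch to a circle
        rad = np.hypot(u, v)
        theta = np.arctan2(v, u)
        k = np.arange(1, p.n_harmonics + 1)
        wobble = 1.0 + (amps[None, None, :] *
                        np.sin(k[None, None, :] * theta[..., None]
                               + phases[None, None, :])).sum(axis=-1)
        mask = rad <= r0 * wobble
        frac = mask.mean()
        lo, hi = p.area_fraction_range
        if not (lo <= frac <= hi):
            continue
        labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
        if n != 1:
            continue
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            continue  # keep the lesion inside the frame
        return mask
    raise RuntimeError("could not sample a lesion satisfying the constraints")


def _hair_layer(p: LesionParams, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative attenuation map of dark 1–2 px arcs drawn over both
    lesion and skin; the mask is left untouched."""
    s = p.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    att = np.ones((s, s))
    for _ in range(p.hair_count):
        # circular arc with centre far outside the frame: locally hair-straight
        cy = rng.uniform(-2 * s, 3 * s)
        cx = rng.uniform(-2 * s, 3 * s)
        radius = rng.uniform(1.0 * s, 3.0 * s)
        width = rng.uniform(0.6, 1.2)
        darkness = rng.uniform(0.25, 0.5)
        band = np.abs(np.hypot(yy - cy, xx - cx) - radius) < width
        att[band] *= (1.0 - darkness)
    return att


def generate_pair(p: LesionParams):
    """One (H,W,3) uint8 dermoscopy-like image and its {0,255} uint8 mask.

    Byte-identical for identical parameters (the generator is a pure
    function of the seed).
    """
    rng = np.random.default_rng(p.seed)
    s = p.image_size
    mask = _lesion_mask(p, rng)

    # skin background: warm tone + smooth illumination gradient + mild noise
    base = np.array([0.80, 0.55, 0.45]) + rng.uniform(-0.05, 0.05, 3)
    gy, gx = rng.uniform(-0.15, 0.15, 2)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64) / s
    illum = 1.0 + gy * (yy - 0.5) + gx * (xx - 0.5)
    img = base[None, None, :] * illum[..., None]
    img += rng.normal(0.0, 0.015, img.shape)

    # lesion texture: darker, slightly shifted hue, mottled
    lesion_tint = np.array([0.45, 0.30, 0.28]) + rng.uniform(-0.04, 0.04, 3)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (s, s)), 4.0)
    texture = 0.06 * texture / (np.abs(texture).max() + 1e-9)
    lesion_rgb = lesion_tint[None, None, :] * (illum + texture)[..., None]

    # soft alpha: blur only the blend, never the stored mask
    alpha = mask.astype(np.float64)
    if p.blur_sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, p.blur_sigma)
    # shift the lesion layer so the final (post-blend, post-hair, post-clip)
    # mean intensity gap between surrounding skin and lesion is at least
    # `contrast`; boundary blending and occluders pull the gap around, so
    # iterate on the pre-blend target
    hair = _hair_layer(p, rng)[..., None] if p.hair_count > 0 else 1.0
    skin_level = img[~mask].mean()
    lesion_level = lesion_rgb[mask].mean()
    want = p.contrast
    for _ in range(8):
        shift = (skin_level - want) - lesion_level
        blended = img * (1.0 - alpha[..., None]) + (lesion_rgb + shift) * alpha[..., None]
        final = np.clip(blended * hair, 0.0, 1.0)
        gap = final[~mask].mean() - final[mask].mean()
        if gap >= p.contrast:
            break
        want += (p.contrast - gap) + 0.01
    return (final * 255).round().astype(np.uint8), mask.astype(np.uint8) * 255


def generate_dataset(n: int, seed: int, out_dir, params: LesionParams | None = None,
                     train_fraction: float = 0.7, force: bool = False) -> dict:
    """Write ``n`` PNG image/mask pairs plus a JSON manifest with the split
    assignment (default 7:3 train/test)."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    base = params or LesionParams()
    entries = []
    n_train = int(round(n * train_fraction))
    for i in range(n):
        p = LesionParams(**{**asdict(base),
                            "seed": int(np.random.default_rng([seed, i]).integers(2 ** 31)),
                            "area_fraction_range": tuple(base.area_fraction_range),
                            "axis_ratio_range": tuple(base.axis_ratio_range)})
        img, mask = generate_pair(p)
        name = f"{i:04d}.png"
        Image.fromarray(img).save(out / "images" / name)
        Image.fromarray(mask).save(out / "masks" / name)
        entries.append({"name": name, "seed": p.seed,
                        "split": "train" if i < n_train else "test"})
    manifest = {
        "n": n, "seed": seed, "train_fraction": train_fraction,
        "params": asdict(base), "entries": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_pair(image_path, mask_path):
    """Read an image/mask PNG pair; masks binarise at >127 (ISIC convention)."""
    img = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.uint8)
    mask = np.asarray(Image.open(mask_path).convert("L"))
    return img, (mask > 127).astype(np.uint8)


def content_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()
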