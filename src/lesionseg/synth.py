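"""Seeded generator of dermoscopy-like images with ground-truth masks.

Real dermoscopic lesion images are characterised by an irregular pigmented
blob on lighter skin, often with fuzzy low-contrast boundaries and
distractor artifacts: dark hairs, glue halos and ruler markings.  The
generator emulates exactly those traits so every training and evaluation
path can be exercised without downloading data:

* the lesion is a star-shaped blob — an ellipse whose radius is perturbed by
  a low-frequency random Fourier series — guaranteeing a connected binary
  mask with an area fraction kept inside [0.05, 0.6];
* the lesion fill is a darker pigment tone blended over a skin-toned
  background with a smooth illumination gradient; boundary fuzziness is a
  Gaussian blur of the compositing matte, and ``contrast`` scales the
  pigment/skin separation;
* artifacts are composited *after* the mask is fixed, so hairs, glue and
  ruler ticks perturb the image but never the ground truth — mirroring real
  annotation semantics;
* pixel noise is Gaussian.

Difficulty presets: ``easy`` (sharp, high-contrast, artifact-free — the
regime where a plain Otsu threshold already segments well), ``medium`` and
``hard`` (fuzzy, low-contrast, artifact-laden).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as sk_polygon

from .augment import ImageSample

SKIN_TONE = np.array([0.85, 0.66, 0.58])
PIGMENT_TONE = np.array([0.35, 0.20, 0.16])


@dataclass(frozen=True)
class SynthSpec:
    image_size: int = 96
    fuzziness: float = 0.5   # Gaussian blur sigma (px) of the compositing matte
    contrast: float = 0.8    # 0..1 pigment/skin separation
    irregularity: float = 0.25  # radial perturbation strength of the blob
    hair: bool = False
    glue: bool = False
    ruler: bool = False
    noise: float = 0.02      # per-pixel Gaussian sigma
    area_range: tuple = (0.05, 0.6)
    seed: int = 0

    @classmethod
    def easy(cls, **kw):
        return cls(fuzziness=0.5, contrast=0.8, **kw)

    @classmethod
    def medium(cls, **kw):
        return cls(fuzziness=2.0, contrast=0.5, hair=True, **kw)

    @classmethod
    def hard(cls, **kw):
        return cls(fuzziness=4.0, contrast=0.25, hair=True, glue=True,
                   ruler=True, noise=0.04, **kw)


def _lesion_mask(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Star-shaped blob mask with area fraction inside ``spec.area_range``."""
    s = spec.image_size
    lo, hi = spec.area_range
    for attempt in range(25):
        frac = rng.uniform(0.10, 0.35)
        r0 = np.sqrt(frac * s * s / np.pi)
        aspect = rng.uniform(0.7, 1.4)
        cy = s / 2 + rng.uniform(-0.08, 0.08) * s
        cx = s / 2 + rng.uniform(-0.08, 0.08) * s
        theta = np.linspace(0.0, 2 * np.pi, 360, endpoint=False)
        radius = np.ones_like(theta)
        for k in range(2, 6):
            radius += (spec.irregularity / k) * rng.normal() * np.cos(
                k * theta + rng.uniform(0, 2 * np.pi))
        radius = np.clip(radius, 0.3, 2.0)
        rr = cy + r0 * aspect * radius * np.sin(theta)
        cc = cx + (r0 / aspect) * radius * np.cos(theta)
        pr, pc = sk_polygon(np.clip(rr, 0, s - 1), np.clip(cc, 0, s - 1), shape=(s, s))
        mask = np.zeros((s, s), dtype=np.uint8)
        mask[pr, pc] = 1
        frac_real = mask.mean()
        if lo <= frac_real <= hi:
            return mask
    raise RuntimeError("could not generate a lesion with admissible area fraction")


def _add_hairs(img, rng, n=None):
    s = img.shape[0]
    n = n if n is not None else rng.integers(3, 7)
    overlay = np.zeros((s, s))
    t = np.linspace(0, 1, 4 * s)
    for _ in range(n):
        p = rng.uniform(0, s, size=(3, 2))  # quadratic Bezier control points
        pts = ((1 - t)[:, None] ** 2 * p[0] + 2 * (t * (1 - t))[:, None] * p[1]
               + (t ** 2)[:, None] * p[2])
        ij = np.round(pts).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < s) & (ij[:, 1] >= 0) & (ij[:, 1] < s)
        overlay[ij[keep, 0], ij[keep, 1]] = 1.0
    overlay = ndimage.grey_dilation(overlay, size=(2, 2))
    overlay = ndimage.gaussian_filter(overlay, 0.6)
    dark = rng.uniform(0.05, 0.25)
    return img * (1 - 0.8 * overlay[..., None]) + dark * 0.8 * overlay[..., None]


def _add_glue(img, mask, rng):
    """Bright translucent halo around the lesion."""
    dist = ndimage.distance_transform_edt(1 - mask)
    ring = np.exp(-((dist - rng.uniform(4, 8)) ** 2) / (2 * 3.0 ** 2)) * (mask == 0)
    return np.clip(img + 0.15 * ring[..., None], 0, 1)


def _add_ruler(img, rng):
    s = img.shape[0]
    row = int(rng.uniform(0.05, 0.15) * s)
    step = max(3, s // 24)
    out = img.copy()
    for c in range(step, s - step, step):
        out[row:row + max(2, s // 32), c:c + 1, :] *= 0.3
    return out


def generate_sample(spec: SynthSpec) -> ImageSample:
    """One seeded dermoscopy-like sample; identical output for identical spec."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    mask = _lesion_mask(spec, rng)

    yy, xx = np.mgrid[0:s, 0:s] / s
    illum = 1.0 - 0.15 * ((yy - rng.uniform(0, 1)) ** 2 + (xx - rng.uniform(0, 1)) ** 2)
    skin = SKIN_TONE[None, None, :] * illum[..., None]
    skin = skin * (1 + 0.03 * rng.normal(size=(s, s, 1)))  # mild skin texture
    pigment = SKIN_TONE + (PIGMENT_TONE - SKIN_TONE) * spec.contrast
    # radial pigment variation: darker core, lighter rim
    dist_in = ndimage.distance_transform_edt(mask)
    depth = dist_in / max(dist_in.max(), 1.0)
    lesion = pigment[None, None, :] * (0.85 + 0.15 * (1 - depth))[..., None]

    matte = mask.astype(np.float64)
    if spec.fuzziness > 0:
        matte = ndimage.gaussian_filter(matte, spec.fuzziness)
    img = lesion * matte[..., None] + skin * (1 - matte[..., None])

    if spec.hair:
        img = _add_hairs(img, rng)
    if spec.glue:
        img = _add_glue(img, mask, rng)
    if spec.ruler:
        img = _add_ruler(img, rng)
    if spec.noise > 0:
        img = img + rng.normal(0, spec.noise, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return ImageSample.from_hwc(img, mask)


def generate_dataset(n: int, spec: SynthSpec, out_dir, split: str = "train",
                     start_seed: int | None = None) -> pd.DataFrame:
    """Write ``n`` PNG image/mask pairs plus a CSV manifest; returns the
    manifest.  Per-sample seeds are ``start_seed + i`` (default: spec.seed),
    so train/val splits started at disjoint offsets share no sample ids."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = spec.seed if start_seed is None else start_seed
    rows = []
    for i in range(n):
        sample_spec = replace(spec, seed=base + i)
        sample = generate_sample(sample_spec)
        image_id = f"{split}_{base + i:05d}"
        img_path = out / f"{image_id}.png"
        mask_path = out / f"{image_id}_mask.png"
        iio.imwrite(img_path, (np.moveaxis(sample.image, 0, -1) * 255).astype(np.uint8))
        iio.imwrite(mask_path, (sample.mask * 255).astype(np.uint8))
        rows.append({"image_id": image_id, "split": split,
                     "image": img_path.name, "mask": mask_path.name,
                     "seed": sample_spec.seed, "image_size": spec.image_size,
                     "fuzziness": spec.fuzziness, "contrast": spec.contrast,
                     "hair": spec.hair, "glue": spec.glue, "ruler": spec.ruler,
                     "noise": spec.noise})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / f"manifest_{split}.csv", index=False)
    return manifest


def generate_samples(n: int, spec: SynthSpec, start_seed: int | None = None) -> list:
    """In-memory dataset (list of :class:`ImageSample`) without file I/O."""
    base = spec.seed if start_seed is None else start_seed
    return [generate_sample(replace(spec, seed=base + i)) for i in range(n)]


def otsu_baseline(sample: ImageSample) -> np.ndarray:
    """Simple thresholding oracle: Otsu on grayscale, lesion = darker side."""
    from skimage.filters import threshold_otsu

    gray = np.moveaxis(sample.image, 0, -1) @ np.array([0.299, 0.587, 0.114])
    return (gray < threshold_otsu(gray)).astype(np.uint8)
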