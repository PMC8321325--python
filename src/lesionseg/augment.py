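"""Train-time geometric augmentation with a replayable transform record.

One augmentation draw composes, in order: horizontal/vertical flips (p=0.5
each), a centred crop at a scale drawn from [0.75, 1.25] (scales above 1
zero-pad), a rotation drawn from [-20, 20] degrees, a crop to the ground-truth
bounding box expanded by 50 px (zero-padded where the expansion leaves the
frame; skipped for empty masks), a rigid moving-least-squares warp driven by
a coarse grid of jittered control points, and finally a resize to the network
input size.  Images are interpolated bilinearly, masks with nearest-neighbour
so they stay strictly binary, and the edge target is re-derived from the
transformed mask.  Every random draw comes from one seeded generator and is
stored in the sample's transform record, so the exact geometric path can be
replayed on any array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from .config import AugmentConfig
from .targets import derive_edge


@dataclass
class ImageSample:
    """An image with its mask, derived edge target and transform provenance."""

    image: np.ndarray  # (3, H, W) float32 in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    edge: np.ndarray | None = None  # (H, W) uint8 in {0, 1}, derived
    transforms: list = field(default_factory=list)

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be (3,H,W), got {self.image.shape}")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError("mask and image spatial sizes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be strictly binary")

    @classmethod
    def from_hwc(cls, image_hwc, mask, **kw):
        img = np.ascontiguousarray(np.moveaxis(image_hwc, -1, 0)).astype(np.float32)
        return cls(image=img, mask=np.asarray(mask, dtype=np.uint8), **kw)


# ---------------------------------------------------------------------------
# rigid moving least squares
# ---------------------------------------------------------------------------

def mls_rigid_transform(v: np.ndarray, p: np.ndarray, q: np.ndarray,
                        eps: float = 1e-8) -> np.ndarray:
    """Rigid (similarity-constrained) moving-least-squares deformation.

    Maps query points ``v`` (M,2) given handles ``p`` -> ``q`` (n,2 each),
    with inverse-square-distance weights.  Reproduces any global rigid motion
    of the handles exactly.
    """
    v = np.asarray(v, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    dr = v[:, 0:1] - p[None, :, 0]  # (M,n)
    dc = v[:, 1:2] - p[None, :, 1]
    w = 1.0 / (dr * dr + dc * dc + eps)
    wsum = w.sum(axis=1)
    pstar_r = w @ p[:, 0] / wsum  # (M,)
    pstar_c = w @ p[:, 1] / wsum
    qstar_r = w @ q[:, 0] / wsum
    qstar_c = w @ q[:, 1] / wsum
    phat_r = p[None, :, 0] - pstar_r[:, None]  # (M,n)
    phat_c = p[None, :, 1] - pstar_c[:, None]
    qhat_r = q[None, :, 0] - qstar_r[:, None]
    qhat_c = q[None, :, 1] - qstar_c[:, None]
    ur = v[:, 0] - pstar_r  # (M,)
    uc = v[:, 1] - pstar_c
    a = phat_r * ur[:, None] + phat_c * uc[:, None]        # p̂·u
    c = -phat_r * uc[:, None] + phat_c * ur[:, None]       # p̂·u⊥, u⊥=(-uc,ur)
    fr_x = (w * (qhat_r * a + qhat_c * c)).sum(axis=1)
    fr_y = (w * (qhat_c * a - qhat_r * c)).sum(axis=1)
    norm = np.hypot(fr_x, fr_y)
    ulen = np.hypot(ur, uc)
    scale = np.where(norm > 1e-12, ulen / np.where(norm > 1e-12, norm, 1.0), 0.0)
    return np.stack([fr_x * scale + qstar_r, fr_y * scale + qstar_c], axis=1)


def _interp_matrix(pos: np.ndarray, n: int) -> np.ndarray:
    """(n, len(pos)) linear-interpolation matrix from samples at ``pos``
    (increasing, covering 0 and n-1) to every integer coordinate."""
    pos = np.asarray(pos)
    M = np.zeros((n, len(pos)))
    x = np.arange(n)
    idx = np.clip(np.searchsorted(pos, x, side="right") - 1, 0, len(pos) - 2)
    t = (x - pos[idx]) / (pos[idx + 1] - pos[idx])
    M[x, idx] = 1.0 - t
    M[x, idx + 1] += t
    return M


def _mls_backward_coords(shape, control_points, displacements, grid_step: int = 2):
    """Per-pixel source coordinates for warping ``shape`` output pixels.

    Backward mapping: the handle at ``p + d`` in the output must sample the
    input at ``p``, i.e. the coordinate field is the rigid MLS deformation
    with handles ``p + d -> p``.  The smooth field is evaluated on a
    ``grid_step``-strided lattice (plus the borders) and expanded bilinearly;
    this is exact for any affine field, so global rigid motions are still
    reproduced exactly.
    """
    h, w = shape
    rows = np.unique(np.r_[np.arange(0, h, grid_step), h - 1])
    cols = np.unique(np.r_[np.arange(0, w, grid_step), w - 1])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    v = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    p = np.asarray(control_points, dtype=np.float64)
    d = np.asarray(displacements, dtype=np.float64)
    src = mls_rigid_transform(v, p + d, p)
    fr = src[:, 0].reshape(len(rows), len(cols))
    fc = src[:, 1].reshape(len(rows), len(cols))
    if grid_step > 1:
        Rr = _interp_matrix(rows, h)
        Rc = _interp_matrix(cols, w)
        fr = Rr @ fr @ Rc.T
        fc = Rr @ fc @ Rc.T
    return fr, fc


def rigid_mls_warp(image: np.ndarray, mask: np.ndarray,
                   control_points: np.ndarray, displacements: np.ndarray):
    """Warp an (H,W[,C]) image and its (H,W) mask by a rigid MLS deformation.

    ``control_points`` are (n,2) row/col handle positions (n >= 3) and
    ``displacements`` their (n,2) shifts.  The image is sampled bilinearly and
    the mask with nearest-neighbour, so the mask stays binary.
    """
    control_points = np.atleast_2d(control_points)
    if control_points.shape[0] < 3:
        raise ValueError("rigid MLS needs at least 3 control points")
    coords = _mls_backward_coords(mask.shape, control_points, displacements)
    warped_mask = _map_coords(np.asarray(mask, dtype=np.uint8), coords, order=0)
    warped_img = _map_coords(np.asarray(image, dtype=np.float64), coords, order=1)
    return warped_img.astype(image.dtype, copy=False), warped_mask


def _map_coords(arr, coords, order):
    if arr.ndim == 2:
        return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")
    out = np.stack([
        ndimage.map_coordinates(arr[..., ch], coords, order=order, mode="nearest")
        for ch in range(arr.shape[-1])
    ], axis=-1)
    return out


# ---------------------------------------------------------------------------
# replayable geometric steps (2-D arrays; images apply them channel-wise)
# ---------------------------------------------------------------------------

def _crop_padded(arr, box):
    """Crop ``arr`` to ``box`` (r0, r1, c0, c1; may exceed the frame) with
    zero padding outside."""
    r0, r1, c0, c1 = box
    out = np.zeros((r1 - r0, c1 - c0) + arr.shape[2:], dtype=arr.dtype)
    sr0, sr1 = max(r0, 0), min(r1, arr.shape[0])
    sc0, sc1 = max(c0, 0), min(c1, arr.shape[1])
    if sr0 < sr1 and sc0 < sc1:
        out[sr0 - r0: sr1 - r0, sc0 - c0: sc1 - c0] = arr[sr0:sr1, sc0:sc1]
    return out


def apply_step(arr: np.ndarray, step: dict, order: int) -> np.ndarray:
    """Apply one recorded geometric step to an (H,W) or (H,W,C) array with the
    given interpolation order (0 = nearest for masks, 1 = bilinear for
    images); channels transform jointly."""
    op = step["op"]
    if op == "gt_crop_skipped":
        return arr  # recorded for provenance; geometric no-op
    if op == "hflip":
        return arr[:, ::-1]
    if op == "vflip":
        return arr[::-1, :]
    if op == "crop":
        return _crop_padded(arr, step["box"])
    if op == "rotate":
        return ndimage.rotate(arr.astype(np.float64), step["angle"], reshape=False,
                              order=order, mode="constant", cval=0.0, axes=(0, 1),
                              prefilter=False).astype(arr.dtype, copy=False)
    if op == "mls":
        coords = _mls_backward_coords(arr.shape[:2], step["points"],
                                      step["displacements"])
        return _map_coords(arr, coords, order=order)
    if op == "resize":
        s = step["size"]
        return sk_resize(arr, (s, s) + arr.shape[2:], order=order,
                         anti_aliasing=False, preserve_range=True).astype(
                             arr.dtype if order == 0 else np.float64, copy=False)
    raise ValueError(f"unknown step {op!r}")


def replay_transforms(arr: np.ndarray, transforms: list, order: int) -> np.ndarray:
    """Replay a recorded transform path on an arbitrary 2-D array."""
    for step in transforms:
        arr = apply_step(arr, step, order)
    return arr


def _draw_steps(mask, cfg: AugmentConfig, rng: np.random.Generator) -> list:
    h, w = mask.shape
    steps = []
    if cfg.hflip and rng.random() < 0.5:
        steps.append({"op": "hflip"})
    if cfg.vflip and rng.random() < 0.5:
        steps.append({"op": "vflip"})
    lo, hi = cfg.crop_scale
    s = rng.uniform(lo, hi)
    ch, cw = max(1, round(h * s)), max(1, round(w * s))
    r0, c0 = (h - ch) // 2, (w - cw) // 2
    steps.append({"op": "crop", "box": (r0, r0 + ch, c0, c0 + cw)})
    steps.append({"op": "rotate", "angle": float(rng.uniform(-cfg.rotate_degrees,
                                                             cfg.rotate_degrees))})
    return steps


def _gt_crop_box(mask, pad):
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    return (int(r0) - pad, int(r1) + 1 + pad, int(c0) - pad, int(c1) + 1 + pad)


def augment_train(sample: ImageSample, cfg: AugmentConfig, input_size: int,
                  rng_seed: int) -> ImageSample:
    """One randomized augmentation draw; fully reproducible from ``rng_seed``."""
    rng = np.random.default_rng(rng_seed)
    image = np.moveaxis(sample.image, 0, -1).astype(np.float64)
    mask = sample.mask.astype(np.uint8)

    steps = _draw_steps(mask, cfg, rng)
    for step in steps:
        mask = apply_step(mask, step, order=0)
        image = apply_step(image, step, order=1)

    record = list(steps)
    # ground-truth bounding-box crop, expanded and zero-padded
    if mask.any():
        step = {"op": "crop", "box": _gt_crop_box(mask, cfg.gt_crop_pad)}
        mask = apply_step(mask, step, order=0)
        image = apply_step(image, step, order=1)
        record.append(step)
    else:
        record.append({"op": "gt_crop_skipped"})

    if cfg.mls_warp and mask.size:
        g = cfg.mls_grid
        h, w = mask.shape
        ry = np.linspace(0, h - 1, g)
        cx = np.linspace(0, w - 1, g)
        pts = np.stack(np.meshgrid(ry, cx, indexing="ij"), axis=-1).reshape(-1, 2)
        amp = cfg.mls_max_shift * min(h, w)
        disp = rng.uniform(-amp, amp, size=pts.shape)
        step = {"op": "mls", "points": pts, "displacements": disp}
        image, mask = rigid_mls_warp(image, mask, pts, disp)
        record.append(step)

    step = {"op": "resize", "size": input_size}
    mask = apply_step(mask, step, order=0)
    image = apply_step(image, step, order=1)
    record.append(step)

    out = ImageSample.from_hwc(np.clip(image, 0.0, 1.0), mask,
                               transforms=sample.transforms + record)
    out.edge = derive_edge(out.mask, thickness=cfg.edge_thickness)
    return out


def resize_sample(sample: ImageSample, input_size: int,
                  edge_thickness: int = 2) -> ImageSample:
    """Resize-only path (augmentation disabled / evaluation)."""
    step = {"op": "resize", "size": input_size}
    image = np.moveaxis(sample.image, 0, -1).astype(np.float64)
    mask = apply_step(sample.mask.astype(np.uint8), step, order=0)
    image = apply_step(image, step, order=1)
    out = ImageSample.from_hwc(np.clip(image, 0.0, 1.0), mask,
                               transforms=sample.transforms + [step])
    out.edge = derive_edge(out.mask, thickness=edge_thickness)
    return out
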