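"""Edge ground truth derivation and test-time augmentation (TTA).

The edge target is never annotated: it is recovered from the segmentation
mask as a thin morphological gradient band around the mask contour, so no
extra labelling is required for the auxiliary task.

TTA applies the six axis-aligned dihedral transforms (identity, three
rotations, two flips), predicts each transformed copy, maps every prediction
back through the exact inverse transform, and averages pixel-wise.  Because
the transforms are axis-aligned the inverses are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross


def derive_edge(mask: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Binary contour band of ``mask``: dilation XOR erosion with a 3x3 cross.

    ``thickness`` controls the band width in pixels (outward iterations =
    ``thickness // 2``, inward = ``(thickness + 1) // 2``); ``thickness=1``
    yields the inner one-pixel boundary.  An empty mask has an empty edge; a
    full-frame mask has its edge along the image border (erosion shrinks from
    the frame).
    """
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be strictly binary (0/1)")
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    m = m.astype(bool)
    out_it = thickness // 2
    in_it = (thickness + 1) // 2
    grown = ndimage.binary_dilation(m, CROSS, iterations=out_it) if out_it else m
    core = ndimage.binary_erosion(m, CROSS, iterations=in_it, border_value=0)
    return (grown & ~core).astype(np.uint8)


# ---------------------------------------------------------------------------
# test-time augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTATransform:
    """An axis-aligned transform with its exact inverse (last two axes)."""

    name: str
    forward: callable
    inverse: callable


def _rot(k):
    return lambda a: np.rot90(a, k, axes=(-2, -1))


TTA_TRANSFORMS = (
    TTATransform("identity", lambda a: a, lambda a: a),
    TTATransform("rot90", _rot(1), _rot(-1)),
    TTATransform("rot180", _rot(2), _rot(-2)),
    TTATransform("rot270", _rot(3), _rot(-3)),
    TTATransform("hflip", lambda a: a[..., ::-1], lambda a: a[..., ::-1]),
    TTATransform("vflip", lambda a: a[..., ::-1, :], lambda a: a[..., ::-1, :]),
)


def predict_tta(predict_fn, images: np.ndarray) -> np.ndarray:
    """Average of inverse-mapped predictions over the six TTA transforms.

    ``predict_fn`` maps a (N,3,S,S) batch to (N,S,S) probabilities.
    """
    images = np.asarray(images)
    acc = None
    for t in TTA_TRANSFORMS:
        pred = predict_fn(np.ascontiguousarray(t.forward(images)))
        pred = t.inverse(pred)
        acc = pred.copy() if acc is None else acc + pred
    return acc / len(TTA_TRANSFORMS)
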