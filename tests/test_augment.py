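"""Geometric augmentation: determinism, alignment, MLS warp properties."""

import numpy as np
import pytest

from lesionseg.augment import (
    ImageSample,
    augment_train,
    mls_rigid_transform,
    replay_transforms,
    resize_sample,
    rigid_mls_warp,
)
from lesionseg.config import AugmentConfig
from lesionseg.metrics import jaccard
from lesionseg.synth import SynthSpec, generate_sample

CFG = AugmentConfig(gt_crop_pad=11)


@pytest.fixture(scope="module")
def sample():
    return generate_sample(SynthSpec.easy(image_size=96, seed=7))


def test_seeded_determinism(sample):
    a = augment_train(sample, CFG, 64, rng_seed=123)
    b = augment_train(sample, CFG, 64, rng_seed=123)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.mask, b.mask)
    np.testing.assert_array_equal(a.edge, b.edge)


def test_different_seeds_differ(sample):
    a = augment_train(sample, CFG, 64, rng_seed=1)
    b = augment_train(sample, CFG, 64, rng_seed=2)
    assert np.abs(a.image - b.image).max() > 0


def test_output_contract(sample):
    out = augment_train(sample, CFG, 64, rng_seed=5)
    assert out.image.shape == (3, 64, 64)
    assert out.mask.shape == (64, 64)
    assert set(np.unique(out.mask)) <= {0, 1}
    assert set(np.unique(out.edge)) <= {0, 1}
    assert out.image.min() >= 0 and out.image.max() <= 1


def test_resize_only_path_keeps_mask_binary(sample):
    out = resize_sample(sample, 64)
    assert out.mask.shape == (64, 64)
    assert set(np.unique(out.mask)) <= {0, 1}
    assert len(out.transforms) == 1


def test_hflip_is_involution(sample):
    step = {"op": "hflip"}
    twice = replay_transforms(sample.mask, [step, step], order=0)
    np.testing.assert_array_equal(twice, sample.mask)


def test_geometric_consistency_mask_replay(sample):
    """Replaying the recorded transform path on the original mask reproduces
    the augmented mask exactly (image and mask share one geometric path)."""
    for seed in range(5):
        out = augment_train(sample, CFG, 64, rng_seed=seed)
        replayed = replay_transforms(sample.mask.astype(np.uint8),
                                     out.transforms, order=0)
        assert jaccard(replayed, out.mask) == 1.0


def test_empty_mask_skips_gt_crop():
    img = np.random.default_rng(0).random((3, 64, 64)).astype(np.float32)
    empty = ImageSample(image=img, mask=np.zeros((64, 64), dtype=np.uint8))
    out = augment_train(empty, CFG, 64, rng_seed=0)
    assert {"op": "gt_crop_skipped"} in out.transforms
    assert out.mask.sum() == 0


class TestRigidMLS:
    def test_zero_displacement_is_identity(self, sample):
        img = np.moveaxis(sample.image, 0, -1)
        pts = np.array([[10.0, 10.0], [10.0, 80.0], [80.0, 10.0], [80.0, 80.0]])
        wimg, wmask = rigid_mls_warp(img, sample.mask, pts, np.zeros_like(pts))
        np.testing.assert_allclose(wimg, img, atol=1e-7)
        np.testing.assert_array_equal(wmask, sample.mask)

    def test_uniform_translation_of_handles_translates_image(self):
        """All handles sharing one shift ⇒ the warp is exactly that global
        translation (rigid MLS reproduces global rigid motions)."""
        rng = np.random.default_rng(3)
        img = rng.random((40, 40))
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[10:25, 12:28] = 1
        pts = np.array([[5.0, 5.0], [5.0, 34.0], [34.0, 5.0], [34.0, 34.0], [20.0, 20.0]])
        shift = np.array([3.0, -2.0])
        disp = np.tile(shift, (len(pts), 1))
        _, wmask = rigid_mls_warp(img, mask, pts, disp)
        expect = np.roll(np.roll(mask, 3, axis=0), -2, axis=1)
        # compare away from the frame where roll wraps but warp clamps
        assert (wmask[5:-5, 5:-5] == expect[5:-5, 5:-5]).all()
        # and the analytic map itself is exact everywhere
        v = rng.uniform(5, 35, size=(50, 2))
        out = mls_rigid_transform(v, pts + disp, pts)
        np.testing.assert_allclose(out, v - shift, atol=1e-6)

    def test_too_few_control_points_rejected(self, sample):
        img = np.moveaxis(sample.image, 0, -1)
        with pytest.raises(ValueError, match="3 control points"):
            rigid_mls_warp(img, sample.mask, np.array([[1.0, 1.0], [2.0, 2.0]]),
                           np.zeros((2, 2)))

    def test_random_warp_keeps_mask_binary_and_area_stable(self, sample):
        """Moderate handle jitter must not destroy the lesion: the mask stays
        binary and its area moves by less than 20% across seeds."""
        img = np.moveaxis(sample.image, 0, -1)
        base_area = int(sample.mask.sum())
        g = np.linspace(0, 95, 4)
        pts = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1).reshape(-1, 2)
        for seed in range(8):
            rng = np.random.default_rng(seed)
            disp = rng.uniform(-4.8, 4.8, size=pts.shape)  # 5% of the 96-px side
            _, wmask = rigid_mls_warp(img, sample.mask, pts, disp)
            assert set(np.unique(wmask)) <= {0, 1}
            assert abs(int(wmask.sum()) - base_area) / base_area < 0.20
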