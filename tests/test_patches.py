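"""Patch sampling and the rotation/flip/translation augmentation family."""

import numpy as np
import pytest

from fundustriage.patches import (PatchSample, _apply_transform,
                                  augment_images, build_patch_dataset)
from fundustriage.types import FundusImage, OpticDiscBox


def _images(n, size=96, seed=0):
    rng = np.random.default_rng(seed)
    imgs = [FundusImage(rng.integers(0, 256, (size, size, 3), dtype=np.uint8))
            for _ in range(n)]
    masks = [rng.random((size, size)) > 0.7 for _ in range(n)]
    return imgs, masks


def test_dataset_size_is_images_times_base_times_multiplier():
    imgs, masks = _images(2)
    out = build_patch_dataset(imgs, masks, n_base_patches=5, patch_size=48,
                              aug_multiplier=3, seed=0)
    assert len(out) == 2 * 5 * 3
    assert all(s.image.shape == (48, 48, 3) for s in out)
    assert all(s.mask.shape == (48, 48) for s in out)


def test_augment_index_zero_is_a_verbatim_crop():
    imgs, masks = _images(1)
    out = build_patch_dataset(imgs, masks, n_base_patches=4, patch_size=32,
                              aug_multiplier=2, seed=5)
    pix = imgs[0].pixels
    for s in out:
        if s.augment_index == 0:
            # the crop must appear verbatim somewhere in the source image
            found = any(
                np.array_equal(pix[r:r + 32, c:c + 32], s.image)
                for r in range(0, 96 - 32 + 1)
                for c in range(0, 96 - 32 + 1))
            assert found


def test_augment_false_gives_all_verbatim():
    imgs, masks = _images(1)
    out = build_patch_dataset(imgs, masks, n_base_patches=3, patch_size=32,
                              aug_multiplier=4, seed=1, augment=False)
    by_base = {}
    for s in out:
        by_base.setdefault(s.base_index, []).append(s)
    for samples in by_base.values():
        first = samples[0]
        for s in samples[1:]:
            assert np.array_equal(s.image, first.image)
            assert np.array_equal(s.mask, first.mask)


def test_deterministic_for_fixed_seed():
    imgs, masks = _images(2)
    a = build_patch_dataset(imgs, masks, 3, 48, 3, seed=9)
    b = build_patch_dataset(imgs, masks, 3, 48, 3, seed=9)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.image, sb.image)
        assert np.array_equal(sa.mask, sb.mask)


def test_patch_larger_than_image_raises():
    imgs, masks = _images(1, size=40)
    with pytest.raises(ValueError):
        build_patch_dataset(imgs, masks, 1, 64, 1, seed=0)


def test_misaligned_mask_raises():
    imgs, _ = _images(1, size=64)
    with pytest.raises(ValueError):
        build_patch_dataset(imgs, [np.zeros((32, 32), bool)], 1, 16, 1, seed=0)


def test_transform_preserves_central_mask_area():
    # a centred disk stays inside the frame under any transform of the
    # family (rotation <= 60 deg, flips, translation <= 5 px), so its pixel
    # count is conserved up to nearest-neighbour discretisation of the rim
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    yy, xx = np.mgrid[:64, :64]
    mask = (yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 10 ** 2
    img[mask] = 200
    for angle in (-60.0, -30.0, 0.0, 45.0, 60.0):
        for tx, ty in ((0.0, 0.0), (5.0, -5.0), (-3.0, 4.0)):
            params = {"angle_deg": angle, "flip_h": angle > 0,
                      "flip_v": tx < 0, "tx": tx, "ty": ty}
            _, warped = _apply_transform(img, mask, params)
            assert abs(int(warped.sum()) - int(mask.sum())) <= \
                0.05 * mask.sum()


def test_image_and_mask_receive_the_same_transform():
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    yy, xx = np.mgrid[:64, :64]
    mask = (yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 8 ** 2
    img[mask] = 255
    params = {"angle_deg": 30.0, "flip_h": True, "flip_v": False,
              "tx": 3.0, "ty": -2.0}
    out_img, out_mask = _apply_transform(img, mask, params)
    bright = out_img[..., 0] > 127
    # the warped bright blob and warped mask coincide up to edge smoothing
    assert np.logical_xor(bright, out_mask).sum() < 0.1 * mask.sum()


def test_augment_images_counts_and_verbatim_head():
    rng = np.random.default_rng(2)
    imgs = [FundusImage(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8))
            for _ in range(5)]
    out = augment_images(imgs, multiplier=10, seed=0)
    assert len(out) == 50
    for k in range(5):
        first, _ = out[k * 10]
        assert np.array_equal(first.pixels, imgs[k].pixels)


def test_augment_images_transforms_boxes_consistently():
    # a bright square at a known box; after augmentation the transformed box
    # must still cover most of the bright pixels
    img = np.zeros((96, 96, 3), dtype=np.uint8)
    img[40:56, 30:46] = 255
    box = OpticDiscBox(x=30, y=40, w=16, h=16)
    out = augment_images([FundusImage(img)], multiplier=8, seed=3,
                         boxes=[box])
    for aug_img, aug_box in out:
        bright = aug_img.pixels[..., 0] > 127
        if bright.sum() == 0:
            continue  # pushed off-frame by the transform
        rows, cols = np.nonzero(bright)
        inside = ((cols >= aug_box.x - 1) & (cols <= aug_box.x + aug_box.w + 1)
                  & (rows >= aug_box.y - 1) & (rows <= aug_box.y + aug_box.h + 1))
        assert inside.mean() > 0.95


def test_augment_images_validation():
    with pytest.raises(ValueError):
        augment_images([], multiplier=2, seed=0)
    rng = np.random.default_rng(0)
    img = FundusImage(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        augment_images([img], multiplier=0, seed=0)
    with pytest.raises(ValueError):
        augment_images([img], multiplier=2, seed=0, boxes=[])
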