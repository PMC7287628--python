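"""Patch sampling and geometric augmentation for training the segmenters.

The artefact segmenter is trained on randomly placed 224x224 patches, the
vessel segmenter on 256x256 patches; each image's base patches are expanded
by a fixed multiplier through random rotation in [-60, 60] degrees, random
horizontal/vertical reflection and random translation of up to 5 px, with
image and mask receiving the identical transform.  The same augmentation
family expands whole thumbnail images (plus their boxes) for the detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import FundusImage, OpticDiscBox

__all__ = ["PatchSample", "build_patch_dataset", "augment_images"]

_ROTATION_RANGE_DEG = 60.0
_TRANSLATION_RANGE_PX = 5.0


@dataclass(frozen=True)
class PatchSample:
    """One (image patch, mask patch) pair with its provenance."""

    image: np.ndarray       # (P, P, 3) uint8
    mask: np.ndarray        # (P, P) bool
    source_index: int       # which base image
    base_index: int         # which base patch within that image
    augment_index: int      # 0 = verbatim crop


def _random_params(rng: np.random.Generator) -> dict:
    return {
        "angle_deg": float(rng.uniform(-_ROTATION_RANGE_DEG, _ROTATION_RANGE_DEG)),
        "flip_h": bool(rng.random() < 0.5),
        "flip_v": bool(rng.random() < 0.5),
        "tx": float(rng.uniform(-_TRANSLATION_RANGE_PX, _TRANSLATION_RANGE_PX)),
        "ty": float(rng.uniform(-_TRANSLATION_RANGE_PX, _TRANSLATION_RANGE_PX)),
    }


def _apply_transform(image: np.ndarray, mask: Optional[np.ndarray],
                     params: dict) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Rotate about the centre, reflect, translate; mask uses nearest-neighbour."""
    img = image
    msk = mask
    if params["flip_h"]:
        img = img[:, ::-1]
        msk = msk[:, ::-1] if msk is not None else None
    if params["flip_v"]:
        img = img[::-1]
        msk = msk[::-1] if msk is not None else None
    h, w = img.shape[:2]
    # rotation about the centre plus translation, expressed in (row, col)
    # coordinates as the inverse map required by affine_transform
    theta = np.deg2rad(params["angle_deg"])
    rot = np.array([[np.cos(theta), np.sin(theta)],
                    [-np.sin(theta), np.cos(theta)]])  # (row, col) rotation
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([params["ty"], params["tx"]])
    rot_inv = rot.T
    offset = centre - rot_inv @ (centre + shift)
    out_img = np.empty_like(img)
    src = np.ascontiguousarray(img, dtype=np.float32)
    for ch in range(img.shape[2]):
        warped = ndimage.affine_transform(src[..., ch], rot_inv, offset=offset,
                                          order=1, mode="constant", cval=0.0)
        out_img[..., ch] = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    out_msk = None
    if msk is not None:
        out_msk = ndimage.affine_transform(msk.astype(np.uint8), rot_inv,
                                           offset=offset, order=0,
                                           mode="constant", cval=0) > 0
    return out_img, out_msk


def build_patch_dataset(images: Sequence[FundusImage],
                        masks: Sequence[np.ndarray],
                        n_base_patches: int,
                        patch_size: int,
                        aug_multiplier: int,
                        seed: int,
                        augment: bool = True) -> list[PatchSample]:
    """Sample and augment training patches.

    Samples ``n_base_patches`` uniformly placed patches per image, then emits
    ``aug_multiplier`` variants of each (index 0 is the verbatim crop; with
    ``augment=False`` every variant is verbatim).  Output size is therefore
    ``len(images) * n_base_patches * aug_multiplier``.  Deterministic for a
    fixed seed.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must align")
    if len(images) == 0:
        raise ValueError("need at least one image")
    if n_base_patches < 1 or aug_multiplier < 1:
        raise ValueError("n_base_patches and aug_multiplier must be >= 1")
    out: list[PatchSample] = []
    for i, (img, mask) in enumerate(zip(images, masks)):
        pix = img.pixels
        h, w = pix.shape[:2]
        if patch_size > h or patch_size > w:
            raise ValueError(
                f"patch size {patch_size} exceeds image {i} dims {h}x{w}")
        if mask.shape != (h, w):
            raise ValueError(f"mask {i} dims {mask.shape} != image dims {(h, w)}")
        rng = np.random.default_rng([seed, i])
        rows = rng.integers(0, h - patch_size + 1, size=n_base_patches)
        cols = rng.integers(0, w - patch_size + 1, size=n_base_patches)
        for b, (r, c) in enumerate(zip(rows, cols)):
            crop = pix[r:r + patch_size, c:c + patch_size]
            mcrop = mask[r:r + patch_size, c:c + patch_size]
            for k in range(aug_multiplier):
                if k == 0 or not augment:
                    out.append(PatchSample(crop.copy(), mcrop.copy(), i, b, k))
                else:
                    pi, pm = _apply_transform(crop, mcrop, _random_params(rng))
                    out.append(PatchSample(pi, pm, i, b, k))
    return out


def augment_images(images: Sequence[FundusImage],
                   multiplier: int,
                   seed: int,
                   boxes: Optional[Sequence[OpticDiscBox]] = None,
                   ) -> list[tuple[FundusImage, Optional[OpticDiscBox]]]:
    """Expand whole images by the augmentation family (detector training set).

    Each base image yields ``multiplier`` variants (index 0 verbatim), so
    1288 thumbnails become 12,880 images at multiplier 10.  When ``boxes``
    are given, each box's corners are pushed through the same transform and
    re-enclosed in an axis-aligned box.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    if boxes is not None and len(boxes) != len(images):
        raise ValueError("boxes must align with images")
    out: list[tuple[FundusImage, Optional[OpticDiscBox]]] = []
    for i, img in enumerate(images):
        rng = np.random.default_rng([seed, i])
        box = boxes[i] if boxes is not None else None
        for k in range(multiplier):
            if k == 0:
                out.append((img, box))
                continue
            params = _random_params(rng)
            pix, _ = _apply_transform(img.pixels, None, params)
            new_box = _transform_box(box, img.pixels.shape[:2], params) \
                if box is not None else None
            out.append((FundusImage(pix, eye_side=img.eye_side), new_box))
    return out


def _transform_box(box: OpticDiscBox, shape: tuple[int, int],
                   params: dict) -> OpticDiscBox:
    h, w = shape
    corners = np.array([[box.x, box.y], [box.x + box.w, box.y],
                        [box.x, box.y + box.h], [box.x + box.w, box.y + box.h]])
    if params["flip_h"]:
        corners[:, 0] = (w - 1) - corners[:, 0]
    if params["flip_v"]:
        corners[:, 1] = (h - 1) - corners[:, 1]
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    angle = np.deg2rad(params["angle_deg"])
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    moved = (corners - centre) @ rot.T + centre + np.array(
        [params["tx"], params["ty"]])
    x0, y0 = moved.min(axis=0)
    x1, y1 = moved.max(axis=0)
    return OpticDiscBox(x=float(x0), y=float(y0), w=float(x1 - x0),
                        h=float(y1 - y0), prob=box.prob)
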