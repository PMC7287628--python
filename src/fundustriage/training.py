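"""Convenience routines that train the default backends on phantoms.

These wire the synthetic generator to the backends so a full, trained
pipeline can be produced from a single seed: the detector learns from
phantom OD boxes, the quality classifier from sharp versus blurred OD
crops, the retina segmenter from retina/artefact ground truth and the
vessel segmenter from vessel ground truth.  Problem sizes are desk-scale
(a few dozen phantoms, minutes of CPU).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .backends import (BlobDetector, SgdCropClassifier, SgdPixelSegmenter,
                       TrainConfig)
from .distort import DistortionKind, DistortionSpec, apply_distortion
from .patches import build_patch_dataset
from .quality import extract_od_crop
from .synthetic import ArtefactKind, default_spec, generate_fundus
from .types import EyeSide, FundusImage

__all__ = [
    "make_phantoms",
    "train_detector",
    "train_quality_classifier",
    "train_retina_segmenter",
    "train_vessel_segmenter",
    "train_default_backends",
    "BLUR_SHARP_SIGMA_MAX",
    "BLUR_BAD_SIGMA_MIN",
]

# Synthetic clarity-label protocol: crops blurred with sigma in the sharp
# range are labelled good, those at or beyond the bad range are labelled
# inadequate (clinically, labelling is done by ophthalmologists; the sigma
# cutoffs stand in for that judgement on phantoms).
BLUR_SHARP_SIGMA_MAX = 3.5
BLUR_BAD_SIGMA_MIN = 14.0


def make_phantoms(n: int, seed: int, *, artefact_kind=ArtefactKind.NONE,
                  coverage: float = 0.0, include_od: bool = True,
                  alternate_sides: bool = True):
    """n phantoms with alternating eye sides and consecutive sub-seeds."""
    out = []
    for i in range(n):
        side = EyeSide.LEFT if (i % 2 == 0 or not alternate_sides) \
            else EyeSide.RIGHT
        spec = default_spec(seed=seed * 100_003 + i, eye_side=side,
                            artefact_kind=artefact_kind,
                            artefact_coverage_target=coverage,
                            include_od=include_od)
        out.append(generate_fundus(spec))
    return out


def train_detector(seed: int, n_phantoms: int = 24,
                   config: Optional[TrainConfig] = None) -> BlobDetector:
    """Detector trained on sharp and blurred phantoms.

    Blurred positives are included because detection must still succeed on
    out-of-focus frames — stage 2 (clarity), not stage 1, is where blur is
    supposed to fail an image.
    """
    pairs = make_phantoms(n_phantoms, seed)
    images = [img for img, _ in pairs]
    boxes = [gt.od_box for _, gt in pairs]
    rng = np.random.default_rng(seed)
    for img, gt in pairs:
        sigma = float(rng.choice([7.0, 14.0, 17.5]))
        blurred = apply_distortion(
            img, DistortionSpec(kind=DistortionKind.BLUR, sigma=sigma))
        images.append(blurred)
        boxes.append(gt.od_box)
    return BlobDetector(seed=seed).fit(images, boxes, config)


def od_quality_crops(seed: int, n_phantoms: int = 30
                     ) -> tuple[list[np.ndarray], list[int]]:
    """Sharp (label 1) and blurred (label 0) OD crops from phantoms.

    A third of the phantoms carry eyelash occluders so the classifier learns
    that clarity, not occlusion, is what stage 2 judges (obstruction is
    stage 3's job).
    """
    crops, labels = [], []
    rng = np.random.default_rng(seed)
    phantoms = make_phantoms(n_phantoms - n_phantoms // 3, seed)
    phantoms += make_phantoms(n_phantoms // 3, seed + 13,
                              artefact_kind=ArtefactKind.EYELASH,
                              coverage=0.3)
    for img, gt in phantoms:
        sharp_sigma = float(rng.choice([0.0, 3.5]))
        bad_sigma = float(rng.choice([14.0, 17.5, 21.0]))
        for sigma, label in ((sharp_sigma, 1), (bad_sigma, 0)):
            if sigma > 0:
                blurred = apply_distortion(
                    img, DistortionSpec(kind=DistortionKind.BLUR, sigma=sigma))
            else:
                blurred = img
            # jitter the box like an imperfect detector would place it
            box = _jitter_box(gt.od_box, rng)
            crops.append(extract_od_crop(blurred, box))
            labels.append(label)
    return crops, labels


def _jitter_box(box, rng: np.random.Generator):
    from .types import OpticDiscBox
    scale = float(rng.uniform(0.85, 1.2))
    dx = float(rng.uniform(-0.15, 0.15)) * box.w
    dy = float(rng.uniform(-0.15, 0.15)) * box.h
    w, h = box.w * scale, box.h * scale
    return OpticDiscBox(x=box.x + dx + (box.w - w) / 2,
                        y=box.y + dy + (box.h - h) / 2,
                        w=w, h=h, prob=box.prob)


def train_quality_classifier(seed: int, n_phantoms: int = 30,
                             config: Optional[TrainConfig] = None
                             ) -> SgdCropClassifier:
    crops, labels = od_quality_crops(seed, n_phantoms)
    return SgdCropClassifier(seed=seed).fit(crops, labels, config)


def train_retina_segmenter(seed: int, n_phantoms: int = 8,
                           n_base_patches: int = 12, patch_size: int = 96,
                           config: Optional[TrainConfig] = None
                           ) -> SgdPixelSegmenter:
    """Retina-vs-rest segmenter from phantoms with eyelash/eyelid occluders."""
    pairs = []
    for i in range(n_phantoms):
        kind = ArtefactKind.EYELASH if i % 2 == 0 else ArtefactKind.EYELID
        spec = default_spec(seed=seed * 200_003 + i, artefact_kind=kind,
                            artefact_coverage_target=0.25)
        pairs.append(generate_fundus(spec))
    images = [img for img, _ in pairs]
    masks = [gt.retina_mask for _, gt in pairs]
    samples = build_patch_dataset(images, masks, n_base_patches, patch_size,
                                  aug_multiplier=2, seed=seed)
    return SgdPixelSegmenter(use_ridge=False, seed=seed).fit(
        [s.image for s in samples], [s.mask for s in samples], config)


def train_vessel_segmenter(seed: int, n_phantoms: int = 8,
                           n_base_patches: int = 12, patch_size: int = 96,
                           config: Optional[TrainConfig] = None
                           ) -> SgdPixelSegmenter:
    pairs = make_phantoms(n_phantoms, seed + 7)
    images = [img for img, _ in pairs]
    masks = [gt.vessel_mask for _, gt in pairs]
    samples = build_patch_dataset(images, masks, n_base_patches, patch_size,
                                  aug_multiplier=2, seed=seed)
    return SgdPixelSegmenter(use_ridge=True, seed=seed).fit(
        [s.image for s in samples], [s.mask for s in samples], config)


def train_default_backends(seed: int):
    """A fully trained :class:`~fundustriage.workflow.BackendSet`."""
    from .workflow import BackendSet
    return BackendSet(
        detector=train_detector(seed),
        quality=train_quality_classifier(seed),
        retina=train_retina_segmenter(seed),
        vessel=train_vessel_segmenter(seed),
    )
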