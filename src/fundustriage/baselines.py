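"""Training-free backend adapters.

These wrap the deterministic baseline operations (bright-blob OD detection,
gradient-energy sharpness, colour-rule retina segmentation, ridge-filter
vessel segmentation) behind the trainable-backend contracts, so the whole
pipeline can run with no fitting step.  They exist for tests, for quick
smoke runs, and as a sanity cross-check against the trained defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import _ridge_response
from .detection import baseline_detect
from .quality import sharpness_baseline
from .types import FundusImage, OpticDiscBox, as_rgb8
from .vessels import _RIDGE_THRESHOLD

__all__ = [
    "BaselineDetector",
    "SharpnessQualityClassifier",
    "ColorRuleRetinaSegmenter",
    "RidgeVesselSegmenter",
    "baseline_backend_set",
]


@dataclass
class BaselineDetector:
    """Detector contract over the bright-blob + vessel-texture baseline."""

    def fit(self, images, boxes, config=None):
        return self  # nothing to train

    def predict(self, image: FundusImage) -> list[tuple[OpticDiscBox, float]]:
        box = baseline_detect(image)
        return [(box, box.prob)]


@dataclass
class SharpnessQualityClassifier:
    """Good-quality probability from gradient-energy sharpness.

    Maps the sharpness score s through 1 - exp(-s / s0); ``scale`` (s0) is
    calibrated on the phantom design so an undistorted OD crop scores well
    above 0.95 while moderate Gaussian blur drops it below.
    """

    scale: float = 2.5e-4

    def fit(self, crops, labels, config=None):
        return self

    def predict(self, crop: np.ndarray) -> float:
        s = sharpness_baseline(crop)
        return float(np.clip(1.0 - np.exp(-s / self.scale), 0.0, 1.0))


@dataclass
class ColorRuleRetinaSegmenter:
    """Real-retina probability from fixed colour rules.

    The retinal field is reddish (R well above B); eyelashes and the black
    surround are dark and desaturated; an eyelid is skin-coloured (high green
    and blue alongside red).  Pixels matching an occluder rule get
    probability 0.05, others 0.95.
    """

    def fit(self, patches, masks, config=None):
        return self

    def predict(self, image: np.ndarray) -> np.ndarray:
        rgb = as_rgb8(image).astype(float)
        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
        brightest = rgb.max(axis=-1)
        spread = rgb.max(axis=-1) - rgb.min(axis=-1)
        dark = (brightest < 50) & (spread < 25)
        skin = (g > 110) & (b > 85) & (r > g)
        retina = ~(dark | skin)
        return np.where(retina, 0.95, 0.05)


@dataclass
class RidgeVesselSegmenter:
    """Vessel probability from the multi-scale dark-ridge response."""

    def fit(self, patches, masks, config=None):
        return self

    def predict(self, image: np.ndarray) -> np.ndarray:
        green = as_rgb8(image)[..., 1].astype(float) / 255.0
        response = _ridge_response(green, sigmas=(1.0, 1.5, 2.5))
        return np.where(response > _RIDGE_THRESHOLD, 1.0, 0.0)


def baseline_backend_set():
    """The four training-free backends, ready for :mod:`fundustriage.workflow`."""
    from .workflow import BackendSet
    return BackendSet(detector=BaselineDetector(),
                      quality=SharpnessQualityClassifier(),
                      retina=ColorRuleRetinaSegmenter(),
                      vessel=RidgeVesselSegmenter())
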