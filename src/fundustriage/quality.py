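"""Stage 2: clarity grading of the detected optic-disc crop.

Because OD blur tracks whole-image blur, grading the small OD crop stands in
for grading the full frame.  A classifier backend emits a good-quality
probability which must strictly exceed ``th_oq`` (default 0.95) for the
image to continue through the pipeline.  ``sharpness_baseline`` provides a
deterministic gradient-energy score that decreases monotonically with
Gaussian blur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import ClassifierBackend
from .types import FundusImage, OpticDiscBox, as_rgb8

__all__ = ["QualityScore", "score_od_quality", "sharpness_baseline",
           "extract_od_crop"]


@dataclass(frozen=True)
class QualityScore:
    prob_good: float
    decision: str  # "good" | "bad"

    def to_json(self) -> dict:
        return {"prob_good": self.prob_good, "decision": self.decision}


def score_od_quality(crop: np.ndarray, backend: ClassifierBackend,
                     th_oq: float = 0.95) -> QualityScore:
    """Grade an OD crop: good iff the backend's probability > th_oq (strict)."""
    crop = as_rgb8(crop)
    if crop.shape[0] == 0 or crop.shape[1] == 0:
        raise ValueError("empty crop")
    p = float(backend.predict(crop))
    return QualityScore(prob_good=p, decision="good" if p > th_oq else "bad")


def sharpness_baseline(crop: np.ndarray) -> float:
    """Mean squared gradient magnitude of the green channel, per pixel.

    Zero for a constant crop; strictly decreasing under Gaussian blur of
    increasing sigma on any textured crop.
    """
    crop = as_rgb8(crop)
    if crop.shape[0] == 0 or crop.shape[1] == 0:
        raise ValueError("empty crop")
    green = crop[..., 1].astype(float) / 255.0
    gy, gx = np.gradient(green)
    return float(np.mean(gx ** 2 + gy ** 2))


def extract_od_crop(img: FundusImage, box: OpticDiscBox,
                    margin: float = 0.10) -> np.ndarray:
    """OD crop with a rim-context margin (fraction of box size) on each side."""
    h, w = img.height, img.width
    r0 = int(np.clip(np.floor(box.y - margin * box.h), 0, h - 1))
    r1 = int(np.clip(np.ceil(box.y + (1 + margin) * box.h), r0 + 1, h))
    c0 = int(np.clip(np.floor(box.x - margin * box.w), 0, w - 1))
    c1 = int(np.clip(np.ceil(box.x + (1 + margin) * box.w), c0 + 1, w))
    return img.pixels[r0:r1, c0:c1]
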