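"""Stage 1: optic-disc localisation and the presence decision.

A detector backend proposes boxes with confidences Pr(OD); the single
highest-confidence box is accepted as the OD when its probability strictly
exceeds ``th_od`` (default 0.9).  Images whose best candidate falls at or
below the threshold are treated as OD-free (outliers, closed eyes, or
diseases that efface the disc).

``baseline_detect`` is a deterministic, training-free fallback that exploits
two anatomical facts: the OD is the brightest compact blob in a fundus
image, and — unlike bright lesions — its interior is crossed by dark vessel
lines.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .backends import DetectorBackend, _gray, _ridge_response, propose_od_candidates
from .types import FundusImage, OpticDiscBox, RegionRect

__all__ = ["detect_od", "baseline_detect", "iou"]

RectLike = Union[RegionRect, OpticDiscBox, tuple]


def detect_od(img: FundusImage, backend: DetectorBackend,
              th_od: float = 0.9) -> Optional[OpticDiscBox]:
    """Return the best detection if its probability strictly exceeds th_od.

    Among all candidates the single highest-probability box wins (one OD per
    image); ties at the threshold are rejected.  Returns ``None`` when no
    candidate clears the threshold.
    """
    candidates = backend.predict(img)
    if not candidates:
        return None
    box, prob = max(candidates, key=lambda t: t[1])
    if prob > th_od:
        return box
    return None


# Calibration constants of the training-free confidence score: a real OD is
# both clearly brighter than its surround (contrast term) and crossed by dark
# vessel lines (ridge-texture term); each term saturates at 1 and the score
# is their product, so a bright blob without vessel texture scores low.
_CONTRAST_SCALE = 0.05
_TEXTURE_SCALE = 0.02


def baseline_detect(img: FundusImage) -> OpticDiscBox:
    """Training-free OD detector: brightest compact blob with vessel texture.

    Always returns a box; the confidence combines (a) how much brighter the
    blob is than its surround and (b) dark-line (vessel) evidence inside it,
    each clipped to [0, 1].  Blob-free images get a centred box with a low
    confidence.
    """
    g = _gray(img.pixels)
    h, w = g.shape
    candidates = propose_od_candidates(img)
    if not candidates:
        side = max(8.0, 0.07 * w)
        candidates = [OpticDiscBox(x=(w - side) / 2.0, y=(h - side) / 2.0,
                                   w=side, h=side, prob=1.0)]
    best: Optional[OpticDiscBox] = None
    best_p = -1.0
    for box in candidates:
        p = _baseline_confidence(g, box)
        if p > best_p:
            best_p = p
            best = box
    return OpticDiscBox(x=best.x, y=best.y, w=best.w, h=best.h, prob=best_p)


def _baseline_confidence(g: np.ndarray, box: OpticDiscBox) -> float:
    h, w = g.shape
    r0, r1 = int(max(0, box.y)), int(min(h, box.y + box.h))
    c0, c1 = int(max(0, box.x)), int(min(w, box.x + box.w))
    if r1 - r0 < 2 or c1 - c0 < 2:
        return 0.0
    inner = g[r0:r1, c0:c1]
    # surround: box grown by half its size, minus the box itself
    gr = int(round(box.h / 2)), int(round(box.w / 2))
    R0, R1 = max(0, r0 - gr[0]), min(h, r1 + gr[0])
    C0, C1 = max(0, c0 - gr[1]), min(w, c1 + gr[1])
    ring = g[R0:R1, C0:C1].copy()
    ring_mask = np.ones_like(ring, dtype=bool)
    ring_mask[r0 - R0:r1 - R0, c0 - C0:c1 - C0] = False
    surround = ring[ring_mask]
    contrast = (inner.mean() - surround.mean()) / 255.0 if surround.size else 0.0
    texture = float(_ridge_response(inner / 255.0).mean())
    score_c = float(np.clip(contrast / _CONTRAST_SCALE, 0.0, 1.0))
    score_t = float(np.clip(texture / _TEXTURE_SCALE, 0.0, 1.0))
    return score_c * score_t


def _as_xywh(r: RectLike) -> tuple[float, float, float, float]:
    if isinstance(r, RegionRect):
        return (r.x0, r.y0, r.w, r.h)
    if isinstance(r, OpticDiscBox):
        return (r.x, r.y, r.w, r.h)
    x, y, w, h = r
    return (float(x), float(y), float(w), float(h))


def iou(a: RectLike, b: RectLike) -> float:
    """Intersection-over-union of two axis-aligned rectangles, in [0, 1]."""
    ax, ay, aw, ah = _as_xywh(a)
    bx, by, bw, bh = _as_xywh(b)
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("rectangles must have positive area")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union
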