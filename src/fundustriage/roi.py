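"""ROI and macula geometry anchored on the optic-disc box.

Both rectangles are fixed multiples of the disc-diameter proxy DD.  With
(X, Y) the upper-left corner of the OD box:

* ROI: upper-left x = X - 0.5 DD (left eye) or X - 4.0 DD (right eye),
  y = Y - 2.5 DD; height 6.0 DD; width 5.5 DD.  It covers the OD, the
  superior and inferior vessel arcades and the macula.
* Macula: upper-left x = X + 2 DD (left) or X - 3 DD (right),
  y = Y - 0.5 DD; height 2.5 DD; width 2 DD.

Coordinates stay exact (fractional) until crop time; clipping against the
image border is explicit and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .types import EyeSide, OpticDiscBox, RegionRect

__all__ = ["EyeSideInfo", "compute_roi", "compute_macula", "infer_eye_side",
           "clip_to_image"]

ROI_HEIGHT_DD = 6.0
ROI_WIDTH_DD = 5.5
MACULA_HEIGHT_DD = 2.5
MACULA_WIDTH_DD = 2.0


@dataclass(frozen=True)
class EyeSideInfo:
    """Eye side together with how it was determined."""

    side: EyeSide
    source: str  # "metadata" | "inferred"


def _require_dd(box: OpticDiscBox) -> float:
    dd = box.dd
    if dd <= 0:
        raise ValueError(f"DD must be positive, got {dd}")
    return dd


def compute_roi(box: OpticDiscBox, side: EyeSide) -> RegionRect:
    """The diagnostic region of interest, in exact (unclipped) coordinates."""
    dd = _require_dd(box)
    x0 = box.x - 0.5 * dd if side is EyeSide.LEFT else box.x - 4.0 * dd
    y0 = box.y - 2.5 * dd
    return RegionRect(x0=x0, y0=y0, w=ROI_WIDTH_DD * dd, h=ROI_HEIGHT_DD * dd)


def compute_macula(box: OpticDiscBox, side: EyeSide) -> RegionRect:
    """The macular rectangle, temporal to the OD, in exact coordinates."""
    dd = _require_dd(box)
    x0 = box.x + 2.0 * dd if side is EyeSide.LEFT else box.x - 3.0 * dd
    y0 = box.y - 0.5 * dd
    return RegionRect(x0=x0, y0=y0, w=MACULA_WIDTH_DD * dd,
                      h=MACULA_HEIGHT_DD * dd)


def infer_eye_side(box: OpticDiscBox, image_width: int,
                   metadata_side: Optional[EyeSide] = None) -> EyeSideInfo:
    """Eye side from metadata when recorded, else from the OD position.

    In a fundus image the OD sits nasally, so an OD centre in the left half
    of the frame implies a left eye (macula extends rightward, inside the
    frame), and vice versa.
    """
    if metadata_side is not None:
        return EyeSideInfo(side=metadata_side, source="metadata")
    cx, _ = box.center
    side = EyeSide.LEFT if cx < image_width / 2.0 else EyeSide.RIGHT
    return EyeSideInfo(side=side, source="inferred")


def clip_to_image(rect: RegionRect, image_shape: tuple[int, int]) -> RegionRect:
    """Intersect with the image bounds; sets ``clipped`` if any edge moved.

    ``image_shape`` is (height, width).  Raises ``ValueError`` when the
    rectangle lies entirely outside the image.
    """
    h, w = image_shape
    x0 = max(rect.x0, 0.0)
    y0 = max(rect.y0, 0.0)
    x1 = min(rect.x1, float(w))
    y1 = min(rect.y1, float(h))
    if x1 <= x0 or y1 <= y0:
        raise ValueError("rectangle lies entirely outside the image")
    moved = (x0 != rect.x0 or y0 != rect.y0 or x1 != rect.x1 or y1 != rect.y1)
    return RegionRect(x0=x0, y0=y0, w=x1 - x0, h=y1 - y0,
                      clipped=rect.clipped or moved)
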