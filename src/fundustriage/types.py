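"""Shared domain types for the triage pipeline.

Conventions used throughout the package:

* images are 8-bit RGB ``numpy`` arrays of shape ``(H, W, 3)``;
* binary masks are boolean arrays of shape ``(H, W)``;
* pixel coordinates are 0-based, ``x`` rightward (columns), ``y`` downward
  (rows); rectangles are half-open, ``[x, x + w) x [y, y + h)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "EyeSide",
    "FundusImage",
    "OpticDiscBox",
    "RegionRect",
    "Thresholds",
    "as_rgb8",
]


class EyeSide(str, enum.Enum):
    """Which eye the image shows; fixes the temporal direction of the macula."""

    LEFT = "left"
    RIGHT = "right"


def as_rgb8(arr: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit RGB raster.

    Raises ``ValueError`` for anything that is not an ``(H, W, 3)`` uint8 array.
    """
    a = np.asarray(arr)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {a.shape}")
    if a.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got dtype {a.dtype}")
    return a


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit RGB fundus raster plus optional eye-side metadata.

    ``eye_side`` is ``None`` when the acquisition device did not record it; the
    geometry stage then infers it from the optic-disc position.
    """

    pixels: np.ndarray
    eye_side: Optional[EyeSide] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", as_rgb8(self.pixels))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def with_pixels(self, pixels: np.ndarray) -> "FundusImage":
        return replace(self, pixels=as_rgb8(pixels))


@dataclass(frozen=True)
class OpticDiscBox:
    """Detected optic-disc bounding box.

    ``x``/``y`` is the upper-left corner; ``dd`` is the disc-diameter proxy,
    defined as ``(w + h) / 2`` because detectors return nearly but not exactly
    square boxes; ``prob`` is the detector's confidence Pr(OD).
    """

    x: float
    y: float
    w: float
    h: float
    prob: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError(f"prob must lie in [0, 1], got {self.prob}")

    @property
    def dd(self) -> float:
        """Optic-disc diameter proxy: mean of box width and height."""
        return (self.w + self.h) / 2.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def to_json(self) -> dict:
        return {
            "x": self.x, "y": self.y, "w": self.w, "h": self.h,
            "dd": self.dd, "prob": self.prob,
        }


@dataclass(frozen=True)
class RegionRect:
    """Axis-aligned rectangle for the ROI or macula, in pixel coordinates.

    Coordinates are kept exact (possibly fractional) until crop time;
    ``clipped`` records whether any edge was moved to fit the image.
    """

    x0: float
    y0: float
    w: float
    h: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"rect must have positive size, got w={self.w}, h={self.h}")

    @property
    def x1(self) -> float:
        return self.x0 + self.w

    @property
    def y1(self) -> float:
        return self.y0 + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains_rect(self, other: "RegionRect") -> bool:
        return (self.x0 <= other.x0 and self.y0 <= other.y0
                and other.x1 <= self.x1 and other.y1 <= self.y1)

    def pixel_slices(self) -> tuple[slice, slice]:
        """Row/column slices after rounding half-to-even to pixel indices."""
        r0 = int(np.rint(self.y0))
        c0 = int(np.rint(self.x0))
        r1 = int(np.rint(self.y1))
        c1 = int(np.rint(self.x1))
        return slice(r0, r1), slice(c0, c1)

    def to_json(self, side: Optional[EyeSide] = None) -> dict:
        d = {"x0": self.x0, "y0": self.y0, "h": self.h, "w": self.w,
             "clipped": self.clipped}
        if side is not None:
            d["side"] = side.value
        return d


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds of the triage workflow.

    Defaults follow the deployed system: a detection is accepted when
    Pr(OD) > ``th_od``; the disc crop is "good" when the classifier probability
    exceeds ``th_oq``; the ROI is obstructed when the artefact fraction P_OB
    exceeds ``th_ob``; at most ``th_count`` acquisitions per session.
    All comparisons are strict.
    """

    th_od: float = 0.9
    th_oq: float = 0.95
    th_ob: float = 0.1
    th_count: int = 5

    def __post_init__(self) -> None:
        for name in ("th_od", "th_oq", "th_ob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.th_count < 1:
            raise ValueError(f"th_count must be a positive integer, got {self.th_count}")
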