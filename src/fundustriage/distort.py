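"""Controlled image distortions for the agreement-study protocol.

Three distortion families are applied to base images: Gaussian blur
(standard deviation sigma, in pixels), luminance shift (signed delta, in
8-bit gray levels, applied per channel) and contrast change (an affine
rescale about each channel's mean so the output standard deviation is a
fixed multiple of the input's).  The enumeration below yields 32 variants
per base image — 10 blur levels (including the sigma = 0 identity), 10
luminance shifts (+-5 .. +-25) and 12 contrast factors (0.6 .. 2.8 step
0.2) — so 10 base images produce 320 distorted images.
"""

from __future__ import annotations

import enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .types import FundusImage

__all__ = [
    "DistortionKind",
    "DistortionSpec",
    "apply_distortion",
    "enumerate_distortion_grid",
    "build_distorted_set",
]


class DistortionKind(str, enum.Enum):
    BLUR = "blur"
    LUMINANCE = "luminance"
    CONTRAST = "contrast"


class DistortionSpec(BaseModel):
    """Exactly one distortion, with its single active parameter."""

    kind: DistortionKind
    sigma: Optional[float] = Field(None, ge=0.0)
    delta: Optional[float] = None
    contrast_factor: Optional[float] = Field(None, gt=0.0)

    @model_validator(mode="after")
    def _one_active_parameter(self) -> "DistortionSpec":
        expected = {
            DistortionKind.BLUR: "sigma",
            DistortionKind.LUMINANCE: "delta",
            DistortionKind.CONTRAST: "contrast_factor",
        }[self.kind]
        for name in ("sigma", "delta", "contrast_factor"):
            value = getattr(self, name)
            if name == expected and value is None:
                raise ValueError(f"{self.kind.value} distortion requires {name}")
            if name != expected and value is not None:
                raise ValueError(
                    f"{self.kind.value} distortion must not set {name}")
        return self

    def label(self) -> str:
        if self.kind is DistortionKind.BLUR:
            return f"blur_sigma{self.sigma:g}"
        if self.kind is DistortionKind.LUMINANCE:
            return f"lum_delta{self.delta:+g}"
        return f"contrast_x{self.contrast_factor:g}"


def apply_distortion(img: FundusImage, d: DistortionSpec) -> FundusImage:
    """Apply one distortion; output has the same dimensions and dtype.

    Blur with sigma = 0 is the identity.  Luminance and contrast results are
    clipped to [0, 255] after the per-channel arithmetic.
    """
    pixels = img.pixels
    if d.kind is DistortionKind.BLUR:
        if d.sigma == 0:
            return img
        out = np.empty_like(pixels, dtype=float)
        for ch in range(3):
            out[..., ch] = ndimage.gaussian_filter(
                pixels[..., ch].astype(float), d.sigma)
        return img.with_pixels(np.clip(np.rint(out), 0, 255).astype(np.uint8))
    if d.kind is DistortionKind.LUMINANCE:
        out = pixels.astype(float) + d.delta
        return img.with_pixels(np.clip(np.rint(out), 0, 255).astype(np.uint8))
    # contrast: affine about each channel mean, target std = factor * input std
    out = pixels.astype(float)
    for ch in range(3):
        mean = out[..., ch].mean()
        out[..., ch] = mean + d.contrast_factor * (out[..., ch] - mean)
    return img.with_pixels(np.clip(np.rint(out), 0, 255).astype(np.uint8))


def enumerate_distortion_grid() -> list[DistortionSpec]:
    """The fixed 32-spec grid, in canonical order.

    Order: blur sigma ascending (0, 3.5, ..., 31.5), then luminance in
    +/- pairs of ascending magnitude (+5, -5, ..., +25, -25), then contrast
    factors ascending (0.6 .. 2.8).  The delta = 0 luminance shift is
    excluded as a duplicate of the sigma = 0 identity.
    """
    specs: list[DistortionSpec] = []
    for k in range(10):
        specs.append(DistortionSpec(kind=DistortionKind.BLUR, sigma=3.5 * k))
    for mag in (5.0, 10.0, 15.0, 20.0, 25.0):
        specs.append(DistortionSpec(kind=DistortionKind.LUMINANCE, delta=+mag))
        specs.append(DistortionSpec(kind=DistortionKind.LUMINANCE, delta=-mag))
    for k in range(12):
        specs.append(DistortionSpec(kind=DistortionKind.CONTRAST,
                                    contrast_factor=round(0.6 + 0.2 * k, 10)))
    return specs


def build_distorted_set(
        images: Sequence[FundusImage],
) -> list[tuple[FundusImage, DistortionSpec]]:
    """Apply the full grid to every base image.

    Returns ``len(images) * 32`` (image, spec) pairs, base-major then grid
    order.  Raises ``ValueError`` on an empty input list.
    """
    if len(images) == 0:
        raise ValueError("need at least one base image")
    grid = enumerate_distortion_grid()
    return [(apply_distortion(img, d), d) for img in images for d in grid]
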