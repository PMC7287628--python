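"""Synthetic ultra-widefield fundus phantoms with ground truth.

A phantom emulates the gross appearance of a scanning-laser-ophthalmoscope
(SLO) fundus image at reduced resolution: a dark elliptical retinal field on a
black surround, one bright near-circular optic disc (OD) with dark vessel
texture inside, superior/inferior vessel arcades curving toward a darker
macular region temporal to the OD, and optional eyelash or eyelid occluders.

Every phantom comes with pixel-accurate ground truth (OD box, vessel mask,
artefact mask, retina mask) so detection, quality, obstruction and vessel
stages can all be scored without manual annotation.  Rendering is fully
deterministic for a fixed seed: all randomness flows from the spec's seed
through named substreams.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage
from skimage.draw import line as draw_line

from .types import EyeSide, FundusImage, OpticDiscBox

__all__ = [
    "ArtefactKind",
    "PhantomSpec",
    "GroundTruth",
    "generate_fundus",
    "default_spec",
]

# Substream tags; fixed so that e.g. vessel layout does not change when
# the artefact substream consumes a different number of draws.
_SUB_BACKGROUND = 1
_SUB_VESSELS = 2
_SUB_ARTEFACT = 3

# Peak rendered intensity is kept below 255 so that a small additive
# luminance distortion (|delta| <= 5) never clips.
_MAX_LEVEL = 250.0


class ArtefactKind(str, enum.Enum):
    NONE = "none"
    EYELASH = "eyelash"
    EYELID = "eyelid"


class PhantomSpec(BaseModel):
    """Parameters of one rendered phantom.

    ``artefact_coverage_target`` is the desired artefact fraction of the
    rendered fundus field; the renderer lands within +-20% relative of it.
    """

    image_width: int = Field(360, ge=64)
    image_height: int = Field(288, ge=64)
    od_center: tuple[float, float] = (108.0, 144.0)
    od_diameter: float = Field(26.0, gt=0)
    eye_side: EyeSide = EyeSide.LEFT
    vessel_density: float = Field(0.5, ge=0.0, le=1.0)
    artefact_kind: ArtefactKind = ArtefactKind.NONE
    artefact_coverage_target: float = Field(0.0, ge=0.0, le=1.0)
    include_od: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _od_box_inside_image(self) -> "PhantomSpec":
        if self.include_od:
            cx, cy = self.od_center
            r = self.od_diameter / 2.0
            if (cx - r < 0 or cy - r < 0
                    or cx + r > self.image_width or cy + r > self.image_height):
                raise ValueError(
                    f"OD box (center {self.od_center}, diameter {self.od_diameter}) "
                    f"falls outside the {self.image_width}x{self.image_height} image")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Per-phantom ground truth.

    ``retina_mask`` and ``artefact_mask`` partition the rendered fundus field:
    they are pixel-wise disjoint and their union equals ``field_mask``.
    ``od_box`` is ``None`` for OD-free (outlier-style) phantoms.
    """

    od_box: Optional[OpticDiscBox]
    vessel_mask: np.ndarray
    artefact_mask: np.ndarray
    retina_mask: np.ndarray
    field_mask: np.ndarray
    eye_side: EyeSide


def default_spec(seed: int = 0, *, eye_side: EyeSide = EyeSide.LEFT,
                 artefact_kind: ArtefactKind = ArtefactKind.NONE,
                 artefact_coverage_target: float = 0.0,
                 include_od: bool = True,
                 image_width: int = 360, image_height: int = 288) -> PhantomSpec:
    """A spec with the OD placed nasally for the requested eye.

    For a left eye the OD sits in the left (nasal) half of the frame so the
    macula, temporal to the OD, falls inside the field; mirrored for the right
    eye.  Small seed-driven jitter is applied to OD position and size.
    """
    rng = np.random.default_rng([seed, 0])
    frac = 0.30 if eye_side is EyeSide.LEFT else 0.70
    cx = image_width * (frac + rng.uniform(-0.02, 0.02))
    cy = image_height * (0.5 + rng.uniform(-0.04, 0.04))
    dia = image_width * rng.uniform(0.068, 0.080)
    return PhantomSpec(
        image_width=image_width, image_height=image_height,
        od_center=(float(cx), float(cy)), od_diameter=float(dia),
        eye_side=eye_side, vessel_density=0.5,
        artefact_kind=artefact_kind,
        artefact_coverage_target=artefact_coverage_target,
        include_od=include_od, seed=seed)


# ----------------------------------------------------------------------------
# rendering helpers


def _coordinate_grids(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                       indexing="ij")


def _field_mask(h: int, w: int) -> np.ndarray:
    yy, xx = _coordinate_grids(h, w)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.47 * h, 0.48 * w
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _stamp_polyline(shape: tuple[int, int], points: np.ndarray,
                    width: int) -> np.ndarray:
    """Rasterize a polyline (float vertices) at the given stroke width."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    pts = np.rint(points).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[ok], cc[ok]] = True
    if width > 1:
        r = max(1, width // 2)
        mask = ndimage.binary_dilation(mask, structure=_disk(r))
    return mask


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy ** 2 + xx ** 2 <= radius ** 2


def _bezier(p0, p1, p2, n: int = 160) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float, amplitude: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma)
    s = noise.std()
    return noise * (amplitude / s) if s > 0 else noise


def _render_vessels(spec: PhantomSpec, od_center_rc: np.ndarray,
                    temporal: float, rng: np.random.Generator) -> np.ndarray:
    """Arcade trunks plus random-walk branches, as a boolean mask."""
    h, w = spec.image_height, spec.image_width
    dd = spec.od_diameter
    start = od_center_rc
    mask = np.zeros((h, w), dtype=bool)

    # superior (-1) and inferior (+1) arcades: leave the OD, arc around the
    # macula toward the temporal edge
    for vert in (-1.0, 1.0):
        ctrl = start + np.array([vert * 3.2 * dd, temporal * 2.0 * dd])
        end = start + np.array([vert * 2.2 * dd + rng.uniform(-0.3, 0.3) * dd,
                                temporal * 6.5 * dd])
        pts = _bezier(start, ctrl, end)
        mask |= _stamp_polyline((h, w), pts, width=3)
        # nasal trunk, shorter and straighter
        end_n = start + np.array([vert * 2.0 * dd, -temporal * 3.0 * dd])
        ctrl_n = start + np.array([vert * 1.6 * dd, -temporal * 1.0 * dd])
        mask |= _stamp_polyline((h, w), _bezier(start, ctrl_n, end_n), width=2)

    # random-walk side branches
    n_branches = int(round(spec.vessel_density * 24))
    anchor_rows = np.flatnonzero(mask.any(axis=1))
    for _ in range(n_branches):
        r = rng.choice(anchor_rows)
        cols = np.flatnonzero(mask[r])
        c = rng.choice(cols)
        pos = np.array([float(r), float(c)])
        heading = rng.uniform(0, 2 * np.pi)
        steps = rng.integers(8, 22)
        pts = [pos.copy()]
        for _ in range(steps):
            heading += rng.uniform(-0.5, 0.5)
            pos = pos + 3.0 * np.array([np.sin(heading), np.cos(heading)])
            pts.append(pos.copy())
        mask |= _stamp_polyline((h, w), np.array(pts), width=1)
    return mask


def _render_eyelash(field: np.ndarray, target: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Dark curved strokes entering from the top until coverage is reached."""
    h, w = field.shape
    field_area = int(field.sum())
    mask = np.zeros_like(field)
    if target <= 0:
        return mask
    goal = target * field_area
    for _ in range(4000):  # hard cap; each stroke adds a small increment
        x0 = rng.uniform(0.1 * w, 0.9 * w)
        length = rng.uniform(0.30, 0.55) * h
        drift = rng.uniform(-0.4, 0.4) * length
        p0 = np.array([0.0, x0])
        p1 = np.array([0.5 * length, x0 + 0.3 * drift])
        p2 = np.array([length, x0 + drift])
        stroke = _stamp_polyline((h, w), _bezier(p0, p1, p2, n=64),
                                 width=int(rng.integers(2, 4)))
        mask |= stroke
        if (mask & field).sum() >= goal:
            break
    return mask & field


def _render_eyelid(field: np.ndarray, target: float) -> np.ndarray:
    """Skin-coloured lid descending from the top; depth solved by bisection."""
    h, w = field.shape
    field_area = int(field.sum())
    if target <= 0:
        return np.zeros_like(field)
    xx = np.arange(w, dtype=float)
    cx = (w - 1) / 2.0
    # lid edge droops most at the frame centre
    profile = 1.0 - 0.45 * ((xx - cx) / (w / 2.0)) ** 2
    yy = np.arange(h, dtype=float)[:, None]

    def region(base: float) -> np.ndarray:
        return (yy < base * profile[None, :]) & field

    lo, hi = 0.0, float(h)
    for _ in range(40):
        mid = (lo + hi) / 2.0
        if region(mid).sum() / field_area < target:
            lo = mid
        else:
            hi = mid
    return region((lo + hi) / 2.0)


# ----------------------------------------------------------------------------
# main entry point


def generate_fundus(spec: PhantomSpec) -> tuple[FundusImage, GroundTruth]:
    """Render a phantom and its ground truth.

    Deterministic: the same spec (including seed) yields a bit-identical
    image.  The OD is always brighter than its surround and carries dark
    vessel texture inside; the artefact coverage lands within +-20% relative
    of ``artefact_coverage_target``.
    """
    h, w = spec.image_height, spec.image_width
    seed = spec.seed
    field = _field_mask(h, w)
    yy, xx = _coordinate_grids(h, w)

    # --- background retina: reddish field, brighter toward the centre
    rng_bg = np.random.default_rng([seed, _SUB_BACKGROUND])
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = (((yy - cy) / (0.47 * h)) ** 2 + ((xx - cx) / (0.48 * w)) ** 2)
    shading = np.clip(1.0 - 0.40 * r2, 0.0, 1.0)
    shading += _smooth_noise(rng_bg, (h, w), sigma=8.0, amplitude=0.035)
    base = np.stack([170.0 * shading, 78.0 * shading, 42.0 * shading], axis=-1)

    od_center_rc = np.array([spec.od_center[1], spec.od_center[0]])
    temporal = 1.0 if spec.eye_side is EyeSide.LEFT else -1.0
    dd = spec.od_diameter

    # --- macula: smooth dark spot temporal to the OD
    if spec.include_od:
        mac_rc = od_center_rc + np.array([0.0, temporal * 2.8 * dd])
    else:
        mac_rc = np.array([cy, cx])
    mac_r = 0.9 * dd
    mac_profile = np.exp(-(((yy - mac_rc[0]) ** 2 + (xx - mac_rc[1]) ** 2)
                           / (2 * mac_r ** 2)))
    base *= (1.0 - 0.38 * mac_profile)[..., None]

    # --- optic disc: bright, slightly elliptical, soft rim
    if spec.include_od:
        od_rx, od_ry = dd / 2.0, 0.96 * dd / 2.0
        d2 = (((yy - od_center_rc[0]) / od_ry) ** 2
              + ((xx - od_center_rc[1]) / od_rx) ** 2)
        od_profile = np.clip(1.0 - np.maximum(d2 - 0.7, 0.0) / 0.6, 0.0, 1.0)
        od_color = np.array([245.0, 225.0, 160.0])
        alpha = od_profile[..., None]
        base = base * (1 - alpha) + od_color[None, None, :] * alpha

    # --- vessels: dark red, drawn over OD so its interior shows texture
    rng_v = np.random.default_rng([seed, _SUB_VESSELS])
    vessel_mask = _render_vessels(spec, od_center_rc, temporal, rng_v) & field
    base[vessel_mask] = np.array([88.0, 26.0, 20.0])

    # --- artefacts on top of everything
    rng_a = np.random.default_rng([seed, _SUB_ARTEFACT])
    artefact_mask = np.zeros((h, w), dtype=bool)
    if spec.artefact_kind is ArtefactKind.EYELASH:
        artefact_mask = _render_eyelash(field, spec.artefact_coverage_target, rng_a)
        base[artefact_mask] = np.array([28.0, 24.0, 24.0])
    elif spec.artefact_kind is ArtefactKind.EYELID:
        artefact_mask = _render_eyelid(field, spec.artefact_coverage_target)
        skin = np.array([212.0, 158.0, 128.0])
        tex = _smooth_noise(rng_a, (h, w), sigma=4.0, amplitude=6.0)
        base[artefact_mask] = np.clip(skin[None, :] + tex[artefact_mask, None],
                                      0, _MAX_LEVEL)

    # --- composite onto the dark surround
    out = np.full((h, w, 3), 9.0)
    out[field] = base[field]
    img = np.clip(out, 0.0, _MAX_LEVEL).astype(np.uint8)

    od_box = None
    if spec.include_od:
        od_box = OpticDiscBox(x=spec.od_center[0] - dd / 2.0,
                              y=spec.od_center[1] - dd / 2.0,
                              w=dd, h=dd, prob=1.0)
    gt = GroundTruth(
        od_box=od_box,
        vessel_mask=vessel_mask & ~artefact_mask,
        artefact_mask=artefact_mask,
        retina_mask=field & ~artefact_mask,
        field_mask=field,
        eye_side=spec.eye_side,
    )
    return FundusImage(img, eye_side=spec.eye_side), gt
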