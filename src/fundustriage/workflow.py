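"""The acquisition-triage state machine.

Each acquired image runs through up to four stages — OD detection, OD
clarity, ROI obstruction, vessel segmentation — and is assigned a quality
level (QL):

* QL 0: no OD found (outlier frame, closed eye, effaced disc) -> report 1
* QL 1: OD found but too blurred -> report 2
* QL 2: OD clear but the ROI is obstructed by artefacts -> report 3
* QL 3: passed everything; vessels are segmented and no report is due

A session acquires images until one reaches QL 3 or the acquisition budget
(``th_count``, default 5) is spent, then transmits the best attempt (largest
QL; ties broken by mean stage confidence, then by acquisition order) as an
on-disk bundle: the selected image, OD/ROI/macula crops, binary vessel image
(QL 3 only) and the operator report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Union

import imageio.v3 as iio
import numpy as np

from .backends import ClassifierBackend, DetectorBackend, SegmenterBackend
from .detection import detect_od
from .obstruction import compute_pob, decide_obstruction, segment_retina
from .quality import QualityScore, extract_od_crop, score_od_quality
from .roi import EyeSideInfo, clip_to_image, compute_macula, compute_roi, infer_eye_side
from .types import EyeSide, FundusImage, OpticDiscBox, RegionRect, Thresholds
from .vessels import VesselMask, segment_vessels

__all__ = [
    "QL_NO_OD", "QL_BLURRED", "QL_OBSTRUCTED", "QL_GOOD",
    "Report", "REPORTS", "BackendSet", "AttemptRecord", "SessionResult",
    "evaluate_image", "run_session", "select_best", "build_bundle",
]

QL_NO_OD = 0
QL_BLURRED = 1
QL_OBSTRUCTED = 2
QL_GOOD = 3


@dataclass(frozen=True)
class Report:
    report_id: int  # 1..3
    headline: str
    reasons: tuple[str, ...]

    def text(self) -> str:
        lines = [f"Report {self.report_id}: {self.headline}"]
        lines += [f"  - {r}" for r in self.reasons]
        return "\n".join(lines)


#: Operator reports keyed by the quality level they explain (QL < 3).
REPORTS: dict[int, Report] = {
    QL_NO_OD: Report(
        report_id=1,
        headline="The retinal image does not contain the OD.",
        reasons=(
            "The patient closed the eye at the moment of image capture.",
            "The distance between the patient's eye and the equipment is not adequate.",
            "The patient suffers some uncommon eye disease.",
        )),
    QL_BLURRED: Report(
        report_id=2,
        headline="The retinal image is blurred.",
        reasons=(
            "Probable movement of the patient at the moment of image capture.",
            "The equipment requires some adjustment (focus, illumination).",
            "The patient's crystalline lens is opaque.",
        )),
    QL_OBSTRUCTED: Report(
        report_id=3,
        headline=("Some part of the ROI is obstructed by artefacts such as "
                  "eyelashes and/or eyelid."),
        reasons=(
            "The patient must try to open the eye more widely.",
        )),
}


@dataclass
class BackendSet:
    """The four backends the pipeline consumes."""

    detector: DetectorBackend
    quality: ClassifierBackend
    retina: SegmenterBackend
    vessel: SegmenterBackend


@dataclass
class AttemptRecord:
    """Everything the pipeline produced for one acquired image.

    Stage outputs are populated exactly up to the failing stage; an attempt
    with a vessel mask always has QL 3.
    """

    image: FundusImage
    ql: int
    report: Optional[Report]
    pr_od: float = 0.0
    od_box: Optional[OpticDiscBox] = None
    quality_score: Optional[QualityScore] = None
    side_info: Optional[EyeSideInfo] = None
    roi: Optional[RegionRect] = None
    macula: Optional[RegionRect] = None
    p_ob: Optional[float] = None
    artefact_mask: Optional[np.ndarray] = None
    vessel_mask: Optional[VesselMask] = None

    @property
    def confidence(self) -> float:
        """Mean of the stage probabilities available so far (tie-breaker)."""
        parts = [self.pr_od]
        if self.quality_score is not None:
            parts.append(self.quality_score.prob_good)
        if self.p_ob is not None:
            parts.append(1.0 - self.p_ob)
        return float(np.mean(parts))


@dataclass
class SessionResult:
    attempts: list[AttemptRecord]
    best_index: int
    bundle_path: Optional[Path] = None

    @property
    def best(self) -> AttemptRecord:
        return self.attempts[self.best_index]


# Fraction of its nominal area the clipped ROI must keep; below this the
# frame is handled like an obstructed ROI (the diagnostic region is mostly
# off-frame).
_MIN_ROI_AREA_FRACTION = 0.5


def evaluate_image(img: FundusImage, backends: BackendSet,
                   thresholds: Thresholds = Thresholds()) -> AttemptRecord:
    """Run the four stages in order, stopping at the first failure."""
    record = AttemptRecord(image=img, ql=QL_NO_OD, report=REPORTS[QL_NO_OD])

    # stage 1: OD detection
    candidates = backends.detector.predict(img)
    record.pr_od = max((p for _, p in candidates), default=0.0)
    box = detect_od(img, backends.detector, thresholds.th_od)
    if box is None:
        return record
    record.od_box = box

    # stage 2: OD clarity
    crop = extract_od_crop(img, box)
    record.quality_score = score_od_quality(crop, backends.quality,
                                            thresholds.th_oq)
    if record.quality_score.decision != "good":
        record.ql = QL_BLURRED
        record.report = REPORTS[QL_BLURRED]
        return record

    # stage 3: geometry + obstruction
    record.side_info = infer_eye_side(box, img.width,
                                      metadata_side=img.eye_side)
    shape = (img.height, img.width)
    roi = clip_to_image(compute_roi(box, record.side_info.side), shape)
    record.roi = roi
    try:
        record.macula = clip_to_image(
            compute_macula(box, record.side_info.side), shape)
    except ValueError:
        record.macula = None  # macula fully off-frame

    nominal_area = (6.0 * box.dd) * (5.5 * box.dd)
    retina = segment_retina(img, backends.retina)
    record.artefact_mask = ~retina
    record.p_ob = compute_pob(record.artefact_mask, roi)
    roi_too_clipped = roi.area < _MIN_ROI_AREA_FRACTION * nominal_area
    if decide_obstruction(record.p_ob, thresholds.th_ob) or roi_too_clipped:
        record.ql = QL_OBSTRUCTED
        record.report = REPORTS[QL_OBSTRUCTED]
        return record

    # stage 4: vessels in the ROI
    rows, cols = roi.pixel_slices()
    record.vessel_mask = segment_vessels(img.pixels[rows, cols],
                                         backends.vessel)
    record.ql = QL_GOOD
    record.report = None
    return record


ImageSource = Union[Iterable[FundusImage], Callable[[], Optional[FundusImage]]]


def _iterate_source(source: ImageSource) -> Iterator[FundusImage]:
    if callable(source):
        while True:
            img = source()
            if img is None:
                return
            yield img
    else:
        yield from source


def run_session(image_source: ImageSource, backends: BackendSet,
                thresholds: Thresholds = Thresholds(),
                out_dir: Optional[Union[str, Path]] = None) -> SessionResult:
    """Acquire and evaluate images until QL 3 or the budget is spent.

    ``image_source`` is an iterable of images or a zero-argument callable
    returning the next image (``None`` when exhausted).  At most
    ``thresholds.th_count`` images are consumed.  Raises if the source
    yields no image at all.  When ``out_dir`` is given, the best attempt's
    bundle is written there.
    """
    attempts: list[AttemptRecord] = []
    for img in _iterate_source(image_source):
        record = evaluate_image(img, backends, thresholds)
        attempts.append(record)
        if record.ql == QL_GOOD or len(attempts) >= thresholds.th_count:
            break
    if not attempts:
        raise ValueError("image source yielded no images")
    best = select_best(attempts)
    result = SessionResult(attempts=attempts, best_index=best)
    if out_dir is not None:
        result.bundle_path = build_bundle(attempts[best], out_dir)
    return result


def select_best(attempts: list[AttemptRecord]) -> int:
    """Index of the best attempt: largest QL, then highest mean stage
    confidence, then earliest acquisition."""
    if not attempts:
        raise ValueError("no attempts to select from")
    return max(range(len(attempts)),
               key=lambda i: (attempts[i].ql, attempts[i].confidence, -i))


def _save_crop(img: FundusImage, rect: RegionRect, path: Path) -> None:
    rows, cols = rect.pixel_slices()
    iio.imwrite(path, img.pixels[rows, cols])


def build_bundle(attempt: AttemptRecord, out_dir: Union[str, Path]) -> Path:
    """Write the transmission bundle for one attempt.

    Always contains the selected image and the report (text + JSON); OD,
    ROI and macula crops are added from the stage the attempt reached, and
    the binary vessel image only for QL 3.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "image.png", attempt.image.pixels)

    report_json: dict = {
        "ql": attempt.ql,
        "report_id": attempt.report.report_id if attempt.report else None,
        "reasons": list(attempt.report.reasons) if attempt.report else [],
        "eye": attempt.side_info.side.value if attempt.side_info else None,
        "p_ob": attempt.p_ob,
        "pr_od": attempt.pr_od,
        "prob_good": (attempt.quality_score.prob_good
                      if attempt.quality_score else None),
        "clipped": attempt.roi.clipped if attempt.roi else None,
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=2))
    headline = attempt.report.text() if attempt.report else \
        "The retinal image passed all quality evaluations."
    (out / "report.txt").write_text(headline + "\n")

    if attempt.od_box is not None:
        crop = extract_od_crop(attempt.image, attempt.od_box)
        iio.imwrite(out / "od.png", crop)
    if attempt.roi is not None:
        _save_crop(attempt.image, attempt.roi, out / "roi.png")
    if attempt.macula is not None:
        _save_crop(attempt.image, attempt.macula, out / "macula.png")
    if attempt.vessel_mask is not None:
        iio.imwrite(out / "vessels.png",
                    (attempt.vessel_mask.mask.astype(np.uint8) * 255))
    return out
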