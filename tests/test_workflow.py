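"""Triage state machine: staging, session budget, best selection, bundles."""

import json

import numpy as np
import pytest

from fundustriage.baselines import baseline_backend_set
from fundustriage.distort import DistortionKind, DistortionSpec, apply_distortion
from fundustriage.types import FundusImage, OpticDiscBox, Thresholds
from fundustriage.workflow import (QL_BLURRED, QL_GOOD, QL_NO_OD,
                                   QL_OBSTRUCTED, REPORTS, AttemptRecord,
                                   BackendSet, build_bundle, evaluate_image,
                                   run_session, select_best)


class StubDetector:
    def __init__(self, candidates):
        self.candidates = candidates

    def fit(self, images, boxes, config=None):
        return self

    def predict(self, image):
        return self.candidates


class StubClassifier:
    def __init__(self, prob):
        self.prob = prob

    def fit(self, crops, labels, config=None):
        return self

    def predict(self, crop):
        return self.prob


class StubSegmenter:
    """Constant probability map (e.g. 1.0 = everything is retina/vessel)."""

    def __init__(self, value):
        self.value = value

    def fit(self, patches, masks, config=None):
        return self

    def predict(self, image):
        return np.full(np.asarray(image).shape[:2], self.value)


def _frame():
    rng = np.random.default_rng(0)
    return FundusImage(rng.integers(0, 200, (288, 360, 3), dtype=np.uint8))


def _good_box():
    # placed so the unclipped ROI and macula both fit inside 360x288
    return OpticDiscBox(x=150.0, y=120.0, w=26.0, h=26.0)


def _stub_backends(detector_prob=0.99, quality_prob=0.99, retina_prob=1.0):
    return BackendSet(
        detector=StubDetector([(_good_box(), detector_prob)]),
        quality=StubClassifier(quality_prob),
        retina=StubSegmenter(retina_prob),
        vessel=StubSegmenter(0.0))


def test_ql0_when_no_od():
    rec = evaluate_image(_frame(), _stub_backends(detector_prob=0.5))
    assert rec.ql == QL_NO_OD
    assert rec.report.report_id == 1
    assert rec.od_box is None and rec.roi is None and rec.vessel_mask is None


def test_ql1_when_blurred():
    rec = evaluate_image(_frame(), _stub_backends(quality_prob=0.5))
    assert rec.ql == QL_BLURRED
    assert rec.report.report_id == 2
    assert rec.od_box is not None
    assert rec.roi is None and rec.p_ob is None


def test_ql2_when_obstructed():
    rec = evaluate_image(_frame(), _stub_backends(retina_prob=0.0))
    assert rec.ql == QL_OBSTRUCTED
    assert rec.report.report_id == 3
    assert "eyelash" in rec.report.headline
    assert rec.p_ob == pytest.approx(1.0)
    assert rec.vessel_mask is None


def test_ql3_on_full_pass():
    rec = evaluate_image(_frame(), _stub_backends())
    assert rec.ql == QL_GOOD
    assert rec.report is None
    assert rec.p_ob == pytest.approx(0.0)
    assert rec.vessel_mask is not None
    rows, cols = rec.roi.pixel_slices()
    assert rec.vessel_mask.mask.shape == (rows.stop - rows.start,
                                          cols.stop - cols.start)


def test_thresholds_are_strict_at_the_boundary():
    rec = evaluate_image(_frame(), _stub_backends(detector_prob=0.9))
    assert rec.ql == QL_NO_OD
    rec = evaluate_image(_frame(), _stub_backends(quality_prob=0.95))
    assert rec.ql == QL_BLURRED


def test_session_stops_at_first_good_image():
    frames = [_frame() for _ in range(5)]
    result = run_session(iter(frames), _stub_backends())
    assert len(result.attempts) == 1
    assert result.best.ql == QL_GOOD


def test_session_consumes_at_most_th_count_images():
    calls = {"n": 0}

    def endless_source():
        calls["n"] += 1
        return _frame()

    result = run_session(endless_source, _stub_backends(detector_prob=0.2))
    assert len(result.attempts) == 5
    assert calls["n"] == 5
    assert result.best.ql == QL_NO_OD


def test_session_custom_budget():
    result = run_session((lambda: _frame()),
                         _stub_backends(detector_prob=0.2),
                         Thresholds(th_count=3))
    assert len(result.attempts) == 3


def test_session_raises_on_empty_source():
    with pytest.raises(ValueError):
        run_session(iter([]), _stub_backends())


def _attempt(ql, pr_od=0.5):
    return AttemptRecord(image=_frame(), ql=ql,
                         report=REPORTS.get(ql), pr_od=pr_od)


def test_select_best_prefers_largest_ql():
    attempts = [_attempt(0), _attempt(1), _attempt(1), _attempt(0), _attempt(2)]
    assert select_best(attempts) == 4


def test_select_best_breaks_ties_by_confidence_then_order():
    attempts = [_attempt(1, pr_od=0.3), _attempt(1, pr_od=0.8),
                _attempt(1, pr_od=0.8)]
    assert select_best(attempts) == 1  # higher confidence, earliest on tie
    attempts = [_attempt(2, pr_od=0.5), _attempt(2, pr_od=0.5)]
    assert select_best(attempts) == 0
    with pytest.raises(ValueError):
        select_best([])


def test_bundle_contents_for_ql3(tmp_path):
    rec = evaluate_image(_frame(), _stub_backends())
    out = build_bundle(rec, tmp_path / "b")
    names = sorted(p.name for p in out.iterdir())
    assert names == ["image.png", "macula.png", "od.png", "report.json",
                     "report.txt", "roi.png", "vessels.png"]
    payload = json.loads((out / "report.json").read_text())
    assert payload["ql"] == 3 and payload["report_id"] is None
    assert "passed all quality evaluations" in (out / "report.txt").read_text()


def test_bundle_contents_for_ql0(tmp_path):
    rec = evaluate_image(_frame(), _stub_backends(detector_prob=0.2))
    out = build_bundle(rec, tmp_path / "b")
    names = sorted(p.name for p in out.iterdir())
    assert names == ["image.png", "report.json", "report.txt"]
    payload = json.loads((out / "report.json").read_text())
    assert payload["ql"] == 0 and payload["report_id"] == 1
    assert "does not contain the OD" in (out / "report.txt").read_text()


def test_session_replays_bit_identically(tmp_path, clean_phantom):
    img, _ = clean_phantom
    blurred = apply_distortion(
        img, DistortionSpec(kind=DistortionKind.BLUR, sigma=17.5))
    backends = baseline_backend_set()
    dirs = []
    for name in ("a", "b"):
        result = run_session([blurred, img], backends,
                             out_dir=tmp_path / name)
        dirs.append(result.bundle_path)
    files_a = sorted(p.name for p in dirs[0].iterdir())
    files_b = sorted(p.name for p in dirs[1].iterdir())
    assert files_a == files_b
    for name in files_a:
        assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()


def test_trained_pipeline_end_to_end(backends, clean_phantom, eyelash_phantom):
    img, _ = clean_phantom
    assert evaluate_image(img, backends).ql == QL_GOOD
    blurred = apply_distortion(
        img, DistortionSpec(kind=DistortionKind.BLUR, sigma=14.0))
    assert evaluate_image(blurred, backends).ql == QL_BLURRED
    occluded, _ = eyelash_phantom
    assert evaluate_image(occluded, backends).ql < QL_GOOD
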