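# Methods

This document records the models, parameters, and numerical choices behind
`fundustriage`, the scope of the synthetic phantom generator, and the known
limitations.

## 1. Pipeline and decision rules

Images flow through four stages; the first failing stage assigns the quality
level (QL) and the operator report. All comparisons against thresholds are
strict (`>`), so a score exactly at a threshold fails.

| Threshold | Default | Meaning |
|---|---|---|
| `th_od` | 0.9 | minimum detector confidence Pr(OD) to accept a disc |
| `th_oq` | 0.95 | minimum good-clarity probability of the OD crop |
| `th_ob` | 0.1 | maximum artefact fraction P_OB of the ROI |
| `th_count` | 5 | maximum acquisitions per session |

QL encodes the stage reached: 0 = no OD (report 1), 1 = blurred (report 2),
2 = ROI obstructed (report 3), 3 = passed everything (no report; vessels are
segmented and the frame is transmitted). One deliberate extension: when the
clipped ROI keeps less than 50% of its nominal 6.0·DD × 5.5·DD area (the
diagnostic region is mostly off-frame), the frame is routed down the
obstructed path even if P_OB over the visible part is small.

Geometry (exact, fractional coordinates; rounding to pixels happens only at
crop time using round-half-to-even):

- ROI: x₀ = X − 0.5·DD (left) / X − 4.0·DD (right), y₀ = Y − 2.5·DD,
  h = 6.0·DD, w = 5.5·DD.
- Macula: x₀ = X + 2·DD (left) / X − 3·DD (right), y₀ = Y − 0.5·DD,
  h = 2.5·DD, w = 2·DD.
- DD = (w + h)/2 of the detected box (detectors return nearly but not
  exactly square boxes).
- Eye side: metadata wins; otherwise OD centre x < width/2 ⇒ left eye.

## 2. Models

The reference system uses deep CNNs (Faster-R-CNN-style detection, encoder–
decoder segmentation) trained on thousands of clinical images. That is not
reproducible at desk scale, so the package keeps the *pipeline contracts*
identical and substitutes compact scikit-learn models plus deterministic
baselines. The CNN hyper-parameter presets are preserved as metadata in
`backends.REFERENCE_CONFIGS` (optimiser, learning rate, batch size, epochs,
train/test split per stage).

### Trainable backends (scikit-learn `SGDClassifier`, log loss)

All four train in ~15 s total (`training.train_default_backends(seed)`) via
per-epoch `partial_fit` with a recorded loss curve.

- **OD detector** (`BlobDetector`): candidate boxes from bright-blob
  proposals — grayscale percentile 99.2 threshold, 5×5 binary closing,
  area/aspect filters — each refined by a half-max threshold around its
  centre (7×7 closing, largest near-centre component). Candidates are scored
  by a logistic classifier over crop features (12×12 thumbnail, multi-scale
  gradient statistics, Laplacian variance). Trained on phantom OD boxes as
  positives (including σ ∈ {7, 14, 17.5} blurred copies, so that blur fails
  at the *clarity* stage, not detection) and random far-from-OD crops as
  negatives.
- **Clarity classifier** (`SgdCropClassifier`): same crop features; labels
  follow the synthetic clarity protocol — crops blurred with σ ≤ 3.5 are
  "good", σ ≥ 14 are "bad" (the cutoffs stand in for ophthalmologist
  judgement on phantoms). A third of training phantoms carry eyelash
  occluders and boxes are jittered (scale 0.85–1.2, shift ±15%) so the
  classifier judges clarity, not occlusion or box placement.
- **Retina-vs-rest segmenter** (`SgdPixelSegmenter`, `use_ridge=False`):
  per-pixel logistic regression over RGB, Gaussian-smoothed colour, and
  local-standard-deviation features; inverse-frequency sample weights
  counter class imbalance; at most 200 000 training pixels are subsampled.
- **Vessel segmenter** (`SgdPixelSegmenter`, `use_ridge=True`): adds
  multi-scale Hessian dark-ridge features (largest eigenvalue, σ²-normalised,
  offset-invariant). Large crops are predicted in overlapping tiles whose
  probability maps are averaged before thresholding at 0.5.

### Deterministic baselines (no training)

- `BaselineDetector` / `baseline_detect`: among bright-blob candidates,
  confidence = (surround-contrast term, saturating at contrast 0.05) ×
  (interior ridge-texture term, saturating at 0.02). Both calibration
  constants were fixed from the phantom design (OD ≈ 60–90 levels brighter
  than the field; vessel texture inside the disc), not tuned on test
  outcomes. A real OD scores near 1; a bright blob without vessel texture
  scores low.
- `SharpnessQualityClassifier`: mean squared gradient of the green channel
  s, mapped through 1 − exp(−s/s₀) with s₀ = 2.5 × 10⁻⁴ (chosen so that the
  σ ≤ 3.5 / σ ≥ 14 label protocol is reproduced on phantoms).
- `ColorRuleRetinaSegmenter`: fixed colour rules (near-black surround;
  skin/eyelid with G > 110, B > 85, R > G) → probabilities 0.05/0.95.
- `RidgeVesselSegmenter` / `ridge_baseline`: Hessian ridge response at
  σ ∈ {1.0, 1.5, 2.5} on the green channel, threshold 0.015 (fixed from the
  rendered vessel contrast). Being built from second derivatives only, the
  pre-threshold response is invariant to constant luminance shifts.

## 3. Synthetic phantom generator

`synthetic.generate_fundus(spec)` renders a 360×288 (configurable) RGB
phantom emulating an ultra-widefield scanning-laser-ophthalmoscope image:

- dark elliptical retinal field on black surround;
- one bright, slightly elliptical OD with dark internal vessel texture,
  placed nasally for the requested eye side (≈ 0.30/0.70 of the width, ±2%
  jitter; diameter 6.8–8.0% of the width);
- superior and inferior vessel arcades (quadratic Béziers, width 3) curving
  toward the macula, nasal trunks, plus random-walk branches; all rendered
  pixels recorded in the vessel ground-truth mask;
- a darker macular disc temporal to the OD;
- optional occluders with exact masks: *eyelash* (curved dark strokes added
  until the target coverage is reached) or *eyelid* (a lid crossing the top
  of the field; its depth is found by bisection so achieved coverage matches
  the target). The renderer lands within ±20% relative of the requested
  coverage; retina and artefact masks partition the field mask exactly.

Determinism: every random draw flows from the spec's seed through named
substreams (`background`, `vessels`, `artefact` = `default_rng([seed, k])`),
so e.g. the vessel layout does not change when the artefact branch consumes
a different number of draws. Peak intensity is capped at 250 so a +5
luminance distortion never clips.

**Scope.** Phantoms model gross geometry and contrast, not clinical
realism: no pathology, no illumination gradients, no camera noise, no
pigmentation variation, and occluders are stylised. Accuracy numbers on
phantoms therefore *validate the pipeline mechanics and the trainability of
the contracts*, not clinical performance.

## 4. Distortion and patch protocols

- Distortion grid (32 variants/base, canonical order): blur σ = 0, 3.5, …,
  31.5 (10); luminance δ = ±5, ±10, ±15, ±20, ±25 (10; δ = 0 excluded as a
  duplicate of σ = 0); contrast factor 0.6–2.8 step 0.2 (12), applied as an
  affine rescale about each channel's mean (output std = factor × input
  std). 10 bases ⇒ 320 images.
- Artefact-segmentation patches: 10 images × 100 base positions × 5
  augmented variants = 5000 at 224×224.
- Vessel-segmentation patches: 10 × 100 × 10 = 10 000 at 256×256.
- Detector thumbnails: 1288 base images × 10 = 12 880.
- Augmentation family: rotation ±60°, horizontal/vertical flips,
  translation ±5 px; image and mask receive the identical transform
  (bilinear for the image, nearest-neighbour for the mask); variant 0 is
  always the verbatim crop. Boxes are augmented by pushing their corners
  through the transform and re-enclosing axis-aligned.

## 5. Evaluation

- Cohen's kappa implemented from the counts: p_o = (N_gg + N_bb)/T,
  p_e = p_yes + p_no from the marginals, κ = (p_o − p_e)/(1 − p_e);
  κ is `None` (not 0) when p_e = 1. Cross-checked against
  `sklearn.metrics.cohen_kappa_score` in the tests.
- Confusion rates return `None` for undefined quantities (empty positive or
  negative class) instead of a silent 0.
- DICE/Jaccard satisfy J = D/(2 − D); both are `None` when both masks are
  empty.
- Superpixels (SLIC, compactness 10, ~1000 regions) are provided as the
  annotation mechanism: ground-truth masks can be produced by one vote per
  region (`mask_from_superpixels`), and ≥ 90% of regions are ≥ 80% pure
  against the three-way phantom ground truth.

## 6. Numerical choices

- Rectangles are half-open `[x, x+w) × [y, y+h)` in exact float
  coordinates; pixelisation uses `np.rint` (round half to even) only at
  crop time.
- Distorted images are computed in float and clipped/rounded back to uint8.
- Seeds: `np.random.default_rng([seed, substream])`; all seeds < 2³¹.
  Training, generation, inference and bundle writing are bit-reproducible
  for a fixed seed (verified by a golden SHA-256 render hash and a
  bundle-replay test; the golden hash is tied to the numpy/scipy versions
  pinned in the environment).
- Probabilities are clipped to [0, 1] on output; `check_contract` verifies
  range, output dimensions and determinism of any backend.

## 7. Limitations

- Clinical accuracies reported for the original CNN system are not
  reproducible here: no clinical data, no deep-learning stack. The
  substituted models recover the behaviour on phantoms only.
- The clarity labels on phantoms come from the σ-cutoff protocol, not human
  graders; κ agreement studies against ophthalmologists are replaced by a
  rater-harness API (`evaluation.agreement_study`) exercised with synthetic
  raters.
- The full-cascade obstruction judgement depends on the detector placing a
  box on a heavily occluded disc; phantoms with ≥ 60% OD occlusion may fail
  at stage 1 or 2 rather than stage 3 (either way they are correctly not
  transmitted). The stage-3 accuracy criterion is therefore evaluated on
  the obstruction stage itself (ground-truth geometry, predicted artefact
  mask), mirroring a protocol where images have already passed stages 1–2.
- Baseline calibration constants (contrast/texture scales, sharpness s₀,
  ridge threshold 0.015, colour rules) are fixed from the phantom design;
  on real images they would need recalibration.
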