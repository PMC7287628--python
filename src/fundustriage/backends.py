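"""Trainable-model contracts and CPU-scale default implementations.

Three contracts are defined (detector, crop classifier, pixel segmenter);
the pipeline stages depend only on these.  The deployed full-scale system
uses large convolutional models for each stage (a two-stage region-proposal
detector for the OD, a transfer-learned image classifier for OD clarity and
an encoder-decoder segmenter for artefacts and vessels); their published
hyper-parameters are kept here as reference presets.  The default
implementations below are deliberately small — linear models over engineered
image features — so they train in seconds on a CPU while honouring the same
contracts, and are interchangeable with any heavier backend.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize
from sklearn.linear_model import SGDClassifier
from sklearn.preprocessing import StandardScaler

from .types import FundusImage, OpticDiscBox, as_rgb8

__all__ = [
    "TrainConfig",
    "REFERENCE_CONFIGS",
    "DetectorBackend",
    "ClassifierBackend",
    "SegmenterBackend",
    "SgdCropClassifier",
    "SgdPixelSegmenter",
    "BlobDetector",
    "check_contract",
    "save_backend",
    "load_backend",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser settings and dataset split for one trainable stage."""

    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 15
    train_fraction: float = 0.8
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


#: Hyper-parameter presets of the full-scale CNN system, kept as metadata
#: (the desk-scale defaults above are much smaller).
REFERENCE_CONFIGS: dict[str, TrainConfig] = {
    "od_detection": TrainConfig(optimizer="sgdm", learning_rate=1e-4,
                                momentum=0.9, batch_size=1, epochs=20,
                                train_fraction=0.7, test_fraction=0.3),
    "od_quality": TrainConfig(optimizer="sgdm", learning_rate=1e-4,
                              momentum=0.9, batch_size=64, epochs=30,
                              train_fraction=0.7, test_fraction=0.3),
    "artefact_segmentation": TrainConfig(optimizer="adam", learning_rate=5e-4,
                                         momentum=0.0, batch_size=8, epochs=400,
                                         train_fraction=0.8, test_fraction=0.2),
    "vessel_segmentation": TrainConfig(optimizer="sgdm", learning_rate=5e-4,
                                       momentum=0.9, batch_size=32, epochs=100,
                                       train_fraction=0.9, test_fraction=0.1),
}


@runtime_checkable
class DetectorBackend(Protocol):
    def fit(self, images: Sequence[FundusImage],
            boxes: Sequence[OpticDiscBox],
            config: Optional[TrainConfig] = None) -> "DetectorBackend": ...

    def predict(self, image: FundusImage) -> list[tuple[OpticDiscBox, float]]: ...


@runtime_checkable
class ClassifierBackend(Protocol):
    def fit(self, crops: Sequence[np.ndarray], labels: Sequence[int],
            config: Optional[TrainConfig] = None) -> "ClassifierBackend": ...

    def predict(self, crop: np.ndarray) -> float: ...


@runtime_checkable
class SegmenterBackend(Protocol):
    def fit(self, patches: Sequence[np.ndarray], masks: Sequence[np.ndarray],
            config: Optional[TrainConfig] = None) -> "SegmenterBackend": ...

    def predict(self, image: np.ndarray) -> np.ndarray: ...


# ----------------------------------------------------------------------------
# feature extraction


def _gray(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(float).mean(axis=-1)


def _crop_features(crop: np.ndarray, thumb: int = 12) -> np.ndarray:
    """Appearance + sharpness features of an RGB crop.

    A small grayscale thumbnail captures layout (bright centre, dark vessel
    lines); gradient-energy statistics at several scales capture focus.
    """
    crop = as_rgb8(crop)
    g = _gray(crop) / 255.0
    small = resize(g, (thumb, thumb), order=1, anti_aliasing=True,
                   preserve_range=True)
    feats = [small.ravel()]
    for sigma in (0.0, 1.0, 2.0):
        s = ndimage.gaussian_filter(g, sigma) if sigma > 0 else g
        gy, gx = np.gradient(s)
        mag = np.hypot(gx, gy)
        feats.append(np.array([mag.mean(), mag.std(), mag.max()]))
    lap = ndimage.laplace(g)
    feats.append(np.array([lap.var(), g.mean(), g.std()]))
    return np.concatenate(feats)


def _ridge_response(gray01: np.ndarray, sigmas=(1.0, 2.0)) -> np.ndarray:
    """Dark-line (vessel) evidence: max over scales of -lambda2 of the Hessian.

    Offset-invariant by construction (second derivatives only).
    """
    best = np.zeros_like(gray01)
    for s in sigmas:
        hxx = ndimage.gaussian_filter(gray01, s, order=(0, 2))
        hyy = ndimage.gaussian_filter(gray01, s, order=(2, 0))
        hxy = ndimage.gaussian_filter(gray01, s, order=(1, 1))
        # eigenvalues of [[hyy, hxy], [hxy, hxx]]
        tr = (hxx + hyy) / 2.0
        det = np.sqrt(((hxx - hyy) / 2.0) ** 2 + hxy ** 2)
        lam_large = tr + det  # most positive curvature; dark ridges -> large
        best = np.maximum(best, (s ** 2) * np.maximum(lam_large, 0.0))
    return best


def _pixel_features(pixels: np.ndarray, use_ridge: bool) -> np.ndarray:
    """Per-pixel feature stack (H, W, F) for segmentation."""
    pixels = as_rgb8(pixels)
    rgb = pixels.astype(float) / 255.0
    g = rgb.mean(axis=-1)
    layers = [rgb[..., 0], rgb[..., 1], rgb[..., 2],
              ndimage.gaussian_filter(g, 2.0),
              np.sqrt(np.maximum(
                  ndimage.gaussian_filter(g ** 2, 2.0)
                  - ndimage.gaussian_filter(g, 2.0) ** 2, 0.0))]
    if use_ridge:
        green = rgb[..., 1]
        layers.append(_ridge_response(green))
        layers.append(_ridge_response(green, sigmas=(3.0,)))
    return np.stack(layers, axis=-1)


def _fit_sgd(X: np.ndarray, y: np.ndarray, config: TrainConfig,
             sample_weight: Optional[np.ndarray], seed: int
             ) -> tuple[StandardScaler, SGDClassifier, list[float]]:
    """Epoch-wise logistic SGD with a recorded training-loss curve."""
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    clf = SGDClassifier(loss="log_loss", alpha=1e-4,
                        learning_rate="constant", eta0=config.learning_rate,
                        random_state=seed)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(y))
        clf.partial_fit(Xs[order], y[order], classes=classes,
                        sample_weight=None if sample_weight is None
                        else sample_weight[order])
        p = np.clip(clf.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
        w = np.ones(len(y)) if sample_weight is None else sample_weight
        loss = -np.average(y * np.log(p) + (1 - y) * np.log(1 - p), weights=w)
        losses.append(float(loss))
    return scaler, clf, losses


# ----------------------------------------------------------------------------
# default implementations


@dataclass
class SgdCropClassifier:
    """Good-quality probability for an OD crop: logistic SGD over
    thumbnail + sharpness features."""

    seed: int = 0
    loss_curve: list[float] = field(default_factory=list)
    _scaler: Optional[StandardScaler] = None
    _clf: Optional[SGDClassifier] = None

    def fit(self, crops, labels, config: Optional[TrainConfig] = None):
        if len(crops) == 0:
            raise ValueError("empty dataset")
        if len(crops) != len(labels):
            raise ValueError("crops and labels must align")
        config = config or TrainConfig()
        X = np.stack([_crop_features(c) for c in crops])
        y = np.asarray(labels, dtype=int)
        self._scaler, self._clf, self.loss_curve = _fit_sgd(
            X, y, config, None, self.seed)
        return self

    def predict(self, crop: np.ndarray) -> float:
        if self._clf is None:
            raise RuntimeError("classifier not fitted")
        X = self._scaler.transform(_crop_features(crop)[None, :])
        return float(np.clip(self._clf.predict_proba(X)[0, 1], 0.0, 1.0))


@dataclass
class SgdPixelSegmenter:
    """Per-pixel foreground probability: logistic SGD over a colour /
    smoothness / (optionally) ridge feature stack.

    ``use_ridge`` adds dark-line Hessian features and should be on for
    vessels, off for artefact-vs-retina.  Class imbalance is handled by
    inverse-frequency sample weights.
    """

    use_ridge: bool = False
    seed: int = 0
    max_train_pixels: int = 200_000
    loss_curve: list[float] = field(default_factory=list)
    _scaler: Optional[StandardScaler] = None
    _clf: Optional[SGDClassifier] = None

    def fit(self, patches, masks, config: Optional[TrainConfig] = None):
        if len(patches) == 0:
            raise ValueError("empty dataset")
        if len(patches) != len(masks):
            raise ValueError("patches and masks must align")
        config = config or TrainConfig()
        feats, labels = [], []
        for patch, mask in zip(patches, masks):
            mask = np.asarray(mask).astype(bool)
            if mask.shape != patch.shape[:2]:
                raise ValueError(
                    f"mask dims {mask.shape} != patch dims {patch.shape[:2]}")
            f = _pixel_features(patch, self.use_ridge)
            feats.append(f.reshape(-1, f.shape[-1]))
            labels.append(mask.ravel())
        X = np.concatenate(feats)
        y = np.concatenate(labels).astype(int)
        rng = np.random.default_rng(self.seed)
        if len(y) > self.max_train_pixels:
            idx = rng.choice(len(y), size=self.max_train_pixels, replace=False)
            X, y = X[idx], y[idx]
        if len(np.unique(y)) < 2:
            raise ValueError("training masks contain a single class")
        # inverse-frequency weighting against background dominance
        freq = np.bincount(y, minlength=2) / len(y)
        weights = (0.5 / np.maximum(freq, 1e-9))[y]
        self._scaler, self._clf, self.loss_curve = _fit_sgd(
            X, y, config, weights, self.seed)
        return self

    def predict(self, image: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("segmenter not fitted")
        f = _pixel_features(image, self.use_ridge)
        X = self._scaler.transform(f.reshape(-1, f.shape[-1]))
        p = self._clf.predict_proba(X)[:, 1]
        return np.clip(p.reshape(image.shape[:2]), 0.0, 1.0)


def propose_od_candidates(image: FundusImage, max_candidates: int = 6
                          ) -> list[OpticDiscBox]:
    """Bright compact blobs as OD candidates (shared with the baseline).

    Thresholds the grayscale at a high percentile, keeps connected components
    of plausible area and aspect, and returns their bounding boxes brightest
    first, slightly expanded toward square.
    """
    g = _gray(image.pixels)
    h, w = g.shape
    th = np.percentile(g, 99.2)
    bright = g >= max(th, 60.0)
    # vessels crossing the disc cut the bright region apart; close the gaps
    bright = ndimage.binary_closing(bright, structure=np.ones((5, 5)))
    blobs = cc_label(bright)
    cands: list[tuple[float, OpticDiscBox]] = []
    for region in regionprops(blobs, intensity_image=g):
        if region.area < 20 or region.area > 0.06 * h * w:
            continue
        r0, c0, r1, c1 = region.bbox
        bh, bw = r1 - r0, c1 - c0
        if max(bh, bw) > 3.5 * min(bh, bw):
            continue
        cy, cx = (r0 + r1) / 2.0, (c0 + c1) / 2.0
        box = _refine_box(g, cy, cx, max(bh, bw))
        cands.append((float(region.intensity_mean), box))
    cands.sort(key=lambda t: -t[0])
    return [b for _, b in cands[:max_candidates]]


def _refine_box(g: np.ndarray, cy: float, cx: float, side0: float
                ) -> OpticDiscBox:
    """Snap a rough blob box to the full bright disc via a half-max rule.

    In a window around the blob centre, pixels above the midpoint between
    the local peak and the background median are taken as disc; the box is
    the (vessel-gap-closed) connected component containing the centre.
    """
    h, w = g.shape
    half = int(max(8, round(1.6 * side0)))
    r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    win = ndimage.gaussian_filter(g[r0:r1, c0:c1], 1.0)
    th = 0.5 * (win.max() + np.median(win))
    # 7x7 closing bridges both vessels and eyelash strokes crossing the disc
    disc = ndimage.binary_closing(win >= th, structure=np.ones((7, 7)))
    lab, n_lab = ndimage.label(disc)
    centre_lab = 0
    if n_lab:
        # largest component whose centroid lies near the proposal centre
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        centroids = ndimage.center_of_mass(disc, lab, range(1, n_lab + 1))
        cen = np.array([cy - r0, cx - c0])
        best_sz = 0
        for k, com in enumerate(centroids, start=1):
            if np.hypot(*(np.asarray(com) - cen)) <= max(side0, 8) \
                    and sizes[k] > best_sz:
                centre_lab, best_sz = k, sizes[k]
        if centre_lab == 0:
            centre_lab = int(sizes.argmax()) if sizes.max() > 0 else 0
    if centre_lab == 0:
        side = max(4.0, side0)
        return OpticDiscBox(x=float(np.clip(cx - side / 2, 0, w - side)),
                            y=float(np.clip(cy - side / 2, 0, h - side)),
                            w=float(side), h=float(side), prob=1.0)
    rows, cols = np.nonzero(lab == centre_lab)
    y0, y1 = rows.min() + r0, rows.max() + r0 + 1
    x0, x1 = cols.min() + c0, cols.max() + c0 + 1
    side = float(max(y1 - y0, x1 - x0))
    cy2, cx2 = (y0 + y1) / 2.0, (x0 + x1) / 2.0
    return OpticDiscBox(x=float(np.clip(cx2 - side / 2, 0, w - side)),
                        y=float(np.clip(cy2 - side / 2, 0, h - side)),
                        w=side, h=side, prob=1.0)


@dataclass
class BlobDetector:
    """Bright-blob proposals scored by a trained crop classifier.

    ``fit`` learns an OD-vs-background appearance model from ground-truth
    boxes (positives) and random off-disc crops (negatives); ``predict``
    scores each blob proposal with that model.
    """

    seed: int = 0
    margin: float = 0.25
    loss_curve: list[float] = field(default_factory=list)
    _scorer: Optional[SgdCropClassifier] = None

    def fit(self, images, boxes, config: Optional[TrainConfig] = None):
        if len(images) == 0:
            raise ValueError("empty dataset")
        if len(images) != len(boxes):
            raise ValueError("images and boxes must align")
        rng = np.random.default_rng(self.seed)
        crops, labels = [], []
        for img, box in zip(images, boxes):
            crops.append(self._crop(img, box))
            labels.append(1)
            for _ in range(2):  # negatives away from the disc
                crops.append(self._random_negative(img, box, rng))
                labels.append(0)
        self._scorer = SgdCropClassifier(seed=self.seed).fit(
            crops, labels, config)
        self.loss_curve = self._scorer.loss_curve
        return self

    def predict(self, image: FundusImage) -> list[tuple[OpticDiscBox, float]]:
        if self._scorer is None:
            raise RuntimeError("detector not fitted")
        out = []
        for box in propose_od_candidates(image):
            p = self._scorer.predict(self._crop(image, box))
            out.append((OpticDiscBox(x=box.x, y=box.y, w=box.w, h=box.h,
                                     prob=p), p))
        out.sort(key=lambda t: -t[1])
        return out

    def _crop(self, image: FundusImage, box: OpticDiscBox) -> np.ndarray:
        h, w = image.height, image.width
        m = self.margin
        r0 = int(np.clip(np.floor(box.y - m * box.h), 0, h - 2))
        r1 = int(np.clip(np.ceil(box.y + (1 + m) * box.h), r0 + 2, h))
        c0 = int(np.clip(np.floor(box.x - m * box.w), 0, w - 2))
        c1 = int(np.clip(np.ceil(box.x + (1 + m) * box.w), c0 + 2, w))
        return image.pixels[r0:r1, c0:c1]

    def _random_negative(self, image: FundusImage, box: OpticDiscBox,
                         rng: np.random.Generator) -> np.ndarray:
        h, w = image.height, image.width
        side = int(max(8, round(box.dd)))
        bx, by = box.center
        for _ in range(50):
            r = int(rng.integers(0, max(1, h - side)))
            c = int(rng.integers(0, max(1, w - side)))
            # require centre at least one diameter away from the disc
            if np.hypot(r + side / 2 - by, c + side / 2 - bx) > 1.5 * box.dd:
                return image.pixels[r:r + side, c:c + side]
        return image.pixels[0:side, 0:side]


# ----------------------------------------------------------------------------
# contract conformance


def check_contract(backend, inputs: Sequence) -> list[str]:
    """Run each input through the backend twice and collect contract
    violations: out-of-range probabilities, mismatched map dimensions,
    non-deterministic repeated predictions.  Empty list means pass.
    """
    failures: list[str] = []
    for i, x in enumerate(inputs):
        a = backend.predict(x)
        b = backend.predict(x)
        if isinstance(a, np.ndarray):
            shape = x.pixels.shape[:2] if isinstance(x, FundusImage) \
                else np.asarray(x).shape[:2]
            if a.shape != shape:
                failures.append(f"input {i}: map dims {a.shape} != {shape}")
            if a.size and (a.min() < 0 or a.max() > 1):
                failures.append(f"input {i}: map values outside [0, 1]")
            if not np.array_equal(a, b):
                failures.append(f"input {i}: non-deterministic prediction")
        elif isinstance(a, list):
            for j, (box, p) in enumerate(a):
                if not (0.0 <= p <= 1.0):
                    failures.append(f"input {i} det {j}: prob {p} outside [0, 1]")
            if [(bx.to_json(), p) for bx, p in a] != \
                    [(bx.to_json(), p) for bx, p in b]:
                failures.append(f"input {i}: non-deterministic detections")
        else:
            p = float(a)
            if not (0.0 <= p <= 1.0):
                failures.append(f"input {i}: prob {p} outside [0, 1]")
            if a != b:
                failures.append(f"input {i}: non-deterministic prediction")
    return failures


def save_backend(backend, path) -> None:
    """Serialize a trained backend (config + weights) to one file."""
    with open(path, "wb") as fh:
        pickle.dump({"class": type(backend).__name__, "backend": backend}, fh)


def load_backend(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return payload["backend"]
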