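"""Evaluation metrics: confusion-matrix rates, Cohen's kappa, overlap
coefficients, and the distorted-image agreement-study harness.

Cohen's kappa corrects the observed agreement p_o between two binary raters
for the agreement p_e expected by chance from their marginal label rates:

    kappa = (p_o - p_e) / (1 - p_e)

with p_o = (N_gg + N_bb) / T and p_e = p_yes + p_no computed from the
marginals ("good" is the positive class).  Undefined quantities (zero
denominators, degenerate marginals) are reported as ``None`` rather than
silently as zero, so they cannot corrupt averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "AgreementCounts",
    "KappaResult",
    "confusion_metrics",
    "cohen_kappa",
    "average_kappa",
    "dice_jaccard",
    "agreement_study",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("at least one count must be positive")


@dataclass(frozen=True)
class AgreementCounts:
    """Joint label counts of two binary raters; g = good, b = bad.

    ``n_gb`` is the number of items the first rater called good and the
    second called bad.
    """

    n_gg: int
    n_gb: int
    n_bg: int
    n_bb: int

    def __post_init__(self) -> None:
        for name in ("n_gg", "n_gb", "n_bg", "n_bb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("at least one count must be positive")

    @property
    def total(self) -> int:
        return self.n_gg + self.n_gb + self.n_bg + self.n_bb


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]
    po: float
    pe: float
    p_yes: float
    p_no: float


def confusion_metrics(c: ConfusionCounts
                      ) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(accuracy, sensitivity, specificity); ``None`` where undefined.

    accuracy = (TP + TN) / (TP + FN + FP + TN);
    sensitivity = TP / (TP + FN); specificity = TN / (TN + FP).
    """
    total = c.tp + c.tn + c.fp + c.fn
    accuracy = (c.tp + c.tn) / total
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return accuracy, sensitivity, specificity


def cohen_kappa(a: AgreementCounts) -> KappaResult:
    """Chance-corrected agreement of two binary raters.

    Returns kappa ``None`` when the marginals are degenerate (p_e = 1, both
    raters constant), where chance correction is undefined.
    """
    t = a.total
    po = (a.n_gg + a.n_bb) / t
    p_yes = ((a.n_gg + a.n_gb) / t) * ((a.n_gg + a.n_bg) / t)
    p_no = ((a.n_bg + a.n_bb) / t) * ((a.n_gb + a.n_bb) / t)
    pe = p_yes + p_no
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else None
    return KappaResult(kappa=kappa, po=po, pe=pe, p_yes=p_yes, p_no=p_no)


def average_kappa(pairs: Sequence[AgreementCounts]) -> float:
    """Arithmetic mean of the member kappas (e.g. over expert/rater pairs).

    Raises on an empty list or when any member kappa is undefined.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one rater pair")
    kappas = []
    for a in pairs:
        r = cohen_kappa(a)
        if r.kappa is None:
            raise ValueError("cannot average undefined kappa (degenerate pair)")
        kappas.append(r.kappa)
    return float(np.mean(kappas))


def dice_jaccard(mask_a: np.ndarray, mask_b: np.ndarray
                 ) -> tuple[Optional[float], Optional[float]]:
    """DICE and Jaccard overlap of two equal-size binary masks.

    D = 2|A n B| / (|A| + |B|), J = |A n B| / |A u B|; the identity
    J = D / (2 - D) holds for every pair.  Both are ``None`` when both masks
    are empty.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dims differ: {a.shape} vs {b.shape}")
    inter = int(np.logical_and(a, b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return None, None
    dice = 2.0 * inter / (sa + sb)
    jaccard = inter / (sa + sb - inter)
    return dice, jaccard


Rater = Callable[[object], str]  # image -> "good" | "bad"


def agreement_study(raters: Sequence[Rater], images: Sequence
                    ) -> tuple[np.ndarray, list[list[Optional[AgreementCounts]]]]:
    """Pairwise kappa over a shared image set.

    Each rater maps an image to "good" or "bad" (anything else raises).
    Returns the symmetric kappa matrix (NaN where undefined) and the matrix
    of :class:`AgreementCounts` (``None`` on the diagonal definition still
    holds — the diagonal is a rater against itself).
    """
    n = len(raters)
    labels = np.empty((n, len(images)), dtype=bool)  # True = good
    for i, rater in enumerate(raters):
        for j, img in enumerate(images):
            v = rater(img)
            if v not in ("good", "bad"):
                raise ValueError(f"rater {i} returned non-binary label {v!r}")
            labels[i, j] = (v == "good")
    kmat = np.full((n, n), np.nan)
    counts: list[list[Optional[AgreementCounts]]] = \
        [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = labels[i], labels[j]
            c = AgreementCounts(
                n_gg=int(np.sum(a & b)), n_gb=int(np.sum(a & ~b)),
                n_bg=int(np.sum(~a & b)), n_bb=int(np.sum(~a & ~b)))
            counts[i][j] = c
            r = cohen_kappa(c)
            if r.kappa is not None:
                kmat[i, j] = r.kappa
    return kmat, counts
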