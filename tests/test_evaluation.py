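"""Metrics: confusion rates, Cohen's kappa, DICE/Jaccard, agreement studies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from fundustriage.evaluation import (AgreementCounts, ConfusionCounts,
                                     agreement_study, average_kappa,
                                     cohen_kappa, confusion_metrics,
                                     dice_jaccard)

counts = st.integers(min_value=0, max_value=200)


def test_confusion_worked_example():
    acc, sens, spec = confusion_metrics(ConfusionCounts(tp=8, tn=5, fp=5, fn=2))
    assert acc == pytest.approx(0.65)
    assert sens == pytest.approx(0.8)
    assert spec == pytest.approx(0.5)


def test_confusion_perfect_classifier():
    acc, sens, spec = confusion_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
    assert (acc, sens, spec) == (1.0, 1.0, 1.0)


def test_confusion_undefined_rates_are_none():
    acc, sens, spec = confusion_metrics(ConfusionCounts(tp=0, tn=9, fp=1, fn=0))
    assert sens is None and spec == 0.9
    acc, sens, spec = confusion_metrics(ConfusionCounts(tp=9, tn=0, fp=0, fn=1))
    assert spec is None and sens == 0.9


def test_confusion_matches_brute_force_counting():
    rng = np.random.default_rng(0)
    for _ in range(200):
        truth = rng.random(40) < 0.5
        pred = rng.random(40) < 0.5
        c = ConfusionCounts(tp=int((truth & pred).sum()),
                            tn=int((~truth & ~pred).sum()),
                            fp=int((~truth & pred).sum()),
                            fn=int((truth & ~pred).sum()))
        acc, _, _ = confusion_metrics(c)
        assert acc == pytest.approx(np.mean(truth == pred))


def test_confusion_rejects_negative_or_empty():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, tn=1, fp=0, fn=0)
    with pytest.raises(ValueError):
        ConfusionCounts(tp=0, tn=0, fp=0, fn=0)


def test_kappa_worked_example():
    r = cohen_kappa(AgreementCounts(n_gg=40, n_gb=10, n_bg=5, n_bb=45))
    assert r.po == pytest.approx(0.85)
    assert r.p_yes == pytest.approx(0.225)
    assert r.p_no == pytest.approx(0.275)
    assert r.pe == pytest.approx(0.50)
    assert r.kappa == pytest.approx(0.70)


def test_kappa_edge_values():
    assert cohen_kappa(AgreementCounts(50, 0, 0, 50)).kappa == pytest.approx(1.0)
    assert cohen_kappa(AgreementCounts(25, 25, 25, 25)).kappa == pytest.approx(0.0)
    assert cohen_kappa(AgreementCounts(0, 50, 50, 0)).kappa == pytest.approx(-1.0)


def test_kappa_undefined_for_degenerate_marginals():
    assert cohen_kappa(AgreementCounts(100, 0, 0, 0)).kappa is None


@settings(deadline=None, max_examples=300, derandomize=True)
@given(n_gg=counts, n_gb=counts, n_bg=counts, n_bb=counts)
def test_kappa_bounded_and_symmetric(n_gg, n_gb, n_bg, n_bb):
    if n_gg + n_gb + n_bg + n_bb == 0:
        return
    a = AgreementCounts(n_gg, n_gb, n_bg, n_bb)
    r = cohen_kappa(a)
    if r.kappa is not None:
        assert -1.0 - 1e-12 <= r.kappa <= 1.0 + 1e-12
    # swapping the raters transposes the table; kappa is unchanged
    swapped = cohen_kappa(AgreementCounts(n_gg, n_bg, n_gb, n_bb))
    assert (r.kappa is None) == (swapped.kappa is None)
    if r.kappa is not None:
        assert swapped.kappa == pytest.approx(r.kappa)


def test_kappa_matches_sklearn_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        a = rng.random(60) < rng.uniform(0.2, 0.8)
        b = rng.random(60) < rng.uniform(0.2, 0.8)
        ours = cohen_kappa(AgreementCounts(
            n_gg=int((a & b).sum()), n_gb=int((a & ~b).sum()),
            n_bg=int((~a & b).sum()), n_bb=int((~a & ~b).sum()))).kappa
        theirs = cohen_kappa_score(a, b)
        if np.isnan(theirs):
            assert ours is None
        else:
            assert ours == pytest.approx(theirs)


def test_average_kappa():
    pairs = [AgreementCounts(40, 10, 5, 45), AgreementCounts(25, 25, 25, 25)]
    assert average_kappa(pairs) == pytest.approx(0.35)
    with pytest.raises(ValueError):
        average_kappa([])
    with pytest.raises(ValueError):
        average_kappa([AgreementCounts(10, 0, 0, 0)])


def test_dice_jaccard_worked_example():
    a = np.zeros(200, dtype=bool)
    b = np.zeros(200, dtype=bool)
    a[:100] = True
    b[50:150] = True  # |A| = |B| = 100, intersection = 50
    dice, jac = dice_jaccard(a, b)
    assert dice == pytest.approx(0.5)
    assert jac == pytest.approx(1 / 3)


def test_dice_jaccard_edges():
    a = np.ones((5, 5), dtype=bool)
    assert dice_jaccard(a, a) == (1.0, 1.0)
    assert dice_jaccard(a, ~a) == (0.0, 0.0)
    assert dice_jaccard(~a, ~a) == (None, None)
    with pytest.raises(ValueError):
        dice_jaccard(np.ones(4, bool), np.ones(5, bool))


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_jaccard_dice_identity(seed):
    rng = np.random.default_rng(seed)
    a = rng.random(50) < 0.4
    b = rng.random(50) < 0.4
    dice, jac = dice_jaccard(a, b)
    if dice is not None:
        assert jac == pytest.approx(dice / (2.0 - dice))


def test_agreement_study_self_and_opposite():
    items = list(range(10))

    def even(i):
        return "good" if i % 2 == 0 else "bad"

    def odd(i):
        return "bad" if i % 2 == 0 else "good"

    kmat, cmat = agreement_study([even, even, odd], items)
    assert kmat[0, 1] == pytest.approx(1.0)
    assert kmat[0, 2] == pytest.approx(-1.0)
    assert np.allclose(kmat, kmat.T, equal_nan=True)
    assert cmat[0][2].n_gg == 0 and cmat[0][2].n_gb == 5


def test_agreement_study_rejects_non_binary_labels():
    with pytest.raises(ValueError):
        agreement_study([lambda i: "maybe"], [1, 2])
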