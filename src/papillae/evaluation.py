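"""Segmentation-quality metrics and the leave-2-out scoring protocol.

Masks are scored pixelwise with three standard measures: the F1-score
(robust to the extreme papilla/background class imbalance), the area under
the ROC curve over the continuous probabilities (computed by the
Mann-Whitney rank statistic, exact on small grids), and Cohen's kappa
(chance-corrected agreement).  By default metrics are computed over tongue
pixels only — scoring the large off-tongue background would inflate the
true-negative count and flatter every metric.

Leave-2-out cross-validation scores a small annotated set without
information leak: two samples are held out per fold, a model is trained on
the rest, and every sample is scored exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def confusion(
    pred: np.ndarray, truth: np.ndarray, support: np.ndarray | None = None
) -> ConfusionCounts:
    """Pixelwise confusion counts, optionally restricted to a support mask."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if support is not None:
        sup = np.asarray(support).astype(bool)
        p, t = p[sup], t[sup]
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def f1_from_confusion(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 1.0


def kappa_from_confusion(c: ConfusionCounts) -> float:
    """Cohen's kappa from the marginals: (p_o - p_e) / (1 - p_e)."""
    n = c.total
    p_o = (c.tp + c.tn) / n
    p_yes = ((c.tp + c.fp) / n) * ((c.tp + c.fn) / n)
    p_no = ((c.fn + c.tn) / n) * ((c.fp + c.tn) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def auc_roc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation (ties get average rank).

    Returns NaN when the truth contains a single class (AUC undefined).
    """
    t = np.asarray(truth).astype(bool).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return (ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def f1_auc_kappa(
    pred_prob: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
    support: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(F1, AUC-ROC, Cohen's kappa) of a probability map against a mask.

    F1 and kappa are computed on the map thresholded at ``threshold``; AUC
    uses the continuous probabilities and is NaN for single-class truth.
    """
    prob = np.asarray(pred_prob, dtype=np.float64)
    t = np.asarray(truth).astype(bool)
    if prob.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {prob.shape} vs truth {t.shape}")
    if support is not None:
        sup = np.asarray(support).astype(bool)
        prob, t = prob[sup], t[sup]
    c = confusion(prob >= threshold, t)
    return f1_from_confusion(c), auc_roc(prob, t), kappa_from_confusion(c)


def leave_two_out(
    annotated_set: Sequence[tuple[np.ndarray, np.ndarray]],
    trainer: Callable[[list[tuple[np.ndarray, np.ndarray]]], Callable[[np.ndarray], np.ndarray]],
    seed: int = 0,
    threshold: float = 0.5,
    supports: Sequence[np.ndarray] | None = None,
) -> list[dict[str, float]]:
    """Leave-2-out cross-validation over an annotated (image, truth) set.

    ``trainer`` maps a training subset to a predictor (image -> probability
    map).  Samples are paired consecutively after a seeded shuffle; each
    fold trains on the rest and scores the held-out pair, so every sample
    is scored exactly once.  Returns one dict per sample (in input order)
    with keys ``sample``, ``F1``, ``AUC``, ``kappa``.
    """
    n = len(annotated_set)
    if n < 4:
        raise ValueError("leave-2-out needs at least 4 annotated samples")
    order = np.random.default_rng(seed).permutation(n)
    folds = [order[i : i + 2] for i in range(0, n, 2)]
    results: dict[int, dict[str, float]] = {}
    for fold in folds:
        held = set(int(i) for i in fold)
        train_subset = [annotated_set[i] for i in range(n) if i not in held]
        predictor = trainer(train_subset)
        for i in held:
            image, truth = annotated_set[i]
            sup = supports[i] if supports is not None else None
            f1, auc, kappa = f1_auc_kappa(predictor(image), truth, threshold, sup)
            results[i] = {"sample": float(i), "F1": f1, "AUC": auc, "kappa": kappa}
    return [results[i] for i in range(n)]
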