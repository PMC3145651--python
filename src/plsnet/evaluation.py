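"""Confusion metrics, ROC/AUC, repeated random-split validation and
stratified k-fold cross-validation of signature classifiers.

Accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
The ROC is the empirical curve over all distinct score cutoffs and the AUC is
its trapezoidal area (ties between case and control scores count one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .datasets import ExpressionDataset, GeneSet
from .pls import HubScoreClassifier

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "EvaluationSummary",
    "confusion",
    "metrics",
    "roc_auc",
    "repeated_split_eval",
    "kfold_cv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true: Sequence[int], pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(true, dtype=int)
    p = np.asarray(pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and pred must be 1-d and the same length")
    if t.size == 0:
        raise ValueError("empty prediction vectors")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); undefined ratios become NaN with
    a warning (e.g. sensitivity when no positives were tested)."""
    if c.n == 0:
        raise ValueError("empty confusion table")
    acc = (c.tp + c.tn) / c.n
    if c.tp + c.fn == 0:
        warnings.warn("no positive samples: sensitivity undefined", UserWarning)
        sens = float("nan")
    else:
        sens = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        warnings.warn("no negative samples: specificity undefined", UserWarning)
        spec = float("nan")
    else:
        spec = c.tn / (c.tn + c.fp)
    return acc, sens, spec


@dataclass
class ROCCurve:
    """Empirical ROC: per cutoff the (sensitivity, specificity) pair, with the
    trapezoidal area. Cutoffs descend so sensitivity is non-decreasing."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes must be present")
    fpr, tpr, cutoffs = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(cutoffs=cutoffs, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


@dataclass
class EvaluationSummary:
    """Per-repeat test accuracy and AUC with their mean +/- SD."""

    accuracies: np.ndarray
    aucs: np.ndarray
    n_repeats: int
    train_fraction: float
    seed: int | None
    n_resampled: int = 0  # degenerate splits that had to be redrawn

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if self.n_repeats > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "accuracy_mean_pct": 100.0 * self.accuracy_mean,
            "accuracy_sd_pct": 100.0 * self.accuracy_sd,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
        }

    def __str__(self) -> str:
        return (
            f"accuracy {100 * self.accuracy_mean:.2f}% +/- {100 * self.accuracy_sd:.2f}%, "
            f"AUC {self.auc_mean:.3f} +/- {self.auc_sd:.3f} "
            f"({self.n_repeats} repeats)"
        )


def _splits(
    y: np.ndarray, n_repeats: int, train_fraction: float, seed: int | None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test splits (both classes in both halves)."""
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats,
        train_size=train_fraction,
        random_state=None if seed is None else seed % (2**32),
    )
    return [(tr, te) for tr, te in splitter.split(np.zeros_like(y), y)]


def _fit_eval_split(
    ds: ExpressionDataset,
    genes: Sequence[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    n_components: int,
) -> tuple[float, float]:
    """One fit/evaluate cycle; returns (test accuracy, test AUC)."""
    x = ds.values.loc[list(genes)].to_numpy().T
    y = ds.labels
    est = HubScoreClassifier(n_components=n_components)
    est.fit(x[train_idx], y[train_idx])
    pred = est.predict(x[test_idx])
    acc = float(np.mean(pred == y[test_idx]))
    auc = roc_auc(est.score_samples(x[test_idx]), y[test_idx]).auc
    return acc, auc


def repeated_split_eval(
    ds: ExpressionDataset,
    genes: GeneSet | Sequence[str],
    n_repeats: int = 100,
    train_fraction: float = 0.5,
    seed: int | None = None,
    n_components: int = 1,
) -> EvaluationSummary:
    """Repeatedly split into stratified train/test halves, train the signature
    classifier (threshold from the training half only) and record test
    accuracy and AUC."""
    ds.require_complete()
    ds.require_two_classes()
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    gene_list = list(genes)
    accs, aucs = [], []
    for train_idx, test_idx in _splits(ds.labels, n_repeats, train_fraction, seed):
        acc, auc = _fit_eval_split(ds, gene_list, train_idx, test_idx, n_components)
        accs.append(acc)
        aucs.append(auc)
    return EvaluationSummary(
        accuracies=np.array(accs),
        aucs=np.array(aucs),
        n_repeats=n_repeats,
        train_fraction=train_fraction,
        seed=seed,
    )


def kfold_cv(
    ds: ExpressionDataset,
    genes: GeneSet | Sequence[str],
    k: int = 5,
    seed: int | None = None,
    n_components: int = 1,
) -> list[ROCCurve]:
    """Stratified k-fold cross-validation; one test ROC per fold."""
    ds.require_complete()
    ds.require_two_classes()
    min_class = int(min((ds.labels == 1).sum(), (ds.labels == 0).sum()))
    if not 2 <= k <= min_class:
        raise ValueError(f"k must lie in [2, min class size = {min_class}]")
    x = ds.values.loc[list(genes)].to_numpy().T
    y = ds.labels
    folds = StratifiedKFold(
        n_splits=k, shuffle=True,
        random_state=None if seed is None else seed % (2**32),
    )
    curves = []
    for train_idx, test_idx in folds.split(x, y):
        est = HubScoreClassifier(n_components=n_components)
        est.fit(x[train_idx], y[train_idx])
        curves.append(roc_auc(est.score_samples(x[test_idx]), y[test_idx]))
    return curves
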