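"""The hub-gene partial least squares score classifier.

The classifier projects standardized expression of a small gene signature onto
a single weight vector chosen to maximize covariance with the class indicator:
with X the standardized samples x genes matrix and ``y_c`` the centered 0/1
labels, the one-component weight vector is the closed form

    w = X^T y_c / ||X^T y_c||            (||w||_2 = 1)

and each sample receives the score ``S = sum_i w_i (x_i - m_i) / s_i`` using
the training means ``m`` and standard deviations ``s``. A decision threshold
``theta`` is picked on the training scores by maximizing Youden's
J = sensitivity + specificity - 1 over all candidate cutoffs; a sample is
called a case when ``S >= theta``. More than one latent component can be
requested, in which case NIPALS deflation is run and the equivalent single
coefficient vector (rescaled to unit norm) is used, so the score formula is
unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .datasets import ExpressionDataset, GeneSet

__all__ = [
    "HubScoreClassifier",
    "PLSModel",
    "fit_weights",
    "select_threshold",
    "fit",
    "compute_scores",
    "classify",
]


def _nipals_weights(xs: np.ndarray, yc: np.ndarray, n_components: int) -> np.ndarray:
    """Unit-norm coefficient vector equivalent to ``n_components`` PLS1
    components fitted on standardized ``xs`` and centered ``yc``."""
    n, p = xs.shape
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components must lie in [1, min(n_genes, n_samples - 1)] = "
            f"[1, {min(p, n - 1)}]"
        )
    cross = xs.T @ yc
    norm = np.linalg.norm(cross)
    if norm == 0:
        raise ValueError("predictors carry no covariance with the labels")
    if n_components == 1:
        return cross / norm

    xd = xs.copy()
    ws, ps, qs = [], [], []
    for _ in range(n_components):
        w = xd.T @ yc
        wn = np.linalg.norm(w)
        if wn < 1e-12:
            break  # remaining components are degenerate
        w /= wn
        t = xd @ w
        tt = float(t @ t)
        ps.append(xd.T @ t / tt)
        qs.append(float(yc @ t) / tt)
        ws.append(w)
        xd = xd - np.outer(t, ps[-1])
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_vec = np.array(qs)
    coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    return coef / np.linalg.norm(coef)


def select_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Training cutoff maximizing Youden's J (ties -> smallest cutoff).

    Candidates are the midpoints between adjacent distinct sorted scores plus
    sentinels below the minimum and above the maximum; the decision rule is
    ``score >= theta -> case``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and the same length")
    n_case, n_control = int((y == 1).sum()), int((y == 0).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be present to select a threshold")
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    pred = s[None, :] >= candidates[:, None]  # candidates x samples
    sens = (pred & (y == 1)).sum(axis=1) / n_case
    spec = (~pred & (y == 0)).sum(axis=1) / n_control
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(candidates[best[0]])


class HubScoreClassifier(ClassifierMixin, BaseEstimator):
    """PLS score classifier for two-class expression data.

    Parameters
    ----------
    n_components : number of latent PLS components (default 1, the closed
        form; the multi-component fit still collapses to one unit-norm
        coefficient vector).

    Attributes (after fit)
    ----------------------
    classes_ : the two class labels; ``classes_[1]`` is the case/tumor class.
    weights_ : unit-norm coefficient vector, zeros for zero-variance genes.
    center_, scale_ : training means / standard deviations per gene.
    threshold_ : decision threshold on the score (>= threshold -> case).
    """

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=4)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("HubScoreClassifier requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        if (y01 == 1).sum() < 2 or (y01 == 0).sum() < 2:
            raise ValueError("need at least 2 samples per class")

        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        usable = scale > 0
        if not usable.any():
            raise ValueError("all predictors have zero training variance")
        if not usable.all():
            warnings.warn(
                f"dropping {int((~usable).sum())} zero-variance predictor(s)",
                UserWarning,
                stacklevel=2,
            )
        self.scale_ = np.where(usable, scale, 1.0)
        xs = (X[:, usable] - self.center_[usable]) / self.scale_[usable]
        yc = y01 - y01.mean()
        w = _nipals_weights(xs, yc, self.n_components)
        self.weights_ = np.zeros(X.shape[1])
        self.weights_[usable] = w
        self.threshold_ = select_threshold(self.score_samples(X), y01.astype(int))
        return self

    def score_samples(self, X) -> np.ndarray:
        """Raw PLS score S per sample."""
        check_is_fitted(self, "center_")
        X = validate_data(self, X, reset=False)
        return ((X - self.center_) / self.scale_) @ self.weights_

    def decision_function(self, X) -> np.ndarray:
        return self.score_samples(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


# ---------------------------------------------------------------------------
# functional interface over ExpressionDataset
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A trained signature classifier: genes, weights, scaling, threshold."""

    genes: tuple[str, ...]
    weights: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    threshold: float
    n_components: int = 1

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "weights": [float(v) for v in self.weights],
            "center": [float(v) for v in self.center],
            "scale": [float(v) for v in self.scale],
            "threshold": float(self.threshold),
            "n_components": int(self.n_components),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=tuple(d["genes"]),
            weights=np.array(d["weights"], dtype=float),
            center=np.array(d["center"], dtype=float),
            scale=np.array(d["scale"], dtype=float),
            threshold=float(d["threshold"]),
            n_components=int(d["n_components"]),
        )


def fit_weights(
    ds: ExpressionDataset, n_components: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weights, centers and scales for all genes of ``ds`` (already restricted
    to the predictor signature)."""
    est = HubScoreClassifier(n_components=n_components).fit(ds.X, ds.y)
    return est.weights_, est.center_, est.scale_


def fit(
    train: ExpressionDataset, genes: GeneSet | Sequence[str], n_components: int = 1
) -> PLSModel:
    """Restrict to the signature, fit weights and pick the training threshold."""
    gene_list = list(genes)
    sub = train.restrict(gene_list)
    sub.require_complete()
    sub.require_two_classes()
    est = HubScoreClassifier(n_components=n_components).fit(sub.X, sub.y)
    return PLSModel(
        genes=tuple(gene_list),
        weights=est.weights_,
        center=est.center_,
        scale=est.scale_,
        threshold=est.threshold_,
        n_components=n_components,
    )


def compute_scores(model: PLSModel, ds: ExpressionDataset) -> np.ndarray:
    """Per-sample score S = sum_i w_i (x_i - center_i)/scale_i, matched by
    gene id (row order of ``ds`` is irrelevant)."""
    missing = [g for g in model.genes if g not in ds.values.index]
    if missing:
        raise KeyError(f"model gene(s) absent from data: {missing}")
    x = ds.values.loc[list(model.genes)].to_numpy().T
    return ((x - model.center) / model.scale) @ model.weights


def classify(model: PLSModel, ds: ExpressionDataset) -> np.ndarray:
    """1 (case) where score >= threshold, else 0."""
    return (compute_scores(model, ds) >= model.threshold).astype(int)
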