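"""Per-gene two-sample differential testing with FDR control, concept-list
filtering and cross-dataset intersection of candidate marker genes.

The per-gene statistic is the classical pooled-variance Student t (Welch
available via ``equal_var=False``); multiplicity is controlled with
Benjamini-Hochberg adjusted q-values. A gene is an up-candidate when it passes
the q cut-off with case mean > control mean in every dataset (and, when a
concept gene set is supplied, belongs to it); down-candidates symmetrically.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset, GeneSet

__all__ = [
    "per_gene_ttest",
    "bh_qvalues",
    "select_candidates",
    "TTestFDRSelector",
]


def _ttest_arrays(
    case: np.ndarray, control: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t; zero-variance rows get t=0, p=1."""
    with warnings.catch_warnings():
        # constant rows trigger a precision warning; they are mapped to
        # (t=0, p=1) below, so the warning is moot
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.ttest_ind(case, control, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return t, p


def per_gene_ttest(ds: ExpressionDataset, equal_var: bool = True) -> pd.DataFrame:
    """Differential-expression table: per gene the Student t statistic,
    two-sided p, BH q, group means and direction (up = case mean higher).

    Requires a complete matrix with >= 2 samples per class.
    """
    ds.require_complete()
    case = ds.values.loc[:, ds.labels == 1].to_numpy()
    control = ds.values.loc[:, ds.labels == 0].to_numpy()
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 samples in each class")
    t, p = _ttest_arrays(case, control, equal_var=equal_var)
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    return pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "q_value": bh_qvalues(p),
            "mean_case": mean_case,
            "mean_control": mean_control,
            "direction": np.where(mean_case > mean_control, "up", "down"),
        },
        index=pd.Index(ds.gene_ids, name="gene"),
    )


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_candidates(
    tables: Iterable[pd.DataFrame],
    q_threshold: float = 0.05,
    concept: GeneSet | None = None,
    require_all: bool = True,
) -> tuple[GeneSet, GeneSet]:
    """Intersect differential-expression tables into (up, down) candidates.

    A gene qualifies as an up-candidate when ``q <= q_threshold`` with
    direction "up" in every table (``require_all=True``; any table otherwise),
    restricted to ``concept`` when given. Output order follows the first table.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("at least one differential-expression table required")
    if not 0.0 < q_threshold <= 1.0:
        raise ValueError("q_threshold must lie in (0, 1]")

    def hits(table: pd.DataFrame, direction: str) -> set[str]:
        sel = (table["q_value"] <= q_threshold) & (table["direction"] == direction)
        return set(table.index[sel])

    combine = set.intersection if require_all else set.union
    up = combine(*(hits(t, "up") for t in tables))
    down = combine(*(hits(t, "down") for t in tables))
    up -= down  # a gene cannot be both (possible only with require_all=False)
    if concept is not None:
        keep = set(concept)
        up &= keep
        down &= keep
    order = {g: i for i, g in enumerate(tables[0].index)}
    key = lambda g: (order.get(g, len(order)), g)
    return (
        GeneSet("up_candidates", tuple(sorted(up, key=key))),
        GeneSet("down_candidates", tuple(sorted(down, key=key))),
    )


class TTestFDRSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector keeping genes with BH q <= threshold.

    Fits on samples x genes ``X`` and binary ``y``; exposes ``tstats_``,
    ``pvalues_`` and ``qvalues_`` and composes with sklearn pipelines.
    """

    def __init__(self, q_threshold: float = 0.05, equal_var: bool = True):
        self.q_threshold = q_threshold
        self.equal_var = equal_var

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("TTestFDRSelector requires exactly two classes")
        case = X[y == classes[1]].T
        control = X[y == classes[0]].T
        if case.shape[1] < 2 or control.shape[1] < 2:
            raise ValueError("need at least 2 samples in each class")
        self.tstats_, self.pvalues_ = _ttest_arrays(
            case, control, equal_var=self.equal_var
        )
        self.qvalues_ = bh_qvalues(self.pvalues_)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.qvalues_ <= self.q_threshold
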