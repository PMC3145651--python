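"""Signature-perturbation experiments probing whether network topology drives
classifier performance.

Two designs, both repeated over shared stratified train/test splits so that
configurations are compared on identical resamples:

addition
    keep all hub genes and add k randomly drawn non-hub genes
    (k = 0 is the unperturbed baseline);
substitution
    keep the signature size fixed and replace hubs with randomly drawn
    non-hubs (hub_count = signature size is the baseline).

Each configuration is compared with the baseline by pooling every test
prediction over all repeats into a 2x2 (configuration x correct/incorrect)
table and applying the two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical import ContingencyTable2x2, fisher_exact_2x2
from .datasets import ExpressionDataset, GeneSet
from .evaluation import _fit_eval_split, _splits, roc_auc
from .pls import HubScoreClassifier

__all__ = [
    "ConfigurationResult",
    "PerturbationResult",
    "addition_experiment",
    "substitution_experiment",
    "compare_performance",
]


@dataclass
class ConfigurationResult:
    """Pooled outcome of one hub/non-hub configuration."""

    hub_count: int
    nonhub_count: int
    accuracies: np.ndarray
    aucs: np.ndarray
    correct: np.ndarray  # pooled per-prediction correctness over all repeats
    p_vs_baseline: float | None = None

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass
class PerturbationResult:
    configs: list[ConfigurationResult]
    n_repeats: int
    seed: int | None
    mode: str

    @property
    def baseline(self) -> ConfigurationResult:
        if self.mode == "addition":
            return next(c for c in self.configs if c.nonhub_count == 0)
        size = self.configs[0].hub_count + self.configs[0].nonhub_count
        return next(c for c in self.configs if c.hub_count == size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hub_count": [c.hub_count for c in self.configs],
                "nonhub_count": [c.nonhub_count for c in self.configs],
                "accuracy_mean": [c.accuracy_mean for c in self.configs],
                "accuracy_sd": [c.accuracy_sd for c in self.configs],
                "auc_mean": [c.auc_mean for c in self.configs],
                "auc_sd": [c.auc_sd for c in self.configs],
                "p_vs_baseline": [c.p_vs_baseline for c in self.configs],
            }
        )


def compare_performance(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> float:
    """Two-sided Fisher exact p for the 2x2 table
    {configuration A, B} x {correct, incorrect} of pooled predictions."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty prediction vectors")
    table = ContingencyTable2x2(
        int(a.sum()), int(a.size - a.sum()), int(b.sum()), int(b.size - b.sum())
    )
    return fisher_exact_2x2(table)


def _run_configuration(
    ds: ExpressionDataset,
    hubs: GeneSet,
    nonhub_pool: GeneSet,
    hub_count: int,
    nonhub_count: int,
    splits: list[tuple[np.ndarray, np.ndarray]],
    seed: int | None,
    n_components: int,
) -> ConfigurationResult:
    hub_list, pool_list = list(hubs), list(nonhub_pool)
    # configuration-specific stream keyed by the counts, not list position,
    # so aggregates are invariant to configuration ordering
    entropy = [0 if seed is None else int(seed), hub_count, nonhub_count]
    rng = np.random.default_rng(entropy)
    y = ds.labels
    accs, aucs, correct = [], [], []
    for train_idx, test_idx in splits:
        drawn_hubs = (
            hub_list
            if hub_count == len(hub_list)
            else list(rng.choice(hub_list, size=hub_count, replace=False))
        )
        drawn_nonhubs = (
            list(rng.choice(pool_list, size=nonhub_count, replace=False))
            if nonhub_count
            else []
        )
        genes = drawn_hubs + drawn_nonhubs
        x = ds.values.loc[genes].to_numpy().T
        est = HubScoreClassifier(n_components=n_components)
        est.fit(x[train_idx], y[train_idx])
        pred = est.predict(x[test_idx])
        ok = pred == y[test_idx]
        correct.append(ok)
        accs.append(float(ok.mean()))
        aucs.append(roc_auc(est.score_samples(x[test_idx]), y[test_idx]).auc)
    return ConfigurationResult(
        hub_count=hub_count,
        nonhub_count=nonhub_count,
        accuracies=np.array(accs),
        aucs=np.array(aucs),
        correct=np.concatenate(correct),
    )


def _check_pools(hubs: GeneSet, pool: GeneSet, needed: int) -> None:
    overlap = set(hubs) & set(pool)
    if overlap:
        raise ValueError(f"non-hub pool overlaps hubs: {sorted(overlap)[:5]}")
    if len(pool) < needed:
        raise ValueError(f"non-hub pool has {len(pool)} genes; need >= {needed}")


def addition_experiment(
    ds: ExpressionDataset,
    hubs: GeneSet,
    nonhub_pool: GeneSet,
    added_counts: Sequence[int] = (1, 2, 4, 6, 8),
    n_repeats: int = 100,
    train_fraction: float = 0.5,
    seed: int | None = None,
    n_components: int = 1,
) -> PerturbationResult:
    """Dilute the hub signature with k random non-hub genes per repeat.

    The k = 0 baseline is always included; every configuration is evaluated on
    the same stratified splits.
    """
    ds.require_complete()
    ds.require_two_classes()
    counts = sorted({0, *map(int, added_counts)})
    _check_pools(hubs, nonhub_pool, max(counts))
    splits = _splits(ds.labels, n_repeats, train_fraction, seed)
    configs = [
        _run_configuration(
            ds, hubs, nonhub_pool, len(hubs), k, splits, seed, n_components
        )
        for k in counts
    ]
    result = PerturbationResult(configs, n_repeats, seed, mode="addition")
    base = result.baseline
    for c in configs:
        c.p_vs_baseline = 1.0 if c is base else compare_performance(c.correct, base.correct)
    return result


def substitution_experiment(
    ds: ExpressionDataset,
    hubs: GeneSet,
    nonhub_pool: GeneSet,
    hub_counts: Sequence[int] = (7, 6, 5, 4, 3, 2, 1, 0),
    signature_size: int = 7,
    n_repeats: int = 100,
    train_fraction: float = 0.5,
    seed: int | None = None,
    n_components: int = 1,
) -> PerturbationResult:
    """Replace hubs with random non-hubs at fixed signature size.

    ``hub_count = signature_size`` is the all-hub baseline.
    """
    ds.require_complete()
    ds.require_two_classes()
    if signature_size > len(hubs):
        raise ValueError("signature_size exceeds the number of hub genes")
    counts = sorted({int(h) for h in hub_counts} | {signature_size}, reverse=True)
    if any(h < 0 or h > signature_size for h in counts):
        raise ValueError("hub counts must lie in [0, signature_size]")
    _check_pools(hubs, nonhub_pool, signature_size)
    splits = _splits(ds.labels, n_repeats, train_fraction, seed)
    configs = [
        _run_configuration(
            ds, hubs, nonhub_pool, h, signature_size - h, splits, seed, n_components
        )
        for h in counts
    ]
    result = PerturbationResult(configs, n_repeats, seed, mode="substitution")
    base = result.baseline
    for c in configs:
        c.p_vs_baseline = 1.0 if c is base else compare_performance(c.correct, base.correct)
    return result
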