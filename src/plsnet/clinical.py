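"""Exact 2x2 association tests and the immunohistochemistry (IHC)
semiquantitative composite score.

The composite score sums, over staining components of a specimen, the product
of intensity grade (0 negative, 1 weak, 2 moderate, 3 strong) and the
percentage of tumor cells at that grade; a specimen scoring at least 100 is
called marker-positive. Associations between binary variables are tested with
the two-sided Fisher exact test (probability-mass criterion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "ContingencyTable2x2",
    "IHCSample",
    "fisher_exact_2x2",
    "ihc_composite_score",
    "group_association",
    "positivity_rate",
]

POSITIVITY_CUTOFF = 100.0
VALID_GRADES = (0, 1, 2, 3)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d): rows = groups, columns = e.g. negative/positive."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise ValueError("table counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value.

    Sums hypergeometric probabilities of all margin-fixed tables no more
    probable than the observed one; a zero margin gives p = 1 (no variation).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


@dataclass(frozen=True)
class IHCSample:
    components: tuple[tuple[int, float], ...]
    score: float
    positive: bool


def ihc_composite_score(components: Sequence[tuple[int, float]]) -> IHCSample:
    """Intensity-weighted percentage score of an IHC specimen.

    ``components`` pairs an intensity grade (0-3) with the percentage of tumor
    cells showing it; score = sum(grade x percentage), positive iff >= 100.
    E.g. 50% moderate (grade 2) + 50% strong (grade 3) scores 250.
    """
    comps = []
    total_pct = 0.0
    for grade, pct in components:
        if grade not in VALID_GRADES:
            raise ValueError(f"intensity grade must be one of {VALID_GRADES}, got {grade}")
        if pct < 0:
            raise ValueError("percentages must be non-negative")
        total_pct += pct
        comps.append((int(grade), float(pct)))
    if total_pct > 100.0 + 1e-9:
        raise ValueError(f"percentages sum to {total_pct}, exceeding 100")
    score = float(sum(g * p for g, p in comps))
    return IHCSample(
        components=tuple(comps), score=score, positive=score >= POSITIVITY_CUTOFF
    )


def group_association(
    status: Sequence[int], category: Sequence[int]
) -> tuple[ContingencyTable2x2, float]:
    """Cross-tabulate a binary marker status against a binary clinical variable
    (rows = category 0/1, columns = status negative/positive) and test with the
    Fisher exact test."""
    s = np.asarray(status, dtype=int)
    c = np.asarray(category, dtype=int)
    if s.shape != c.shape or s.ndim != 1:
        raise ValueError("status and category must be 1-d and the same length")
    if not (np.isin(s, (0, 1)).all() and np.isin(c, (0, 1)).all()):
        raise ValueError("status and category must be binary 0/1")
    table = ContingencyTable2x2(
        a=int(((c == 0) & (s == 0)).sum()),
        b=int(((c == 0) & (s == 1)).sum()),
        c=int(((c == 1) & (s == 0)).sum()),
        d=int(((c == 1) & (s == 1)).sum()),
    )
    return table, fisher_exact_2x2(table)


def positivity_rate(status: Sequence[int]) -> float:
    """Percentage of marker-positive subjects in a binary status vector."""
    s = np.asarray(status, dtype=float)
    if s.size == 0:
        raise ValueError("empty status vector")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("status must be binary 0/1")
    return float(100.0 * s.mean())
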