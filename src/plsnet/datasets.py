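"""Core in-memory containers: expression matrices, interaction networks, gene sets.

Expression data are stored genes x samples (the orientation of microarray
supplementary tables); estimators consume the transposed ``.X`` view
(samples x genes) following scikit-learn convention. Phenotype labels are
coded 1 = case (tumor) and 0 = control (non-tumor) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EFFECT_TOKENS = ("positive", "negative", "unspecified")


@dataclass(frozen=True)
class GeneSet:
    """A named, order-preserving set of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g), None)
        object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)

    def intersection(self, other: Iterable[str]) -> "GeneSet":
        keep = set(other)
        return GeneSet(self.name, tuple(g for g in self.genes if g in keep))

    def difference(self, other: Iterable[str]) -> "GeneSet":
        drop = set(other)
        return GeneSet(self.name, tuple(g for g in self.genes if g not in drop))


class Edge(NamedTuple):
    source: str
    target: str
    effect: str = "unspecified"


@dataclass
class InteractionNetwork:
    """A signed, directed gene-gene interaction network.

    Self-loops are removed and duplicate (source, target) pairs collapsed at
    construction. Effect signs (positive / negative / unspecified) are kept as
    annotation only; degree computations treat the network as undirected.
    """

    edges: list[Edge] = field(default_factory=list)
    nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], Edge] = {}
        n_loops = 0
        for e in self.edges:
            e = Edge(str(e[0]), str(e[1]), e[2] if len(e) > 2 else "unspecified")
            if e.effect not in EFFECT_TOKENS:
                raise ValueError(
                    f"unknown effect {e.effect!r}; allowed: {', '.join(EFFECT_TOKENS)}"
                )
            if e.source == e.target:
                n_loops += 1
                continue
            clean.setdefault((e.source, e.target), e)
        if n_loops:
            logger.info("dropped %d self-loop edge(s)", n_loops)
        self.edges = list(clean.values())
        node_order: dict[str, None] = {str(n): None for n in self.nodes}
        for e in self.edges:
            node_order.setdefault(e.source, None)
            node_order.setdefault(e.target, None)
        self.nodes = tuple(node_order)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        """Undirected simple graph view (antiparallel edges collapse)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, effect=e.effect)
        return g


@dataclass
class ExpressionDataset:
    """Expression matrix (genes x samples) with binary phenotype labels.

    Parameters
    ----------
    values : DataFrame indexed by gene id, columns = sample ids. Missing
        entries (NaN) are allowed at ingest and must be removed by
        :func:`plsnet.io.impute_and_filter` before model fitting.
    labels : one 0/1 label per sample column (1 = case/tumor).
    """

    values: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)[:5]}")
        if self.labels.shape != (self.values.shape[1],):
            raise ValueError(
                f"{self.values.shape[1]} samples but {self.labels.size} labels"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be coded 0 (control) / 1 (case)")

    # -- basic views -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    @property
    def X(self) -> np.ndarray:
        """Samples x genes matrix (scikit-learn orientation)."""
        return self.values.to_numpy().T

    @property
    def y(self) -> np.ndarray:
        return self.labels.copy()

    # -- subsetting --------------------------------------------------------
    def restrict(self, genes: Iterable[str]) -> "ExpressionDataset":
        """Restrict to the given genes, preserving their order."""
        genes = [str(g) for g in genes]
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing[:5]}")
        return ExpressionDataset(self.values.loc[genes], self.labels.copy())

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(self.values.iloc[:, idx], self.labels[idx])

    def rename_genes(self, mapping: Mapping[str, str]) -> "ExpressionDataset":
        return ExpressionDataset(self.values.rename(index=dict(mapping)), self.labels)

    # -- validation --------------------------------------------------------
    def require_complete(self) -> None:
        if self.n_missing:
            raise ValueError(
                f"{self.n_missing} missing value(s) present; impute first"
            )

    def require_two_classes(self) -> None:
        if not (self.labels == 1).any() or not (self.labels == 0).any():
            raise ValueError("both classes must be non-empty")
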