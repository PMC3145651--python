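"""Synthetic scale-free networks and two-class expression data.

The generator emulates the statistical structure the hub-gene classifier
assumes: a scale-free interaction network, differential signal concentrated
on high-degree (hub) genes, co-expression between network neighbours, Gaussian
noise, and (optionally) missing values. Ground truth (which genes are hubs,
which carry signal and in which direction) is returned alongside the data so
that every downstream stage can be tested for parameter recovery.

Generative model
----------------
Per gene *i* a baseline ``mu_i ~ N(0, 1)``. For sample *s* of class
``y_s in {0, 1}``::

    x_is = mu_i + beta_i * y_s + eps_is

with ``beta_i = +-hub_effect`` for hub genes (signs split roughly half
up-/half down-regulated), ``+-nonhub_effect`` for a ``nonhub_de_fraction`` of
non-hub genes, and 0 otherwise. The noise vector per sample is drawn from
``N(0, noise_sd^2 * R)`` where R is a unit-diagonal correlation matrix built
from the degree-normalised adjacency (see :func:`neighbor_correlation_matrix`)
so that network neighbours are co-expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .datasets import Edge, ExpressionDataset, GeneSet, InteractionNetwork

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "generate_hub_network",
    "generate_expression",
    "simulate",
    "make_fixture",
    "paperlike_config",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the kind of two-class liver microarray comparison the
    classifier was designed for: a few hundred genes, 29 case vs 17 control
    samples, seven hub genes of degree >= 31 carrying the signal.
    """

    n_genes: int = 500
    n_case: int = 29
    n_control: int = 17
    n_hubs: int = 7
    hub_min_degree: int = 31
    hub_effect: float = 1.5
    nonhub_de_fraction: float = 0.1
    nonhub_effect: float = 0.4
    neighbor_correlation: float = 0.3
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_hubs < 1 or self.n_hubs >= self.n_genes:
            raise ValueError("need 1 <= n_hubs < n_genes")
        if self.hub_min_degree < 1 or self.hub_min_degree >= self.n_genes:
            raise ValueError("need 1 <= hub_min_degree < n_genes")
        if not 0.0 <= self.nonhub_de_fraction <= 1.0:
            raise ValueError("nonhub_de_fraction must lie in [0, 1]")
        if not 0.0 <= self.neighbor_correlation < 1.0:
            raise ValueError("neighbor_correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SimulatedTruth:
    """Ground truth of a simulation: hub membership and per-gene effects."""

    hub_genes: GeneSet
    de_genes_up: GeneSet
    de_genes_down: GeneSet
    effects: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        hubs = set(self.hub_genes)
        return pd.DataFrame(
            {
                "gene": list(self.effects),
                "is_hub": [g in hubs for g in self.effects],
                "effect": list(self.effects.values()),
            }
        ).set_index("gene")


# Sub-stream indices spawned from the master seed. Network generation and the
# expression stages draw from independent streams so that e.g. changing
# n_case never perturbs the network.
_STREAM_NETWORK, _STREAM_BASELINE, _STREAM_EFFECTS, _STREAM_NOISE, _STREAM_MASK = range(5)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[stream])


def _gene_name(i: int, n_genes: int) -> str:
    width = len(str(n_genes))
    return f"G{i + 1:0{width}d}"


def generate_hub_network(cfg: SimulationConfig) -> InteractionNetwork:
    """Grow a preferential-attachment network whose first ``n_hubs`` nodes are
    topped up to degree >= ``hub_min_degree``.

    The designated hubs are the earliest nodes of the Barabasi-Albert growth
    (which already attract most attachments); where attachment alone falls
    short, extra edges are wired to uniformly chosen non-neighbours. The
    resulting graph is connected and reproducible from ``cfg.seed``.
    """
    rng = _rng(cfg.seed, _STREAM_NETWORK)
    m = min(2, cfg.n_genes - 1)
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(cfg.n_genes, m, seed=ba_seed)
    for hub in range(cfg.n_hubs):
        deficit = cfg.hub_min_degree - g.degree(hub)
        if deficit > 0:
            candidates = np.array(
                sorted(set(g.nodes) - set(g.neighbors(hub)) - {hub})
            )
            extra = rng.choice(candidates, size=deficit, replace=False)
            g.add_edges_from((hub, int(v)) for v in extra)
    mapping = {i: _gene_name(i, cfg.n_genes) for i in g.nodes}
    edges = [Edge(mapping[u], mapping[v], "unspecified") for u, v in g.edges]
    return InteractionNetwork(edges, nodes=tuple(mapping[i] for i in sorted(g.nodes)))


def neighbor_correlation_matrix(
    graph: nx.Graph, nodelist: list[str], target: float
) -> np.ndarray:
    """Unit-diagonal correlation matrix encoding neighbour co-expression.

    With A the symmetric adjacency and D its degree diagonal (floored at 1),
    let ``A_norm = D^{-1/2} A D^{-1/2}`` and ``c = (1 + 1e-6)|lambda_min|`` of
    A_norm. ``R = I + (alpha / c) A_norm`` is positive definite for any
    ``alpha in [0, 1]``; alpha is chosen so the mean correlation over edges
    equals ``target``, capped at the alpha = 1 definiteness limit.
    """
    p = len(nodelist)
    if target == 0.0 or graph.number_of_edges() == 0:
        return np.eye(p)
    a = nx.to_scipy_sparse_array(graph, nodelist=nodelist, dtype=float, format="csr")
    deg = np.maximum(np.asarray(a.sum(axis=1)).ravel(), 1.0)
    dinv = 1.0 / np.sqrt(deg)
    a_norm = scipy.sparse.diags(dinv) @ a @ scipy.sparse.diags(dinv)
    if p <= 1500:
        lam_min = float(
            scipy.linalg.eigvalsh(a_norm.toarray(), subset_by_index=[0, 0])[0]
        )
    else:
        lam_min = float(
            scipy.sparse.linalg.eigsh(a_norm, k=1, which="SA",
                                      return_eigenvectors=False)[0]
        )
    c = (1.0 + 1e-6) * abs(lam_min)
    mean_edge = float(a_norm.sum() / a.sum())  # mean of A_norm over edges
    alpha = min(1.0, target * c / mean_edge) if mean_edge > 0 else 0.0
    return np.eye(p) + (alpha / c) * a_norm.toarray()


def generate_expression(
    net: InteractionNetwork, cfg: SimulationConfig
) -> tuple[ExpressionDataset, SimulatedTruth]:
    """Draw a two-class expression matrix over the network's gene universe."""
    if cfg.n_case < 2 or cfg.n_control < 2:
        raise ValueError("need at least 2 samples per class")
    genes = list(net.nodes)
    p, n = len(genes), cfg.n_case + cfg.n_control
    graph = net.to_graph()
    degrees = dict(graph.degree)
    # hubs = highest-degree nodes (ties broken by identifier)
    hub_genes = sorted(genes, key=lambda g: (-degrees[g], g))[: cfg.n_hubs]

    rng_base = _rng(cfg.seed, _STREAM_BASELINE)
    rng_eff = _rng(cfg.seed, _STREAM_EFFECTS)
    rng_noise = _rng(cfg.seed, _STREAM_NOISE)
    rng_mask = _rng(cfg.seed, _STREAM_MASK)

    mu = rng_base.normal(0.0, 1.0, size=p)

    beta = dict.fromkeys(genes, 0.0)
    perm = list(rng_eff.permutation(hub_genes))
    n_up = math.ceil(len(perm) / 2)
    for g in perm[:n_up]:
        beta[g] = +cfg.hub_effect
    for g in perm[n_up:]:
        beta[g] = -cfg.hub_effect
    nonhubs = [g for g in genes if g not in set(hub_genes)]
    k = round(cfg.nonhub_de_fraction * len(nonhubs))
    if k and cfg.nonhub_effect:
        chosen = list(rng_eff.choice(nonhubs, size=k, replace=False))
        half = math.ceil(k / 2)
        for g in chosen[:half]:
            beta[g] = +cfg.nonhub_effect
        for g in chosen[half:]:
            beta[g] = -cfg.nonhub_effect

    y = np.concatenate([np.ones(cfg.n_case, dtype=int), np.zeros(cfg.n_control, dtype=int)])
    sample_ids = [f"T{i + 1:03d}" for i in range(cfg.n_case)] + [
        f"N{i + 1:03d}" for i in range(cfg.n_control)
    ]

    corr = neighbor_correlation_matrix(graph, genes, cfg.neighbor_correlation)
    if np.allclose(corr, np.eye(p)):
        eps = rng_noise.standard_normal((p, n))
    else:
        chol = np.linalg.cholesky(corr)
        eps = chol @ rng_noise.standard_normal((p, n))
    beta_vec = np.array([beta[g] for g in genes])
    x = mu[:, None] + beta_vec[:, None] * y[None, :] + cfg.noise_sd * eps

    if cfg.missing_rate > 0:
        mask = rng_mask.random((p, n)) < cfg.missing_rate
        x = np.where(mask, np.nan, x)

    values = pd.DataFrame(x, index=genes, columns=sample_ids)
    ds = ExpressionDataset(values, y)
    truth = SimulatedTruth(
        hub_genes=GeneSet("hubs", tuple(hub_genes)),
        de_genes_up=GeneSet("up", tuple(g for g in genes if beta[g] > 0)),
        de_genes_down=GeneSet("down", tuple(g for g in genes if beta[g] < 0)),
        effects={g: float(beta[g]) for g in genes},
    )
    return ds, truth


def simulate(
    cfg: SimulationConfig,
) -> tuple[ExpressionDataset, InteractionNetwork, SimulatedTruth]:
    """Network + expression in one call, fully determined by ``cfg.seed``."""
    net = generate_hub_network(cfg)
    ds, truth = generate_expression(net, cfg)
    return ds, net, truth


def paperlike_config(seed: int = 7) -> SimulationConfig:
    """Study-sized conditions: 29 case / 17 control samples, 7 hub-signal
    genes of degree >= 31 in a 300-gene scale-free network, standardized hub
    effect 2, no non-hub signal."""
    return SimulationConfig(
        n_genes=300,
        n_case=29,
        n_control=17,
        n_hubs=7,
        hub_min_degree=31,
        hub_effect=2.0,
        nonhub_de_fraction=0.0,
        nonhub_effect=0.0,
        neighbor_correlation=0.3,
        seed=seed,
    )


FixtureKind = Literal["separable7", "null", "paperlike"]

_FIXTURE_KINDS = ("separable7", "null", "paperlike")


def make_fixture(
    kind: FixtureKind,
) -> tuple[ExpressionDataset, InteractionNetwork, SimulatedTruth]:
    """Deterministic test fixtures.

    separable7
        7 informative genes (classes separated by 4 noise SDs each) + 93 pure
        noise genes, 20 vs 20 samples; perfectly separable by construction.
    null
        2000 genes, 20 vs 20 samples, no signal, independent noise.
    paperlike
        :func:`paperlike_config` at its fixed internal seed.
    """
    if kind == "separable7":
        return _separable7()
    if kind == "null":
        cfg = SimulationConfig(
            n_genes=2000,
            n_case=20,
            n_control=20,
            n_hubs=5,
            hub_min_degree=31,
            hub_effect=0.0,
            nonhub_de_fraction=0.0,
            nonhub_effect=0.0,
            neighbor_correlation=0.0,
            seed=101,
        )
        return simulate(cfg)
    if kind == "paperlike":
        return simulate(paperlike_config())
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {_FIXTURE_KINDS}")


def _separable7() -> tuple[ExpressionDataset, InteractionNetwork, SimulatedTruth]:
    rng = np.random.default_rng(20_240_501)
    n_case = n_control = 20
    informative = [f"I{k}" for k in range(1, 8)]
    noise_genes = [f"N{k:03d}" for k in range(1, 94)]
    genes = informative + noise_genes
    y = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    x = rng.normal(0.0, 1.0, size=(len(genes), n_case + n_control))
    signs = [+1, +1, +1, +1, -1, -1, -1]  # 4 up-, 3 down-regulated
    effects = dict.fromkeys(genes, 0.0)
    for row, (g, s) in enumerate(zip(informative, signs)):
        # tight noise + wide class gap => guaranteed separation
        x[row] = rng.normal(0.0, 0.25, size=x.shape[1]) + 2.0 * s * (2 * y - 1)
        effects[g] = 4.0 * s
    sample_ids = [f"T{i + 1:03d}" for i in range(n_case)] + [
        f"N{i + 1:03d}" for i in range(n_control)
    ]
    ds = ExpressionDataset(pd.DataFrame(x, index=genes, columns=sample_ids), y)
    # star-like network: each informative gene linked to 31 noise genes
    edges = []
    for k, g in enumerate(informative):
        for j in range(31):
            edges.append(Edge(g, noise_genes[(13 * k + j) % len(noise_genes)]))
    net = InteractionNetwork(edges, nodes=tuple(genes))
    truth = SimulatedTruth(
        hub_genes=GeneSet("hubs", tuple(informative)),
        de_genes_up=GeneSet("up", tuple(informative[:4])),
        de_genes_down=GeneSet("down", tuple(informative[4:])),
        effects=effects,
    )
    return ds, net, truth


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from e.g. a YAML mapping, rejecting unknown keys."""
    valid = set(asdict(SimulationConfig()).keys())
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
    return SimulationConfig(**d)
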