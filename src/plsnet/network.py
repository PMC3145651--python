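"""Node connectivity, hidden-edge fractions and hub-gene selection.

A hub is a node with at least ``min_connections`` distinct neighbours
(direction ignored, self-loops excluded) and, when a reference network is
available, with fewer than ``max_hidden_fraction`` of its reference
interactions missing from the candidate subnetwork. The hidden fraction of a
node is ``1 - degree_sub / degree_ref`` (0 for isolated reference nodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .datasets import GeneSet, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["HubCriteria", "node_degrees", "hidden_fractions", "select_hubs"]


@dataclass(frozen=True)
class HubCriteria:
    """Default rule: more than thirty connections (degree >= 31) and a hidden
    fraction strictly below one half."""

    min_connections: int = 31
    max_hidden_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_connections < 1:
            raise ValueError("min_connections must be positive")
        if not 0.0 <= self.max_hidden_fraction <= 1.0:
            raise ValueError("max_hidden_fraction must lie in [0, 1]")


def node_degrees(net: InteractionNetwork) -> pd.DataFrame:
    """Per-node count of distinct neighbours (undirected, simple)."""
    g = net.to_graph()
    return pd.DataFrame(
        {"degree_sub": [g.degree(n) for n in net.nodes]},
        index=pd.Index(net.nodes, name="node"),
    )


def hidden_fractions(
    sub: InteractionNetwork, ref: InteractionNetwork
) -> pd.DataFrame:
    """Per-node degree in the candidate subnetwork and in the reference
    network, with the hidden fraction 1 - degree_sub/degree_ref."""
    ref_nodes = set(ref.nodes)
    missing = [n for n in sub.nodes if n not in ref_nodes]
    if missing:
        raise ValueError(f"node(s) absent from reference network: {missing[:5]}")
    g_sub, g_ref = sub.to_graph(), ref.to_graph()
    extra = [e for e in g_sub.edges if not g_ref.has_edge(*e)]
    if extra:
        logger.warning(
            "%d subnetwork edge(s) not present in the reference network "
            "(kept; degree_sub may exceed degree_ref): e.g. %s",
            len(extra), extra[:3],
        )
    rows = []
    for n in sub.nodes:
        d_sub, d_ref = g_sub.degree(n), g_ref.degree(n)
        hidden = 0.0 if d_ref == 0 else max(0.0, 1.0 - d_sub / d_ref)
        rows.append((d_sub, d_ref, hidden))
    return pd.DataFrame(
        rows,
        columns=["degree_sub", "degree_ref", "hidden_fraction"],
        index=pd.Index(sub.nodes, name="node"),
    )


def select_hubs(
    sub: InteractionNetwork,
    ref: InteractionNetwork | None = None,
    criteria: HubCriteria = HubCriteria(),
) -> GeneSet:
    """Hub genes of the candidate network, sorted for determinism.

    Without a reference network only the connectivity criterion applies.
    """
    degrees = node_degrees(sub)["degree_sub"]
    keep = degrees >= criteria.min_connections
    if ref is not None:
        hidden = hidden_fractions(sub, ref)["hidden_fraction"]
        keep &= hidden < criteria.max_hidden_fraction
    return GeneSet("hubs", tuple(sorted(degrees.index[keep])))
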