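"""Bundled hub-gene signature lists.

These are the published liver-cancer hub signatures (10 up-regulated, 7
down-regulated, 27 combined) and the 4-gene prostate signature, shipped as
plain gene lists so the classifier can be trained on any expression matrix
containing them. They are fixtures, not outputs of this package: the
literature-curated interaction network they were derived from is proprietary
and cannot be redistributed.
"""

from __future__ import annotations

from importlib import resources

from .datasets import GeneSet

__all__ = ["load_hub_genes", "HUB_SET_NAMES"]

HUB_SET_NAMES = ("up", "down", "combined", "prostate")

_FILES = {
    "up": "hub_genes_up.txt",
    "down": "hub_genes_down.txt",
    "combined": "hub_genes_combined.txt",
    "prostate": "hub_genes_prostate.txt",
}


def load_hub_genes(which: str = "down") -> GeneSet:
    """Load one of the bundled hub signatures ('up', 'down', 'combined',
    'prostate'). The 7-gene 'down' signature is the default classifier."""
    if which not in _FILES:
        raise ValueError(f"unknown hub set {which!r}; choose from {HUB_SET_NAMES}")
    text = resources.files("plsnet.data").joinpath(_FILES[which]).read_text()
    genes = [ln.split("#", 1)[0].strip() for ln in text.splitlines()]
    return GeneSet(f"hubs_{which}", tuple(g for g in genes if g))
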