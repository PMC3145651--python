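"""Readers/writers for expression tables, edge lists and gene lists, plus
probe-level preprocessing (missing-value filtering/imputation, probe collapse).

File conventions
----------------
Expression matrix
    Tab-delimited; first column gene/probe id, header row = sample ids. An
    optional row named ``CLASS`` carries 0/1 phenotype labels; alternatively a
    sidecar two-column file (sample id TAB label) can be given. Empty cells and
    ``NA`` are read as missing.
Edge list
    ``source TAB target TAB effect`` with effect in {positive, negative,
    unspecified}; the effect column may be omitted.
Gene list
    One identifier per line; ``#`` starts a comment.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import Edge, EFFECT_TOKENS, ExpressionDataset, GeneSet, InteractionNetwork

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA", "na", "NaN", "nan")

DEFAULT_LABEL_ROW = "CLASS"

#: accepted spellings of phenotype labels (case-insensitive)
LABEL_ALIASES = {
    "1": 1, "0": 0,
    "case": 1, "control": 0,
    "tumor": 1, "tumour": 1, "non-tumor": 0, "nontumor": 0, "normal": 0,
    "hcc": 1, "pclt": 0,
}


def _parse_label(token: str) -> int:
    key = token.strip().lower()
    if key in LABEL_ALIASES:
        return LABEL_ALIASES[key]
    raise ValueError(
        f"unrecognized class label {token!r}; use 0/1 or one of "
        f"{sorted(set(LABEL_ALIASES) - {'0', '1'})}"
    )


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample id TAB label) file into a Series of 0/1."""
    rows = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 tab-separated fields")
            sample, token = parts
            if sample in rows:
                raise ValueError(f"{path}: line {ln}: duplicate sample id {sample!r}")
            rows[sample] = _parse_label(token)
    return pd.Series(rows, dtype=int)


def read_expression_table(
    path: str | Path,
    label_row: str | None = DEFAULT_LABEL_ROW,
    labels_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a genes x samples TSV into an :class:`ExpressionDataset`.

    Labels come either from the in-file row named ``label_row`` or from the
    sidecar ``labels_path``; exactly one source must provide them.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = [s.strip() for s in header[1:]]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"{path}: duplicate sample ids: {dupes}")
        n_fields = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        labels_from_row: np.ndarray | None = None
        for ln, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != n_fields:
                raise ValueError(
                    f"{path}: line {ln}: {len(rec)} fields, expected {n_fields}"
                )
            rid, cells = rec[0].strip(), rec[1:]
            if label_row is not None and rid == label_row:
                labels_from_row = np.array([_parse_label(c) for c in cells])
                continue
            parsed = []
            for j, cell in enumerate(cells):
                cell = cell.strip()
                if cell in MISSING_TOKENS:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at gene "
                        f"{rid!r}, sample {sample_ids[j]!r} (line {ln})"
                    ) from None
            gene_ids.append(rid)
            rows.append(parsed)

    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    if labels_path is not None:
        side = read_labels(labels_path)
        missing = [s for s in sample_ids if s not in side.index]
        if missing:
            raise ValueError(f"labels file lacks sample(s): {missing[:5]}")
        labels = side.reindex(sample_ids).to_numpy()
    elif labels_from_row is not None:
        labels = labels_from_row
    else:
        raise ValueError(
            f"{path}: no label row {label_row!r} found and no labels file given"
        )
    return ExpressionDataset(values, labels)


def write_expression_table(
    ds: ExpressionDataset, path: str | Path, label_row: str | None = DEFAULT_LABEL_ROW
) -> None:
    """Write a dataset back to TSV (missing values as ``NA``)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ID"] + ds.sample_ids)
        if label_row is not None:
            w.writerow([label_row] + [str(int(v)) for v in ds.labels])
        for gene, row in ds.values.iterrows():
            w.writerow(
                [gene]
                + [("NA" if not np.isfinite(v) else repr(float(v))) for v in row]
            )


def write_labels(ds: ExpressionDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, lab in zip(ds.sample_ids, ds.labels):
            fh.write(f"{s}\t{int(lab)}\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_and_filter(
    ds: ExpressionDataset, max_missing_fraction: float = 0.3
) -> ExpressionDataset:
    """Drop genes missing in more than ``max_missing_fraction`` of samples,
    then impute remaining gaps with the gene's median over observed samples.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = ds.values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    if (frac >= 1.0).any() and max_missing_fraction >= 1.0:
        bad = list(ds.values.index[frac >= 1.0])
        raise ValueError(f"gene(s) with all values missing: {bad[:5]}")
    values = ds.values.loc[keep].copy()
    medians = values.median(axis=1, skipna=True)
    values = values.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d gene(s) exceeding missing fraction %.2f",
                    dropped, max_missing_fraction)
    return ExpressionDataset(values, ds.labels.copy())


def collapse_probes(
    ds: ExpressionDataset, probe_to_gene: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse probes to gene symbols, keeping per symbol the probe with the
    highest mean expression across all samples (ties: first in input order).
    Unmapped probes are dropped.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    means = ds.values.mean(axis=1, skipna=True)
    best: dict[str, tuple[float, str]] = {}
    for probe in ds.gene_ids:
        symbol = probe_to_gene.get(probe)
        if symbol is None:
            continue
        m = float(means[probe])
        if symbol not in best or m > best[symbol][0]:
            best[symbol] = (m, probe)
    if not best:
        raise ValueError("no probe in the dataset is covered by the mapping")
    symbols = list(best)
    probes = [best[s][1] for s in symbols]
    values = ds.values.loc[probes]
    values.index = symbols
    return ExpressionDataset(values, ds.labels.copy())


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: probe id TAB gene symbol."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 fields")
            mapping[parts[0].strip()] = parts[1].strip()
    if not mapping:
        raise ValueError(f"{path}: empty probe map")
    return mapping


# ---------------------------------------------------------------------------
# networks and gene lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a TSV edge list (source, target[, effect]) into a network."""
    edges: list[Edge] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) == 2:
                src, tgt, eff = parts[0], parts[1], "unspecified"
            elif len(parts) == 3:
                src, tgt, eff = parts
            else:
                raise ValueError(f"{path}: line {ln}: expected 2 or 3 fields")
            if eff not in EFFECT_TOKENS:
                raise ValueError(
                    f"{path}: line {ln}: unknown effect {eff!r}; "
                    f"allowed: {', '.join(EFFECT_TOKENS)}"
                )
            edges.append(Edge(src, tgt, eff))
    return InteractionNetwork(edges)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.effect}\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list (``#`` comments ignored)."""
    path = Path(path)
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    if not genes:
        raise ValueError(f"{path}: no gene identifiers found")
    return GeneSet(name or path.stem, tuple(genes))


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
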