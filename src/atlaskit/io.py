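"""Plain-text file I/O: MatrixMarket counts, TSV metadata, GMT gene sets.

Conventions: delimited tables are tab-separated with a header row; the
count matrix is MatrixMarket coordinate format with rows = cells and
columns = genes; gene sets are GMT (name, description, then one gene per
tab-separated field).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import BulkMatrix, CellDataset, InteractionTable
from .errors import StructuralError, ValidationError
from .signatures import SignatureSet


def _read_lines(path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def _write_lines(path, lines: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(f"{line}\n")


# ---------------------------------------------------------------------------
# CellDataset
# ---------------------------------------------------------------------------

def load_cell_dataset(counts_path, genes_path, cells_path, meta_path) -> CellDataset:
    """Load a :class:`CellDataset` from MTX counts + gene/cell lists + TSV metadata.

    Raises
    ------
    StructuralError
        if the matrix dimensions do not match the gene/cell list lengths.
    ValidationError
        if identifiers are duplicated, counts are negative or non-integer,
        or the metadata table does not have one row per cell.
    """
    counts = scipy.io.mmread(os.fspath(counts_path))
    genes = _read_lines(genes_path)
    cells = _read_lines(cells_path)
    if counts.shape != (len(cells), len(genes)):
        raise StructuralError(
            f"matrix shape {counts.shape} does not match "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell": str})
    if "cell" not in meta.columns:
        raise StructuralError("metadata table must have a 'cell' column")
    meta = meta.set_index("cell")
    return CellDataset(
        counts=sp.csr_matrix(counts),
        genes=pd.Index(genes),
        cells=pd.Index(cells),
        cell_meta=meta,
    )


def write_cell_dataset(dataset: CellDataset, out_dir) -> dict[str, Path]:
    """Write counts.mtx, genes.txt, cells.txt and meta.tsv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.mtx",
        "genes": out / "genes.txt",
        "cells": out / "cells.txt",
        "meta": out / "meta.tsv",
    }
    counts = dataset.counts
    if not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
    scipy.io.mmwrite(os.fspath(paths["counts"]), counts.tocoo())
    _write_lines(paths["genes"], dataset.genes)
    _write_lines(paths["cells"], dataset.cells)
    dataset.cell_meta.to_csv(paths["meta"], sep="\t", index_label="cell")
    return paths


# ---------------------------------------------------------------------------
# BulkMatrix
# ---------------------------------------------------------------------------

def load_bulk_matrix(values_path, meta_path=None) -> BulkMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.DataFrame()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return BulkMatrix(values=values, sample_meta=meta)


def write_bulk_matrix(bulk: BulkMatrix, values_path, meta_path=None) -> None:
    bulk.values.to_csv(values_path, sep="\t", index_label="sample")
    if meta_path is not None:
        bulk.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Signatures (GMT + thresholds TSV)
# ---------------------------------------------------------------------------

def write_signatures(signatures: Sequence[SignatureSet], gmt_path,
                     thresholds_path=None) -> None:
    """Write signatures as GMT; optionally a TSV of the thresholds used.

    GMT: one line per signature — name, description (the target cell type),
    then the genes, all tab-separated.  An empty signature writes name and
    description only.
    """
    lines = []
    for sig in signatures:
        fields = [sig.name, sig.target_cell_type or ""] + list(sig.genes)
        lines.append("\t".join(fields))
    _write_lines(gmt_path, lines)
    if thresholds_path is not None:
        rows = []
        for sig in signatures:
            thr = sig.thresholds
            if isinstance(thr, tuple):
                sfc_min, fc_min, auroc_min = thr
            else:
                sfc_min = fc_min = auroc_min = thr  # e.g. "composite"
            rows.append({"name": sig.name, "target": sig.target_cell_type,
                         "sfc_min": sfc_min, "fc_min": fc_min,
                         "auroc_min": auroc_min})
        pd.DataFrame(rows).to_csv(thresholds_path, sep="\t", index=False)


def read_signatures(gmt_path, thresholds_path=None) -> list[SignatureSet]:
    thr_by_name: dict[str, object] = {}
    if thresholds_path is not None:
        thr = pd.read_csv(thresholds_path, sep="\t")
        for _, row in thr.iterrows():
            vals = (row["sfc_min"], row["fc_min"], row["auroc_min"])
            if len(set(map(str, vals))) == 1 and not _is_number(vals[0]):
                thr_by_name[row["name"]] = str(vals[0])
            else:
                thr_by_name[row["name"]] = tuple(float(v) for v in vals)
    sigs = []
    with open(gmt_path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise StructuralError(f"malformed GMT line: {line!r}")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            sigs.append(SignatureSet(
                name=name, target_cell_type=desc, genes=genes,
                thresholds=thr_by_name.get(name),
            ))
    return sigs


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# Interaction pairs, run manifests
# ---------------------------------------------------------------------------

def load_interaction_table(path) -> InteractionTable:
    return InteractionTable(pd.read_csv(path, sep="\t", dtype=str))


def write_interaction_table(table: InteractionTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def write_run_manifest(path, operation: str, params: dict, seed=None) -> None:
    """Record the parameters and seed of an analysis step as JSON."""
    payload = {"operation": operation, "seed": seed, "params": params}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
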