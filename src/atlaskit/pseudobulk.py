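"""Pseudobulk aggregation and CPM/log2 normalization.

Single cells are summed into per-(patient, cell type) or per-patient
("mixed") pseudobulk samples; groups with fewer cells than the minimum
(default 10) are discarded.  Aggregates are normalized to counts per
million and log2(x+1)-transformed before any signature work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CellDataset
from .errors import EmptyResultError, ValidationError

MIXED = "mixed"

RAW_COUNTS = "raw_counts"
CPM = "cpm"
LOG2_CPM = "log2_cpm"


@dataclass
class PseudobulkMatrix:
    """Group × gene aggregate.

    ``values`` is a dense DataFrame (groups are few); ``groups`` carries one
    row per retained group with ``patient``, ``cell_type`` (the sentinel
    ``"mixed"`` when all types are pooled), ``dataset`` and ``n_cells``;
    ``scale`` is one of ``raw_counts``, ``cpm``, ``log2_cpm``.
    """

    values: pd.DataFrame
    groups: pd.DataFrame
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValidationError("values and groups must share the same index")
        if (self.groups["n_cells"] < 1).any():
            raise ValidationError("every retained group must have n_cells >= 1")
        if self.scale == RAW_COUNTS:
            arr = self.values.to_numpy()
            if arr.size and (arr.min() < 0 or not np.all(np.mod(arr, 1) == 0)):
                raise ValidationError("raw_counts pseudobulk must be nonnegative integers")
        elif self.scale == CPM:
            sums = self.values.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValidationError("cpm rows must sum to 1e6")

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def __len__(self) -> int:
        return len(self.values)


def aggregate(dataset: CellDataset, group_by: str = "patient_cell_type",
              min_cells: int = 10) -> PseudobulkMatrix:
    """Sum transcript counts per group; drop groups below ``min_cells``.

    ``group_by`` is ``"patient_cell_type"`` (requires every cell labeled) or
    ``"patient_mixed"`` (all cell types pooled per patient).

    Raises
    ------
    ValidationError
        for unlabeled cells under ``patient_cell_type``.
    EmptyResultError
        if no group survives the filter.
    """
    meta = dataset.cell_meta
    if group_by == "patient_cell_type":
        if "cell_type" not in meta.columns or meta["cell_type"].isna().any():
            n_bad = int(meta["cell_type"].isna().sum()) if "cell_type" in meta.columns \
                else dataset.n_cells
            raise ValidationError(
                f"{n_bad} cells lack a cell_type label; label or subset them first"
            )
        keys = list(zip(meta["patient"], meta["cell_type"]))
    elif group_by == "patient_mixed":
        keys = [(p, MIXED) for p in meta["patient"]]
    else:
        raise ValidationError(f"unknown group_by: {group_by!r}")

    key_index = pd.MultiIndex.from_tuples(keys, names=["patient", "cell_type"])
    codes, uniques = pd.factorize(key_index, sort=True)
    n_groups = len(uniques)
    indicator = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_groups, dataset.n_cells),
    )
    sums = np.asarray((indicator @ dataset.counts).todense())
    n_cells = np.bincount(codes, minlength=n_groups)

    keep = n_cells >= min_cells
    if not keep.any():
        raise EmptyResultError(
            f"no pseudobulk group reached min_cells={min_cells} "
            f"(largest group had {int(n_cells.max()) if n_groups else 0} cells)"
        )

    patient_dataset = meta.drop_duplicates("patient").set_index("patient")["dataset"]
    kept = [uniques[i] for i in np.flatnonzero(keep)]
    index = pd.Index([f"{p}|{t}" for p, t in kept], name="group")
    groups = pd.DataFrame(
        {
            "patient": [p for p, _ in kept],
            "cell_type": [t for _, t in kept],
            "dataset": [patient_dataset[p] for p, _ in kept],
            "n_cells": n_cells[keep].astype(int),
        },
        index=index,
    )
    values = pd.DataFrame(sums[keep].astype(np.int64), index=index,
                          columns=dataset.genes)
    return PseudobulkMatrix(values=values, groups=groups, scale=RAW_COUNTS)


def normalize_cpm_log2(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """Scale each row to counts per million, then apply log2(x + 1).

    Requires raw counts; a zero-total row is an error naming the group.
    """
    if pb.scale != RAW_COUNTS:
        raise ValidationError(f"expected raw_counts input, got scale={pb.scale!r}")
    arr = pb.values.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"zero-total pseudobulk rows: {list(pb.values.index[zero[:5]])}"
        )
    cpm = arr / totals[:, None] * 1e6
    values = pd.DataFrame(np.log2(cpm + 1.0), index=pb.values.index,
                          columns=pb.values.columns)
    return replace(pb, values=values, scale=LOG2_CPM)
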