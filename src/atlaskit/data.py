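"""Core in-memory containers: single-cell counts, bulk expression, interaction pairs.

``CellDataset`` is the atlas stand-in: a sparse cell × gene integer count
matrix plus per-cell metadata (patient, sample, dataset, cell type, tissue,
condition, stage).  ``BulkMatrix`` holds linear-scale bulk expression with
per-sample phenotype metadata.  ``InteractionTable`` holds ligand–receptor
pairs; multi-subunit complexes are written as member symbols joined by "_".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

TISSUES = frozenset({"tumor_primary", "normal_adjacent", "normal"})
CONDITIONS = frozenset({"LUAD", "LUSC", "other"})
TUMOR_STAGES = frozenset({"early", "advanced"})

META_REQUIRED = ("patient", "sample", "dataset")
META_OPTIONAL = ("cell_type", "tissue", "condition", "tumor_stage")

COMPLEX_SEP = "_"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


def _check_counts_integer_nonneg(counts: sp.spmatrix) -> None:
    data = counts.data if sp.issparse(counts) else np.asarray(counts).ravel()
    if data.size and data.min() < 0:
        raise ValidationError("counts contain negative entries")
    if not np.issubdtype(data.dtype, np.integer):
        if data.size and not np.all(np.mod(data, 1) == 0):
            raise ValidationError("counts contain non-integer entries")


@dataclass
class CellDataset:
    """Sparse UMI counts with per-cell metadata.

    Parameters
    ----------
    counts
        cell × gene matrix of nonnegative integers (stored CSR).
    genes, cells
        Ordered unique gene symbols / cell identifiers.
    cell_meta
        One row per cell (indexed by cell id) with at least the columns
        ``patient``, ``sample``, ``dataset``; optionally ``cell_type``
        (may be missing for query cells awaiting label transfer),
        ``tissue``, ``condition``, ``tumor_stage``.
    """

    counts: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.genes) or n_cells != len(self.cells):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        _check_unique(self.genes, "gene symbols")
        _check_unique(self.cells, "cell identifiers")
        _check_counts_integer_nonneg(self.counts)

        meta = self.cell_meta
        if len(meta) != n_cells:
            raise ValidationError(
                f"cell_meta has {len(meta)} rows for {n_cells} cells"
            )
        if not meta.index.equals(self.cells):
            if set(meta.index) != set(self.cells):
                raise ValidationError("cell_meta index does not match cell identifiers")
            self.cell_meta = meta = meta.reindex(self.cells)
        meta.index.name = "cell"
        missing = [c for c in META_REQUIRED if c not in meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing required columns: {missing}")
        for col in META_REQUIRED:
            if meta[col].isna().any():
                raise ValidationError(f"cell_meta column {col!r} has missing values")
        # each sample belongs to exactly one patient and one dataset
        per_sample = meta.groupby("sample", sort=False)[["patient", "dataset"]].nunique()
        bad = per_sample[(per_sample > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValidationError(f"samples mapped to multiple patients/datasets: {bad[:5]}")
        for col, allowed in (("tissue", TISSUES), ("condition", CONDITIONS),
                             ("tumor_stage", TUMOR_STAGES)):
            if col in meta.columns:
                values = set(meta[col].dropna().unique())
                if not values <= allowed:
                    raise ValidationError(
                        f"invalid {col} values: {sorted(values - allowed)}"
                    )

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> list:
        if "cell_type" not in self.cell_meta.columns:
            return []
        return sorted(self.cell_meta["cell_type"].dropna().unique())

    def subset_cells(self, mask) -> "CellDataset":
        """Restrict to cells selected by a boolean mask or cell-id sequence."""
        if isinstance(mask, (pd.Series,)):
            mask = mask.reindex(self.cells).to_numpy()
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = self.cells.isin(mask)
        return CellDataset(
            counts=self.counts[mask],
            genes=self.genes,
            cells=self.cells[mask],
            cell_meta=self.cell_meta.loc[mask],
        )

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.genes),
        )


@dataclass
class BulkMatrix:
    """Bulk expression, linear scale, samples × genes, with optional phenotype metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.values.index, "sample identifiers")
        _check_unique(self.values.columns, "gene symbols")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("bulk values contain non-finite entries")
        if arr.size and arr.min() < 0:
            raise ValidationError("bulk values contain negative entries")
        if len(self.sample_meta):
            if not set(self.values.index) <= set(self.sample_meta.index):
                raise ValidationError("sample_meta does not cover all samples")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


def complex_members(symbol: str) -> list[str]:
    """Split a (possibly multi-subunit) interaction member into gene symbols."""
    return [s for s in str(symbol).split(COMPLEX_SEP) if s]


@dataclass
class InteractionTable:
    """Ligand–receptor pair table with columns ``ligand``, ``receptor``, ``pair_id``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in ("ligand", "receptor", "pair_id"):
            if col not in self.table.columns:
                raise ValidationError(f"interaction table missing column {col!r}")
        ids = pd.Index(self.table["pair_id"])
        _check_unique(ids, "pair_id values")
        for col in ("ligand", "receptor"):
            for entry in self.table[col]:
                members = complex_members(entry)
                if not members:
                    raise ValidationError(f"empty {col} symbol in pair table: {entry!r}")

    def __len__(self) -> int:
        return len(self.table)
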