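"""Condition-differential ligand–receptor crosstalk.

For each differentially expressed ligand of a source cell type (DE results
are an input, e.g. from a pseudobulk DESeq2 run), every interaction pair
containing it is reported for each receiver cell type whose receptor is
expressed in at least ``min_frac`` (default 10%, inclusive) of that type's
cells.  Expression fractions are the unweighted mean of per-patient
fractions, so patients contributing many cells do not dominate; "expressed"
means raw count > 0.  Multi-subunit complexes pass only if every member
passes, and report the minimum member fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CellDataset, InteractionTable, complex_members
from .errors import EmptyResultError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Differential-expression rows: cell_type, gene, log2fc, adjusted_p."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_type", "gene", "log2fc", "adjusted_p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"DE table missing columns: {sorted(missing)}")
        p = self.table["adjusted_p"].to_numpy(dtype=float)
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValidationError("adjusted_p must lie in [0, 1]")


@dataclass
class CrosstalkResult:
    """Filtered interactions: source ligand change x receiver receptor expression."""

    table: pd.DataFrame
    n_unmatched_de_genes: int = 0

    def __len__(self) -> int:
        return len(self.table)


def expression_fractions(dataset: CellDataset, genes, cell_type: str) -> pd.Series:
    """Fraction of ``cell_type`` cells expressing each gene, patient-balanced.

    For every patient with at least one cell of the type, the fraction of
    those cells with count > 0 is computed; the result is the unweighted
    mean over patients (missing genes yield NaN).
    """
    meta = dataset.cell_meta
    if "cell_type" not in meta.columns:
        raise ValidationError("dataset has no cell_type labels")
    mask = (meta["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        raise EmptyResultError(f"no patient has cells of type {cell_type!r}")
    genes = list(genes)
    present = [g for g in genes if g in dataset.genes]
    cols = dataset.genes.get_indexer(present)
    sub = dataset.counts[mask][:, cols]
    expressed = pd.DataFrame((sub > 0).toarray(), columns=present,
                             index=meta.index[mask])
    expressed["patient"] = meta.loc[mask, "patient"].to_numpy()
    per_patient = expressed.groupby("patient").mean()
    fractions = per_patient.mean(axis=0)
    return fractions.reindex(genes)


def expression_fraction(dataset: CellDataset, gene: str, cell_type: str) -> float:
    """Scalar convenience wrapper around :func:`expression_fractions`."""
    value = expression_fractions(dataset, [gene], cell_type).iloc[0]
    if np.isnan(value):
        raise ValidationError(f"gene {gene!r} not present in dataset")
    return float(value)


def _complex_fraction(fractions: pd.Series, symbol: str, min_frac: float):
    """(passes, reported fraction) for a possibly multi-subunit symbol."""
    members = complex_members(symbol)
    vals = fractions.reindex(members)
    if vals.isna().any():
        return False, float("nan")
    passes = bool((vals >= min_frac).all())
    return passes, float(vals.min())


def differential_crosstalk(de: DEResult, pairs: InteractionTable,
                           dataset: CellDataset, receiver_types,
                           min_frac: float = 0.10, de_fdr: float = 0.1,
                           lfc_min: float = 0.0) -> CrosstalkResult:
    """Differential ligands x receptors expressed in >= min_frac of receivers.

    A DE gene passes at ``adjusted_p < de_fdr`` and ``|log2fc| > lfc_min``;
    each interaction pair whose ligand contains it is emitted once per
    receiver type whose receptor (all complex members) reaches ``min_frac``
    (inclusive).  Direction is the sign of the ligand's log2fc.  DE genes
    absent from the pair table yield no rows; their count is logged and
    reported on the result.
    """
    det = de.table
    passing = det[(det["adjusted_p"] < de_fdr)
                  & (det["log2fc"].abs() > lfc_min)]

    # receiver fractions are computed lazily, once per (receiver, gene set)
    needed_genes = sorted({m for lig, rec in zip(pairs.table["ligand"],
                                                 pairs.table["receptor"])
                           for m in complex_members(rec)})
    receiver_fracs = {
        rt: expression_fractions(dataset, needed_genes, rt)
        for rt in receiver_types
    }

    rows = []
    unmatched = 0
    for _, de_row in passing.iterrows():
        gene = de_row["gene"]
        hits = pairs.table[[gene in complex_members(l)
                            for l in pairs.table["ligand"]]]
        if not len(hits):
            unmatched += 1
            continue
        direction = "up" if de_row["log2fc"] > 0 else "down"
        for _, pair in hits.iterrows():
            for rt in receiver_types:
                ok, frac = _complex_fraction(receiver_fracs[rt],
                                             pair["receptor"], min_frac)
                if ok:
                    rows.append({
                        "source_cell_type": de_row["cell_type"],
                        "ligand": pair["ligand"],
                        "receiver_cell_type": rt,
                        "receptor": pair["receptor"],
                        "direction": direction,
                        "receiver_expr_fraction": frac,
                        "pair_id": pair["pair_id"],
                    })
    if unmatched:
        logger.info("%d differential genes had no entry in the pair table", unmatched)
    columns = ["source_cell_type", "ligand", "receiver_cell_type", "receptor",
               "direction", "receiver_expr_fraction", "pair_id"]
    table = pd.DataFrame(rows, columns=columns)
    return CrosstalkResult(table=table, n_unmatched_de_genes=unmatched)
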