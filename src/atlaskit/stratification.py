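"""Patient stratification into tumor immune phenotypes.

Per-patient cell-type fractions (primary tumor cells, configurable type
exclusions such as neutrophils, renormalized to sum 1) have dataset batch
effects removed by a linear model on dataset indicators (equivalently,
within-dataset centering), and patients are clustered with graph-based
Leiden on a correlation-distance neighbor graph.  Clusters are named after
their predominant cell type; a cluster dominated by cancer cells with no
immune lineage above a floor is "immune-deserted".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellDataset
from .errors import ValidationError

IMMUNE_DESERTED = "immune-deserted"


@dataclass
class PatientFractionMatrix:
    """Patient x cell-type fractions (rows sum to 1 over included types)."""

    values: pd.DataFrame
    dataset: pd.Series
    included_types: list[str]

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
            raise ValidationError("fractions must lie in [0, 1]")
        if arr.size and not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("fractions must sum to 1 per patient")
        self.dataset = self.dataset.reindex(self.values.index)
        if self.dataset.isna().any():
            raise ValidationError("every patient needs a dataset assignment")


@dataclass
class StratificationResult:
    clusters: pd.Series  # patient -> cluster label (string)
    resolution: float
    seed: int
    cluster_names: dict = field(default_factory=dict)
    ties: dict = field(default_factory=dict)


def compute_fractions(dataset: CellDataset, exclude_types=(),
                      tissue_filter: str | None = "tumor_primary"
                      ) -> PatientFractionMatrix:
    """Per-patient fractions of each included cell type, renormalized to 1.

    Cells are filtered to ``tissue_filter`` (None disables), unlabeled cells
    are ignored, and ``exclude_types`` are dropped before renormalizing.
    Patients left without cells are dropped with a warning.
    """
    meta = dataset.cell_meta
    if "cell_type" not in meta.columns:
        raise ValidationError("dataset has no cell_type labels")
    mask = meta["cell_type"].notna()
    if tissue_filter is not None and "tissue" in meta.columns:
        mask &= meta["tissue"] == tissue_filter
    mask &= ~meta["cell_type"].isin(set(exclude_types))
    sub = meta[mask]
    if not len(sub):
        raise ValidationError("no labeled cells remain after filters")
    all_patients = meta["patient"].unique()
    counts = pd.crosstab(sub["patient"], sub["cell_type"])
    dropped = sorted(set(all_patients) - set(counts.index))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} patients without included cells: "
                      f"{dropped[:5]}")
    fractions = counts.div(counts.sum(axis=1), axis=0)
    patient_dataset = (meta.drop_duplicates("patient")
                       .set_index("patient")["dataset"]
                       .reindex(fractions.index))
    return PatientFractionMatrix(values=fractions, dataset=patient_dataset,
                                 included_types=list(fractions.columns))


def regress_out_batch(m: PatientFractionMatrix) -> pd.DataFrame:
    """Residuals of each cell-type column after OLS on dataset indicators.

    With an intercept plus dataset dummies this is exactly within-dataset
    centering, so per-dataset column means of the residuals are 0.  A
    dataset containing a single patient gets residual 0 (the fit is exact)
    and is flagged with a warning.
    """
    if len(m.values) < 2:
        raise ValidationError("need at least 2 patients")
    sizes = m.dataset.value_counts()
    singletons = sizes[sizes == 1].index.tolist()
    if singletons:
        warnings.warn(f"datasets with a single patient (residual forced to 0): "
                      f"{singletons}")
    centered = m.values - m.values.groupby(m.dataset).transform("mean")
    return centered


def cluster_patients(residuals: pd.DataFrame, resolution: float = 1.0,
                     seed: int = 0, n_neighbors: int | None = None
                     ) -> StratificationResult:
    """Leiden clustering on a correlation-distance kNN graph of patients.

    ``n_neighbors`` defaults to min(15, n_patients - 1).  A constant patient
    profile (undefined correlation) is rejected by name.
    """
    n = len(residuals)
    if n < 3:
        raise ValidationError("need at least 3 patients to cluster")
    row_sd = residuals.std(axis=1, ddof=0)
    flat = residuals.index[row_sd == 0].tolist()
    if flat:
        raise ValidationError(
            f"constant profile (correlation undefined) for patients: {flat[:5]}"
        )
    if n_neighbors is None:
        n_neighbors = min(15, n - 1)

    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(residuals.to_numpy(dtype=np.float64),
                       obs=pd.DataFrame(index=residuals.index.astype(str)))
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, metric="correlation",
                    use_rep="X", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg", key_added="cluster")
    clusters = pd.Series(adata.obs["cluster"].astype(str).to_numpy(),
                         index=residuals.index, name="cluster")
    return StratificationResult(clusters=clusters, resolution=resolution, seed=seed)


def name_clusters(result: StratificationResult, fractions: PatientFractionMatrix,
                  immune_floor: float = 0.1, cancer_type: str = "cancer"
                  ) -> dict:
    """Name clusters by their predominant cell type.

    A cluster whose cancer-cell mean fraction is the largest while every
    immune (non-cancer) type stays below ``immune_floor`` is named
    "immune-deserted".  Exact ties between top types give a composite
    "a/b" name and are flagged in ``result.ties``.
    """
    names: dict = {}
    ties: dict = {}
    values = fractions.values.reindex(result.clusters.index)
    for cluster in sorted(result.clusters.unique()):
        members = result.clusters[result.clusters == cluster].index
        means = values.loc[members].mean(axis=0)
        immune = means.drop(cancer_type, errors="ignore")
        cancer_mean = means.get(cancer_type, 0.0)
        if (len(immune) and cancer_mean >= means.max() - 1e-12
                and (immune < immune_floor).all()):
            names[cluster] = IMMUNE_DESERTED
            continue
        top = means.max()
        top_types = sorted(means.index[means >= top - 1e-12])
        if len(top_types) > 1:
            ties[cluster] = top_types
        names[cluster] = "/".join(top_types)
    result.cluster_names = names
    result.ties = ties
    return names
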