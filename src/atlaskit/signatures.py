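"""Cell-type marker signatures: FC / sFC / AUROC statistics, threshold
selection, bulk scoring, and patient-level grid-search cross-validation.

For a target cell type, per gene on log2-CPM pseudobulk groups:

* ``fc``    — mean over target groups minus mean over all non-target groups
  (a log2 fold change);
* ``sfc``   — mean over target groups minus the *highest* per-type mean among
  the other cell types (the "most confusable" background; specific fold change);
* ``auroc`` — probability that a random target group exceeds a random
  non-target group (Mann–Whitney with ties counted half), pooled over groups.

A signature is the genes strictly exceeding all three thresholds, ranked by
AUROC.  Thresholds are chosen by a grid search under patient-level
cross-validation: signatures are scored (mean of across-sample z-scores) on
per-patient mixed pseudobulk of held-out patients, and quality is the
Pearson correlation between score and the true fraction of the target type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._rng import substream
from .data import BulkMatrix, CellDataset
from .errors import UnscorableError, ValidationError
from .pseudobulk import LOG2_CPM, PseudobulkMatrix, aggregate, normalize_cpm_log2

AUROC_DEFAULT_GRID = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.96, 0.97)

# permissive cutoffs used for subcluster marker listing: sFC > 1, FC > 1.5
PERMISSIVE_SFC_MIN = 1.0
PERMISSIVE_FC_MIN = 1.5


@dataclass
class GeneStats:
    """Per-gene fc / sfc / auroc for one target cell type."""

    target: str
    stats: pd.DataFrame  # index: gene; columns: fc, sfc, auroc

    def __post_init__(self) -> None:
        auroc = self.stats["auroc"].to_numpy()
        if auroc.size and (auroc.min() < 0 or auroc.max() > 1):
            raise ValidationError("auroc outside [0, 1]")


@dataclass
class GridSpec:
    """Threshold grids for sfc, fc and auroc, each strictly increasing."""

    sfc_grid: tuple
    fc_grid: tuple
    auroc_grid: tuple

    def __post_init__(self) -> None:
        for name in ("sfc_grid", "fc_grid", "auroc_grid"):
            g = tuple(float(v) for v in getattr(self, name))
            if len(g) == 0 or any(b <= a for a, b in zip(g, g[1:])):
                raise ValidationError(f"{name} must be non-empty and strictly increasing")
            setattr(self, name, g)

    @classmethod
    def default(cls) -> "GridSpec":
        steps = tuple(round(0.5 + 0.1 * i, 1) for i in range(25))  # 0.5 .. 2.9
        return cls(sfc_grid=steps, fc_grid=steps, auroc_grid=AUROC_DEFAULT_GRID)

    @classmethod
    def reduced(cls) -> "GridSpec":
        """A 5 x 5 x 4 grid spanning the same ranges, for CI-scale runs."""
        return cls(sfc_grid=(0.5, 1.0, 1.5, 2.0, 2.5),
                   fc_grid=(0.5, 1.0, 1.5, 2.0, 2.5),
                   auroc_grid=(0.7, 0.8, 0.9, 0.97))

    @property
    def n_combinations(self) -> int:
        return len(self.sfc_grid) * len(self.fc_grid) * len(self.auroc_grid)

    def combinations(self) -> list[tuple[float, float, float]]:
        """All (sfc_min, fc_min, auroc_min) combinations, lexicographic order."""
        return list(itertools.product(self.sfc_grid, self.fc_grid, self.auroc_grid))


@dataclass
class SignatureSet:
    """An ordered marker gene list with the thresholds that produced it."""

    name: str
    target_cell_type: str | None
    genes: list[str]
    thresholds: object = None  # (sfc_min, fc_min, auroc_min) or "composite"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CVResult:
    """Grid-search cross-validation report.

    ``table`` has one row per grid combination with per-fold and mean
    Pearson r; ``best_combination`` is the argmax of the mean (ties broken
    toward the lexicographically smallest, i.e. most permissive, thresholds);
    ``test_r`` is the Pearson r of the final signature on held-out patients.
    """

    table: pd.DataFrame
    best_combination: tuple[float, float, float]
    test_r: float
    train_patients: list
    test_patients: list
    seed: int


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def compute_gene_stats(pb: PseudobulkMatrix, target: str) -> GeneStats:
    """Per-gene fc, sfc and pooled AUROC of ``target`` vs all other groups."""
    if pb.scale != LOG2_CPM:
        raise ValidationError(f"gene stats require log2_cpm pseudobulk, got {pb.scale!r}")
    types = pb.groups["cell_type"]
    is_target = (types == target).to_numpy()
    n1 = int(is_target.sum())
    n0 = int((~is_target).sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError(
            f"need >= 2 target and >= 2 non-target groups, got {n1} and {n0}"
        )
    X = pb.values.to_numpy()
    target_mean = X[is_target].mean(axis=0)
    fc = target_mean - X[~is_target].mean(axis=0)

    other_types = [t for t in types.unique() if t != target]
    other_means = np.stack([
        X[(types == t).to_numpy()].mean(axis=0) for t in other_types
    ])
    sfc = target_mean - other_means.max(axis=0)

    ranks = rankdata(X, axis=0, method="average")
    rank_sum = ranks[is_target].sum(axis=0)
    auroc = (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    stats = pd.DataFrame({"fc": fc, "sfc": sfc, "auroc": auroc}, index=pb.genes)
    return GeneStats(target=target, stats=stats)


def select_signature(stats: GeneStats, sfc_min: float, fc_min: float,
                     auroc_min: float, top_n: int | None = None,
                     name: str | None = None) -> SignatureSet:
    """Genes strictly exceeding all thresholds, ranked by descending AUROC
    (ties: descending fc, then gene symbol).  An empty result is valid."""
    df = stats.stats
    mask = ((df["sfc"] > sfc_min) & (df["fc"] > fc_min)
            & (df["auroc"] > auroc_min)).to_numpy()
    sel = df[mask]
    order = np.lexsort((
        sel.index.to_numpy().astype(str),
        -sel["fc"].to_numpy(),
        -sel["auroc"].to_numpy(),
    ))
    genes = list(sel.index[order])
    if top_n is not None:
        genes = genes[:top_n]
    return SignatureSet(
        name=name or f"{stats.target}_signature",
        target_cell_type=stats.target,
        genes=genes,
        thresholds=(float(sfc_min), float(fc_min), float(auroc_min)),
    )


def union_signature(a: SignatureSet, b: SignatureSet, name: str) -> SignatureSet:
    """Set union (a's genes first, then b's unseen genes); thresholds 'composite'."""
    genes = list(a.genes) + [g for g in b.genes if g not in set(a.genes)]
    if a.target_cell_type == b.target_cell_type:
        target = a.target_cell_type
    else:
        target = f"{a.target_cell_type}+{b.target_cell_type}"
    return SignatureSet(name=name, target_cell_type=target, genes=genes,
                        thresholds="composite",
                        provenance={"components": [a.name, b.name]})


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _expression_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, BulkMatrix):
        return matrix.values
    if isinstance(matrix, PseudobulkMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise ValidationError(f"cannot score a {type(matrix).__name__}")


def _score_block(values: pd.DataFrame, genes: list[str]) -> pd.Series | None:
    present = [g for g in genes if g in values.columns]
    if not present:
        return None
    X = values[present].to_numpy(dtype=float)
    sd = X.std(axis=0)  # population sd
    ok = sd > 0
    if not ok.any():
        return None
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    return pd.Series(Z.mean(axis=1), index=values.index)


def score_signature(matrix, signature: SignatureSet,
                    sample_datasets: pd.Series | None = None) -> pd.Series:
    """Mean of across-sample z-scores of the signature genes, per sample.

    z-scores use the population standard deviation across samples; genes
    with zero variance are dropped.  When ``sample_datasets`` is given,
    z-scores are computed within each dataset separately (samples from
    different cohorts are never standardized jointly).

    Raises
    ------
    UnscorableError
        if no signature gene is present or every present gene is constant.
    """
    values = _expression_frame(matrix)
    if len(values) < 2:
        raise ValidationError("scoring needs at least 2 samples")
    if len(signature.genes) == 0:
        raise UnscorableError(f"signature {signature.name!r} is empty")
    if sample_datasets is None:
        blocks = [values]
    else:
        sample_datasets = sample_datasets.reindex(values.index)
        blocks = [values.loc[sample_datasets == d]
                  for d in sample_datasets.unique()]
    parts = []
    for block in blocks:
        scored = _score_block(block, signature.genes)
        if scored is None:
            raise UnscorableError(
                f"signature {signature.name!r} has no scoreable gene in a "
                f"{len(block)}-sample block"
            )
        parts.append(scored)
    return pd.concat(parts).reindex(values.index)


# ---------------------------------------------------------------------------
# grid-search cross-validation
# ---------------------------------------------------------------------------

def _pearson_rows(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of S against y; zero variance on either side -> 0."""
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    Sc = S - S.mean(axis=1, keepdims=True)
    num = Sc @ yc
    den = np.sqrt((Sc ** 2).sum(axis=1) * y_ss)
    out = np.zeros(S.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(_pearson_rows(x[None, :], y)[0])


def _grid_fold_r(stats: GeneStats, val_values: pd.DataFrame, frac: np.ndarray,
                 combos: np.ndarray) -> np.ndarray:
    """Pearson r of every grid combination on one validation fold (vectorized).

    Empty signatures score -1 (so the argmax is total); non-empty but
    unscorable ones score 0 (the zero-variance convention).
    """
    df = stats.stats.reindex(val_values.columns)
    sfc = df["sfc"].to_numpy()
    fc = df["fc"].to_numpy()
    auroc = df["auroc"].to_numpy()

    X = val_values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]

    pass_mask = ((sfc[None, :] > combos[:, 0:1])
                 & (fc[None, :] > combos[:, 1:2])
                 & (auroc[None, :] > combos[:, 2:3]))
    n_selected = pass_mask.sum(axis=1)
    scoreable = pass_mask & ok[None, :]
    n_scoreable = scoreable.sum(axis=1)

    scores = scoreable.astype(float) @ Z.T  # combos x samples
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(n_scoreable[:, None] > 0,
                          scores / np.maximum(n_scoreable, 1)[:, None], 0.0)
    r = _pearson_rows(scores, frac)
    r[n_selected == 0] = -1.0
    r[(n_selected > 0) & (n_scoreable == 0)] = 0.0
    return r


def _true_fractions_from_labels(dataset: CellDataset, target: str) -> pd.Series:
    meta = dataset.cell_meta.dropna(subset=["cell_type"])
    per_patient = meta.groupby("patient").size()
    per_target = meta[meta["cell_type"] == target].groupby("patient").size()
    return (per_target.reindex(per_patient.index, fill_value=0) / per_patient)


def _mixed_scores_vs_fractions(dataset: CellDataset, patients: list,
                               signature: SignatureSet, fractions: pd.Series,
                               min_cells: int) -> float:
    """Score a signature on per-patient mixed pseudobulk; Pearson r vs fractions."""
    sub = dataset.subset_cells(dataset.cell_meta["patient"].isin(patients))
    pb = normalize_cpm_log2(aggregate(sub, "patient_mixed", min_cells=min_cells))
    if len(pb) < 2 or len(signature.genes) == 0:
        return 0.0
    try:
        scores = score_signature(pb, signature)
    except UnscorableError:
        return 0.0
    frac = fractions.reindex(pb.groups["patient"]).to_numpy()
    return _safe_pearson(scores.to_numpy(), frac)


def grid_search_cv(dataset: CellDataset, target: str,
                   grid: GridSpec | None = None, test_fraction: float = 0.2,
                   folds: int = 5, seed: int = 0,
                   true_fractions: pd.Series | None = None,
                   min_cells: int = 10) -> tuple[CVResult, SignatureSet]:
    """Choose signature thresholds by patient-level grid-search CV.

    Patients are shuffled (seeded; sorted first for platform stability) and
    split into a held-out test fraction and training patients.  Within each
    CV fold, gene statistics are computed on the fold-train patients'
    (patient x cell type) pseudobulk, every grid combination is turned into
    a signature, and each signature is scored on the fold-validation
    patients' per-patient *mixed* pseudobulk; quality is the Pearson r
    between score and the true fraction of the target type.  The combination
    with the highest mean r across folds wins, the final signature is
    recomputed on all training patients, and ``test_r`` reports its quality
    on the held-out patients.

    ``true_fractions`` defaults to the per-patient fraction of target-type
    cells among labeled cells (how the atlas pipeline defines it); pass a
    Series to override with external ground truth.
    """
    grid = grid or GridSpec.default()
    if "cell_type" not in dataset.cell_meta.columns:
        raise ValidationError("grid_search_cv requires cell_type labels")
    if target not in set(dataset.cell_meta["cell_type"].dropna()):
        raise ValidationError(f"target cell type {target!r} not present")
    if true_fractions is None:
        true_fractions = _true_fractions_from_labels(dataset, target)

    patients = sorted(dataset.cell_meta["patient"].unique())
    rng = substream(seed, "grid_search_cv")
    shuffled = [patients[i] for i in rng.permutation(len(patients))]
    n_test = max(1, int(round(test_fraction * len(patients))))
    test_patients = shuffled[:n_test]
    train_patients = shuffled[n_test:]
    if len(train_patients) < folds + 1:
        raise ValidationError(
            f"need >= folds+1 = {folds + 1} training patients, got {len(train_patients)}"
        )
    fold_chunks = [list(c) for c in np.array_split(np.array(train_patients, dtype=object), folds)]
    for k, chunk in enumerate(fold_chunks):
        if len(chunk) < 2:
            raise ValidationError(f"fold {k} has {len(chunk)} patients (< 2)")

    combos = np.array(grid.combinations(), dtype=float)
    R = np.zeros((len(combos), folds))
    train_set = set(train_patients)
    meta_patient = dataset.cell_meta["patient"]
    for k, val_p in enumerate(fold_chunks):
        fold_train = sorted(train_set - set(val_p))
        sub_tr = dataset.subset_cells(meta_patient.isin(fold_train))
        stats = compute_gene_stats(
            normalize_cpm_log2(aggregate(sub_tr, "patient_cell_type", min_cells=min_cells)),
            target,
        )
        sub_val = dataset.subset_cells(meta_patient.isin(val_p))
        pb_val = normalize_cpm_log2(aggregate(sub_val, "patient_mixed", min_cells=min_cells))
        frac = true_fractions.reindex(pb_val.groups["patient"]).to_numpy()
        R[:, k] = _grid_fold_r(stats, pb_val.values, frac, combos)

    mean_r = R.mean(axis=1)
    best_idx = int(np.argmax(mean_r))  # first max = lexicographically smallest combo
    best = tuple(float(v) for v in combos[best_idx])

    sub_train = dataset.subset_cells(meta_patient.isin(train_patients))
    stats_full = compute_gene_stats(
        normalize_cpm_log2(aggregate(sub_train, "patient_cell_type", min_cells=min_cells)),
        target,
    )
    signature = select_signature(stats_full, *best, name=f"{target}_cv")
    test_r = _mixed_scores_vs_fractions(dataset, test_patients, signature,
                                        true_fractions, min_cells)
    signature.provenance = {
        "seed": seed,
        "train_patients": list(train_patients),
        "test_r": test_r,
    }
    table = pd.DataFrame(combos, columns=["sfc_min", "fc_min", "auroc_min"])
    for k in range(folds):
        table[f"fold_{k}_r"] = R[:, k]
    table["mean_r"] = mean_r
    result = CVResult(table=table, best_combination=best, test_r=test_r,
                      train_patients=list(train_patients),
                      test_patients=list(test_patients), seed=seed)
    return result, signature
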