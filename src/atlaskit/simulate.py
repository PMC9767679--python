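"""Synthetic atlas generator with known ground truth.

Emulates the structure of a multi-dataset single-cell atlas — several
datasets x patients x cell types — with negative-binomial UMI counts,
planted marker genes, multiplicative (log2) dataset batch effects,
lognormal library sizes, bulk mixtures with known cell fractions,
per-cell phenotype-association labels, and Gaussian latent embeddings.
Every generator is a pure function of (config, seed); substreams are
derived from the global seed and the operation name.

The generators deliberately omit ambient RNA, doublets and
chemistry-specific effects: batch differences are mean shifts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .data import BulkMatrix, CellDataset
from .errors import ValidationError


@dataclass
class CellTypeSpec:
    """One simulated cell type: a linear-scale base expression profile over
    all genes, the indices of its planted marker genes, and the marker
    boost in log2 units (effect 2 means markers are 4x the base mean)."""

    name: str
    base_profile: np.ndarray
    marker_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    marker_log2_effect: float = 0.0

    def __post_init__(self) -> None:
        self.base_profile = np.asarray(self.base_profile, dtype=float)
        self.marker_genes = np.asarray(self.marker_genes, dtype=int)
        if not np.isfinite(self.marker_log2_effect) or self.marker_log2_effect < 0:
            raise ValidationError(f"marker_log2_effect must be finite and >= 0")
        if (self.base_profile < 0).any() or not np.all(np.isfinite(self.base_profile)):
            raise ValidationError("base_profile must be finite and nonnegative")


@dataclass
class AtlasSimConfig:
    n_datasets: int
    patients_per_dataset: int
    cell_types: list[CellTypeSpec]
    cells_per_patient_per_type: object = 50  # int or (low, high) inclusive range
    nb_dispersion: float = 0.5
    dataset_batch_log2_sd: float = 0.0
    dataset_batch_log2_shift: np.ndarray | None = None  # n_datasets x G, overrides sd
    library_size_mean: float = 5000.0
    library_size_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_datasets < 1 or self.patients_per_dataset < 1:
            raise ValidationError("need at least one dataset and one patient")
        if not self.cell_types:
            raise ValidationError("need at least one cell type")
        G = len(self.cell_types[0].base_profile)
        seen: set[int] = set()
        for ct in self.cell_types:
            if len(ct.base_profile) != G:
                raise ValidationError("base profiles must share one gene axis")
            markers = set(ct.marker_genes.tolist())
            if markers & seen:
                raise ValidationError("marker gene sets must be disjoint across cell types")
            seen |= markers
        if not (self.nb_dispersion > 0 and np.isfinite(self.nb_dispersion)):
            raise ValidationError("nb_dispersion must be > 0")
        if self.library_size_mean <= 0:
            raise ValidationError("library_size_mean must be > 0")
        if self.dataset_batch_log2_shift is not None:
            shifts = np.asarray(self.dataset_batch_log2_shift, dtype=float)
            if shifts.shape != (self.n_datasets, G):
                raise ValidationError("dataset_batch_log2_shift must be n_datasets x n_genes")

    @property
    def n_genes(self) -> int:
        return len(self.cell_types[0].base_profile)


@dataclass
class GroundTruth:
    """What the generator planted: marker sets, per-patient cell-type
    fractions (rows sum to 1), and where applicable the phenotype driver
    and per-cell association labels."""

    markers: dict
    true_fractions: pd.DataFrame
    phenotype_driver: str | None = None
    cell_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.true_fractions):
            sums = self.true_fractions.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("true fractions must sum to 1 per patient/sample")


def default_atlas_config(n_genes: int = 2000, n_cell_types: int = 4,
                         n_datasets: int = 2, patients_per_dataset: int = 12,
                         markers_per_type: int = 30,
                         marker_log2_effect: float = 2.0,
                         cells_per_patient_per_type=(20, 80),
                         nb_dispersion: float = 0.5,
                         dataset_batch_log2_sd: float = 0.3,
                         library_size_mean: float = 5000.0,
                         seed: int = 0) -> AtlasSimConfig:
    """Build a standard study configuration.

    The base profile is lognormal over genes and *shared* by all cell
    types, so planted markers are the only systematic type difference;
    the first ``markers_per_type`` genes of disjoint blocks are markers.
    """
    rng = substream(seed, "default_atlas_config")
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    types = []
    for t in range(n_cell_types):
        markers = np.arange(t * markers_per_type, (t + 1) * markers_per_type)
        if markers_per_type and markers[-1] >= n_genes:
            raise ValidationError("not enough genes for disjoint marker blocks")
        types.append(CellTypeSpec(
            name=f"type{t}", base_profile=base,
            marker_genes=markers if markers_per_type else np.array([], dtype=int),
            marker_log2_effect=marker_log2_effect,
        ))
    return AtlasSimConfig(
        n_datasets=n_datasets, patients_per_dataset=patients_per_dataset,
        cell_types=types, cells_per_patient_per_type=cells_per_patient_per_type,
        nb_dispersion=nb_dispersion, dataset_batch_log2_sd=dataset_batch_log2_sd,
        library_size_mean=library_size_mean, seed=seed,
    )


def _cells_per_group(config: AtlasSimConfig, rng: np.random.Generator) -> int:
    spec = config.cells_per_patient_per_type
    if np.isscalar(spec):
        return int(spec)
    low, high = spec
    return int(rng.integers(low, high + 1))


def generate_atlas(config: AtlasSimConfig) -> tuple[CellDataset, GroundTruth]:
    """Draw the synthetic atlas.

    For a cell of type t in dataset d, gene g has negative-binomial mean
    proportional to ``base[g] * 2**(effect if g in markers(t)) *
    2**(batch_shift[d, g])``, rescaled to the cell's lognormal library
    size.  Dispersion is shared: variance = mu + dispersion * mu^2.
    """
    config.validate()
    rng = substream(config.seed, "generate_atlas")
    G = config.n_genes
    if config.dataset_batch_log2_shift is not None:
        shifts = np.asarray(config.dataset_batch_log2_shift, dtype=float)
    else:
        shifts = rng.normal(0.0, config.dataset_batch_log2_sd, size=(config.n_datasets, G))

    r = 1.0 / config.nb_dispersion
    log_lib = np.log(config.library_size_mean) - config.library_size_log_sd ** 2 / 2.0

    blocks, cell_ids, meta_rows = [], [], []
    counts_per_patient_type: dict[tuple, int] = {}
    for d in range(config.n_datasets):
        ds_name = f"ds{d}"
        for p in range(config.patients_per_dataset):
            patient = f"{ds_name}_p{p:02d}"
            condition = "LUAD" if (d + p) % 2 == 0 else "LUSC"
            stage = "early" if p % 2 == 0 else "advanced"
            for ct in config.cell_types:
                n = _cells_per_group(config, rng)
                profile = ct.base_profile.copy()
                if len(ct.marker_genes):
                    profile[ct.marker_genes] *= 2.0 ** ct.marker_log2_effect
                profile *= 2.0 ** shifts[d]
                prop = profile / profile.sum()
                libs = rng.lognormal(mean=log_lib, sigma=config.library_size_log_sd, size=n)
                mu = prop[None, :] * libs[:, None]
                counts = rng.negative_binomial(r, r / (r + mu))
                blocks.append(sp.csr_matrix(counts))
                cell_ids.extend(f"{patient}_{ct.name}_{i:04d}" for i in range(n))
                meta_rows.extend(
                    {"patient": patient, "sample": f"{patient}_s1",
                     "dataset": ds_name, "cell_type": ct.name,
                     "tissue": "tumor_primary", "condition": condition,
                     "tumor_stage": stage}
                    for _ in range(n)
                )
                counts_per_patient_type[(patient, ct.name)] = n

    counts = sp.vstack(blocks, format="csr")
    genes = pd.Index([f"G{i:05d}" for i in range(G)])
    cells = pd.Index(cell_ids)
    meta = pd.DataFrame(meta_rows, index=cells)
    dataset = CellDataset(counts=counts, genes=genes, cells=cells, cell_meta=meta)

    type_names = [ct.name for ct in config.cell_types]
    patients = sorted({p for p, _ in counts_per_patient_type})
    frac = pd.DataFrame(
        [[counts_per_patient_type[(p, t)] for t in type_names] for p in patients],
        index=pd.Index(patients, name="patient"), columns=type_names, dtype=float,
    )
    frac = frac.div(frac.sum(axis=1), axis=0)
    markers = {ct.name: [genes[i] for i in ct.marker_genes] for ct in config.cell_types}
    return dataset, GroundTruth(markers=markers, true_fractions=frac)


def generate_bulk_mixtures(dataset: CellDataset, n_samples: int,
                           concentration=1.0, noise_sd: float = 0.0,
                           seed: int = 0,
                           fractions: pd.DataFrame | None = None
                           ) -> tuple[BulkMatrix, GroundTruth]:
    """Mix per-cell-type mean profiles into bulk samples with known fractions.

    Fractions are Dirichlet(concentration) unless an explicit samples x
    cell-type ``fractions`` table is given; noise is multiplicative
    lognormal with log-sd ``noise_sd`` (0 = exact mixture).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = substream(seed, "generate_bulk_mixtures")
    types = dataset.cell_types
    if not types:
        raise ValidationError("dataset has no labeled cell types")
    profiles = np.stack([
        np.asarray(dataset.counts[(dataset.cell_meta["cell_type"] == t).to_numpy()]
                   .mean(axis=0)).ravel()
        for t in types
    ])
    if fractions is not None:
        missing = set(fractions.columns) - set(types)
        if missing:
            raise ValidationError(f"cell types absent from dataset: {sorted(missing)}")
        F = fractions.reindex(columns=types, fill_value=0.0).to_numpy(dtype=float)
        index = pd.Index(fractions.index.astype(str), name="sample")
    else:
        if np.isscalar(concentration):
            alpha = np.full(len(types), float(concentration))
        else:
            unknown = set(concentration) - set(types)
            if unknown:
                raise ValidationError(f"cell types absent from dataset: {sorted(unknown)}")
            alpha = np.array([concentration[t] for t in types], dtype=float)
        F = rng.dirichlet(alpha, size=n_samples)
        index = pd.Index([f"bulk{i:03d}" for i in range(n_samples)], name="sample")
    values = F @ profiles
    if noise_sd > 0:
        values = values * rng.lognormal(mean=0.0, sigma=noise_sd, size=values.shape)
    bulk = BulkMatrix(
        values=pd.DataFrame(values, index=index, columns=dataset.genes),
        sample_meta=pd.DataFrame({"dataset": "bulk_sim"}, index=index),
    )
    truth = GroundTruth(
        markers={},
        true_fractions=pd.DataFrame(F, index=index, columns=types),
    )
    return bulk, truth


def generate_phenotypes(dataset: CellDataset, driver: str, effect: float = 0.0,
                        base_rate: float = 0.1, seed: int = 0
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Draw per-cell association labels and per-patient phenotypes.

    Cells are labeled plus / minus / neutral.  Non-driver cells get plus and
    minus at the symmetric ``base_rate``; driver cells get plus at
    ``base_rate + effect``.  Under effect 0 the labeling is exchangeable.
    Per-patient phenotypes (binary response, exponential survival with
    censoring) are tied to the realized driver-cell fraction.
    """
    if driver not in dataset.cell_types:
        raise ValidationError(f"driver cell type {driver!r} not present")
    if not (0 <= base_rate and base_rate + max(effect, 0.0) <= 1 - base_rate):
        raise ValidationError("base_rate/effect leave no room for neutral cells")
    rng = substream(seed, "generate_phenotypes")
    is_driver = (dataset.cell_meta["cell_type"] == driver).to_numpy()
    p_plus = np.where(is_driver, base_rate + effect, base_rate)
    u = rng.random(dataset.n_cells)
    labels = np.where(u < p_plus, "plus",
                      np.where(u < p_plus + base_rate, "minus", "neutral"))
    cell_labels = pd.Series(labels, index=dataset.cells, name="assoc_label")

    meta = dataset.cell_meta
    driver_frac = (meta[meta["cell_type"] == driver].groupby("patient").size()
                   .reindex(sorted(meta["patient"].unique()), fill_value=0)
                   / meta.groupby("patient").size())
    centered = driver_frac - driver_frac.mean()
    p_resp = 1.0 / (1.0 + np.exp(-4.0 * centered * np.sign(effect if effect else 1.0)))
    response = (rng.random(len(driver_frac)) < p_resp).astype(int)
    surv = rng.exponential(scale=np.exp(-2.0 * centered.to_numpy()))
    censor_at = np.quantile(surv, 0.8)
    event = (surv <= censor_at).astype(int)
    surv = np.minimum(surv, censor_at)
    patient_pheno = pd.DataFrame(
        {"response": response, "survival_time": surv, "event": event,
         "driver_fraction": driver_frac},
        index=driver_frac.index,
    )
    return cell_labels, patient_pheno


def generate_embedding(dataset: CellDataset, separation: float = 10.0,
                       k_latent: int = 10, seed: int = 0) -> pd.DataFrame:
    """Gaussian latent clouds per cell type (unit within-type sd).

    Centroids are orthogonal directions scaled by ``separation`` (random
    directions when k_latent < number of types); separation 0 collapses all
    types into a single cloud.  A stand-in for a batch-corrected joint
    embedding.
    """
    if k_latent < 1:
        raise ValidationError("k_latent must be >= 1")
    if separation < 0:
        raise ValidationError("separation must be >= 0")
    rng = substream(seed, "generate_embedding")
    types = dataset.cell_types
    if not types:
        raise ValidationError("dataset has no labeled cell types")
    k_types = len(types)
    if k_latent >= k_types:
        basis, _ = np.linalg.qr(rng.standard_normal((k_latent, k_latent)))
        dirs = basis[:, :k_types].T
    else:
        raw = rng.standard_normal((k_types, k_latent))
        dirs = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    centroids = {t: separation * dirs[i] for i, t in enumerate(types)}
    coords = rng.standard_normal((dataset.n_cells, k_latent))
    cell_types = dataset.cell_meta["cell_type"].to_numpy()
    for t in types:
        coords[cell_types == t] += centroids[t]
    return pd.DataFrame(coords, index=dataset.cells,
                        columns=[f"latent_{i}" for i in range(k_latent)])
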