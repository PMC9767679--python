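# Methods

This note documents the models and procedures implemented in `atlaskit`,
the parameters that matter, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Data model

A `CellDataset` is a sparse cell × gene matrix of nonnegative integer UMI
counts with per-cell metadata (patient, sample, dataset, optional cell
type, tissue, condition, stage). Counts stay sparse throughout; no stage
densifies the full matrix (pseudobulk aggregation multiplies by a sparse
group-indicator matrix and only the small group × gene result is dense).
Gene-symbol collisions are rejected at load time rather than resolved:
identifier remapping belongs upstream of this package. Missing cell-type
labels are allowed — they are exactly the state of query cells before label
transfer — and every operation that needs labels rejects unlabeled cells
explicitly instead of guessing. On-disk formats are deliberately plain:
MatrixMarket coordinate (1-based) plus gene/cell lists and a tab-separated
metadata table; GMT for gene sets; TSV for everything tabular.

## Pseudobulk

Counts are summed per (patient, cell type) or per patient with all types
mixed. Groups with fewer than `min_cells` cells (default 10, i.e. groups of
≤ 9 are dropped) are discarded before any statistic is computed; this
filter suppresses noisy groups dominated by a handful of cells. Rows are
then scaled to counts per million and transformed with log2(x + 1).
The pseudocount of 1 CPM makes zero counts map to 0 and keeps the
transform invertible (tests verify `2^y − 1` restores rows summing to 1e6).
Note the phenotype-association module uses a *different*, inclusive-10
exclusion (≤ 10 cells excluded, 11 retained); the two thresholds are
separate parameters on purpose and are never merged.

## Marker statistics and signatures

FC and sFC are differences of group means on the log2-CPM scale — i.e.
log2 fold changes. The grids (0.5–2.9) are interpreted on this scale;
values below 1 are meaningful as log2 ratios but not as linear ratios,
which is why the log2 reading was adopted. The sFC background is the
*maximum* per-type mean among non-target types — the most confusable
background — which is the standard construction for a "specific" fold
change and guarantees sFC ≤ FC. AUROC is the Mann–Whitney probability
computed from pooled ranks over all pseudobulk groups (average ranks, so
ties count half); pooling across patients was chosen over per-patient
averaging because groups are already patient-level aggregates.
Selection uses strict inequalities (a gene exactly at a threshold is
excluded), ranks by descending AUROC with ties broken by descending FC and
then gene symbol, and an empty selection is a valid result.

### Grid-search cross-validation

Patients (sorted lexicographically first, then shuffled by the seeded
generator, so runs reproduce across platforms) are split into a held-out
test fraction (default 20%, at least one patient) and training patients;
5-fold CV runs over the training patients in contiguous chunks of the
shuffled order. Per fold, gene statistics come from the fold-train
(patient × cell type) pseudobulk; each grid combination yields a signature
scored on the fold-validation patients' per-patient mixed pseudobulk, and
quality is the Pearson correlation between score and the true fraction of
the target type (by default the labeled-cell fraction per patient, exactly
how an annotated atlas defines it; an external ground-truth Series can be
passed instead). Numerical conventions, chosen for a total and
deterministic argmax:

- a combination whose signature is empty scores r = −1 in CV (worse than
  any real correlation, so degenerate thresholds can never win);
- Pearson r with a zero-variance side is defined as 0;
- a non-empty signature none of whose genes vary in the validation block
  scores 0 (it carries no information);
- ties in the argmax over mean fold r resolve to the lexicographically
  smallest (sFC, FC, AUROC) — the most permissive, largest signature;
- the final signature (recomputed on all training patients with the best
  combination) reports `test_r` on the held-out patients, with 0 — the
  no-information value — when it is empty or unscorable there.

The CV inner loop is vectorized: all combinations are evaluated as one
boolean combination × gene mask matrix multiplied against the z-scored
validation expression, so the full 5,000-combination grid costs a single
small matrix product per fold.

### Scoring

Signature scores are means of per-gene z-scores taken across samples
(population standard deviation; the choice only rescales scores uniformly
and cannot change rankings or correlations). Genes absent from the matrix
or constant across samples are dropped; if none survive, scoring fails
loudly (`UnscorableError`) rather than returning zeros. When samples come
from several cohorts, pass `sample_datasets` to z-score within each cohort
separately — cross-cohort location shifts should not leak into scores.

## Label transfer

The vote uses the transitive connectivity C′ = C·C of the joint
reference+query kNN graph: it widens each query's effective neighborhood
and connects queries whose direct neighbors are all queries. The kNN
weights are 1/(1 + Euclidean distance), symmetrized by the elementwise
maximum of directed weights. The upstream choice of kernel is not critical
— the vote is invariant to uniform rescaling of C, and any positive
decreasing kernel preserves it on separated data — so the kernel lives in
one place and can be swapped. Ties break lexicographically by label and
are flagged; a query with zero transitive connectivity to every reference
is reported "unassigned" (the argmax is undefined there, and a silent
nearest-centroid fallback would hide integration failures).

## Patient stratification

Fractions are computed over labeled tumor-primary cells after configurable
type exclusions (e.g. neutrophils, which droplet-based chemistries capture
poorly; or whole datasets restricted to a single lineage) and renormalized
to sum 1. Batch removal is OLS of each cell-type column on dataset
indicator variables, which is exactly within-dataset centering; residuals
may be negative and are used as-is (no clipping or renormalization — the
clustering metric only needs relative profiles). Patients are clustered
with Leiden (leidenalg backend, seeded) on a kNN graph under correlation
distance (1 − Pearson r between patient profiles), k = min(15,
n_patients − 1) by default; a constant patient profile is rejected by name
because its correlation to anything is undefined. Cluster naming takes the
cell type with the highest mean fraction; a cluster whose cancer fraction
is the maximum while every immune type stays below a floor (default mean
fraction 0.1 — the phenotype is descriptive, so the floor is a parameter,
not a claim) is "immune-deserted"; exact ties produce a composite name and
a flag.

## Differential crosstalk

The module deliberately does *not* re-test interactions: differential
expression of signaling molecules arrives as an input (typically a
pseudobulk DESeq2 contrast, default filter adjusted p < 0.1, with a
stricter FDR < 0.01, |log2FC| > 1 variant reachable through the
parameters). Each passing ligand of the source type is joined to the pair
table and emitted once per receiver type whose receptor is expressed in at
least 10% of cells — inclusive, per the plain reading of "at least".
"Expressed" means raw count > 0; the fraction is the unweighted mean of
per-patient fractions, making the quantity invariant to how many cells a
patient happened to contribute. Fractions are computed across all patients
(not within condition groups); filter the dataset first for a per-group
variant. Multi-subunit complexes (members joined by `_`) pass only if
every member passes, and report the minimum member fraction — the limiting
subunit. DE genes absent from the pair table produce no rows; their count
is logged and attached to the result.

## Phenotype association

Per (patient, cell type) with more than 10 cells, plus- and minus-fractions
get a pseudocount of 0.01 added *after* division. The per-type statistic
is log2(mean frac_plus) − log2(mean frac_minus), computed as a difference
of logarithms so that swapping the labels negates it bitwise. The paired
test is the Wilcoxon signed-rank with zero differences retained in the
ranking and their rank mass split evenly between the positive and negative
sums ("zsplit"), under the normal approximation with tie correction —
deterministic and defined for the zero-inflated differences pseudocounted
fractions produce. An all-zero difference vector is the exact null: the
statistic is 0 and p = 1 by convention. The test-suite oracle enumerates
the exact zsplit null for ≤ 8 pairs and confirms the statistic exactly and
the p-value up to the approximation error expected at such small n.
P-values are BH-adjusted across cell types and called significant strictly
below FDR 0.01. Pairing is by patient; a cell type absent from a patient
drops that patient pairwise. Score stratification uses linear
order-statistic quantiles at 0.25/0.75 with groups assigned by value, so
tied scores never straddle groups; a degenerate (all-equal) distribution
assigns everything to "mid" with a warning.

## Synthetic data

The generator emulates the *structure* the pipeline depends on — several
datasets × patients × cell types, overdispersed counts, planted markers,
multiplicative batch effects, bulk mixtures with known composition,
phenotype labels with a known driver, and Gaussian latent embeddings — and
is a pure function of (config, seed), with per-operation substreams keyed
on (seed, operation name) so stages can be regenerated independently.

Counts are negative-binomial with mean proportional to
`base[g] · 2^(effect·[g ∈ markers(t)]) · 2^(batch[d,g])`, rescaled to a
lognormal library size, with a single shared dispersion (variance
μ + φμ²). Default study conditions, chosen once as what a practitioner
would call realistic for pseudobulk work at desk scale: dispersion φ = 0.5;
library size mean 5,000 (log-sd 0.3); dataset batch shifts N(0, 0.3²) in
log2; cells per patient per type uniform in [20, 80] — the variation in
realized cell-type fractions across patients is what makes the
score-vs-fraction correlation a meaningful target; a lognormal(0, 1) base
profile *shared* across cell types, so planted markers are the only
systematic type difference and a no-marker configuration is a genuine
null. Phenotype labels use a symmetric base rate of 0.1 for plus and minus
with the driver type's plus rate raised by the configured effect.
Embedding centroids are orthogonal directions scaled by the separation
parameter with unit within-type noise.

What the generator does **not** emulate — ambient RNA, doublets, per-gene
dispersion, chemistry-specific dropout, correlated marker programs,
type-specific background expression — bounds what passing tests show:
they demonstrate that each algorithm recovers exactly the signal it is
defined to recover under its own model assumptions, not that those
assumptions hold in any particular tissue. On real atlases the interesting
failure modes (markers shared between related types, batch effects that
are not mean shifts) must be assessed with the usual orthogonal controls.

## Problem sizes

The test suite and the verification script run at reduced but non-trivial
scale, chosen so each stage's target is meaningfully exercised: the marker
recovery study uses 2 datasets × 12 patients × 4 types × ~50 cells
(~4,800 cells, 2,000 genes) with the spec'd reduced 5 × 5 × 4 threshold
grid; null calibration averages 20 independent small atlases; association
calibration runs 200 null and 100 alternative simulations on a
20-patient × 3-type × 200-cell dataset; label transfer checks 50 random
graphs of up to 200 cells against a brute-force oracle. The full
5,000-combination grid is enumerated (and counted) directly; running the
CV search on it is a supported but slower configuration of the same code
path.
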