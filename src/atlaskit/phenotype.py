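"""Per-cell phenotype-association statistics and score-based stratification.

Cells carry labels in {plus, minus, neutral} from an upstream single-cell /
bulk phenotype association method (e.g. positively or negatively associated
with a mutation or with survival).  Per patient and cell type, the fraction
of plus and of minus cells is computed with a pseudocount of 0.01, samples
contributing <= 10 cells to a type are excluded, and the per-type statistic
is

    log2_ratio = log2( mean_patients(frac_plus) / mean_patients(frac_minus) ),

tested by a paired Wilcoxon signed-rank test with zero_method="zsplit"
(zero differences keep their ranks, split evenly between the positive and
negative sums) under the normal approximation, Benjamini-Hochberg adjusted
across cell types and called significant at FDR < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .data import CellDataset
from .errors import ValidationError

LABELS = ("plus", "minus", "neutral")


@dataclass
class ScissorLabels:
    """Per-cell association labels plus bookkeeping about their origin."""

    labels: pd.Series  # cell -> {plus, minus, neutral}
    phenotype: str = ""
    family: str = ""  # e.g. "logistic" (mutation) or "cox" (survival)

    def __post_init__(self) -> None:
        bad = set(self.labels.dropna().unique()) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown association labels: {sorted(bad)}")


@dataclass
class AssocTable:
    """Per cell type: log2_ratio, p_value, fdr, significant; plus the
    per-(patient, cell_type) fraction table it was computed from."""

    per_type: pd.DataFrame
    fractions: pd.DataFrame
    excluded_types: list = field(default_factory=list)


def assoc_fractions(labels: ScissorLabels, dataset: CellDataset,
                    pseudocount: float = 0.01,
                    min_cells_exclusive: int = 10) -> pd.DataFrame:
    """Pseudocounted plus/minus fractions per (patient, cell_type).

    A (patient, cell_type) sample is kept only if it contributes strictly
    more than ``min_cells_exclusive`` cells (<= 10 cells excluded).  The
    pseudocount is added *after* dividing: frac = n_label/n + pseudocount.
    """
    lab = labels.labels.reindex(dataset.cells)
    if lab.isna().any():
        raise ValidationError(
            f"{int(lab.isna().sum())} cells lack an association label"
        )
    meta = dataset.cell_meta
    if "cell_type" not in meta.columns:
        raise ValidationError("dataset has no cell_type labels")
    df = pd.DataFrame({
        "patient": meta["patient"],
        "cell_type": meta["cell_type"],
        "label": lab,
    }).dropna(subset=["cell_type"])
    grouped = df.groupby(["patient", "cell_type"], sort=True)
    n = grouped.size()
    n_plus = grouped["label"].apply(lambda s: int((s == "plus").sum()))
    n_minus = grouped["label"].apply(lambda s: int((s == "minus").sum()))
    out = pd.DataFrame({
        "n_cells": n,
        "frac_plus": n_plus / n + pseudocount,
        "frac_minus": n_minus / n + pseudocount,
    })
    return out[out["n_cells"] > min_cells_exclusive]


def assoc_statistic(fractions: pd.DataFrame, fdr_threshold: float = 0.01
                    ) -> AssocTable:
    """log2-ratio of mean plus vs mean minus fractions per cell type, with a
    paired zsplit Wilcoxon test and BH adjustment across cell types.

    Cell types observed in fewer than 2 patients are excluded and reported
    on the result rather than tested.
    """
    rows = []
    excluded = []
    for cell_type, sub in fractions.groupby(level="cell_type", sort=True):
        fp = sub["frac_plus"].to_numpy(dtype=float)
        fm = sub["frac_minus"].to_numpy(dtype=float)
        if len(fp) < 2:
            excluded.append(cell_type)
            continue
        # difference of logs rather than log of ratio: exactly antisymmetric
        # under swapping the plus and minus labels
        log2_ratio = float(np.log2(fp.mean()) - np.log2(fm.mean()))
        diffs = fp - fm
        if np.all(diffs == 0):
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(wilcoxon(fp, fm, zero_method="zsplit",
                                   method="approx").pvalue)
        rows.append({"cell_type": cell_type, "n_patients": len(fp),
                     "log2_ratio": log2_ratio, "p_value": p})
    per_type = pd.DataFrame(rows, columns=["cell_type", "n_patients",
                                           "log2_ratio", "p_value"])
    if len(per_type):
        per_type["fdr"] = multipletests(per_type["p_value"], method="fdr_bh")[1]
        per_type["significant"] = per_type["fdr"] < fdr_threshold
        per_type = per_type.set_index("cell_type")
    else:
        per_type = per_type.set_index("cell_type")
        per_type["fdr"] = pd.Series(dtype=float)
        per_type["significant"] = pd.Series(dtype=bool)
    return AssocTable(per_type=per_type, fractions=fractions,
                      excluded_types=excluded)


def stratify_by_score(scores: pd.Series, lower_q: float = 0.25,
                      upper_q: float = 0.75) -> pd.Series:
    """Assign each sample to low / mid / high by score quantiles.

    Samples at or below the ``lower_q`` quantile are "low", at or above the
    ``upper_q`` quantile "high", the rest "mid" (linear order-statistic
    interpolation; tied scores always land in the same group).  If the two
    quantiles coincide (e.g. all scores identical) everything is "mid".
    """
    if len(scores) < 4:
        raise ValidationError("need at least 4 samples to stratify")
    values = scores.to_numpy(dtype=float)
    ql = float(np.quantile(values, lower_q))
    qh = float(np.quantile(values, upper_q))
    if ql >= qh:
        warnings.warn("degenerate score distribution; every sample assigned 'mid'")
        return pd.Series("mid", index=scores.index, name="group")
    group = np.where(values <= ql, "low", np.where(values >= qh, "high", "mid"))
    return pd.Series(group, index=scores.index, name="group")


def export_association_design(scores: pd.Series, sample_meta: pd.DataFrame,
                              path=None) -> pd.DataFrame:
    """One row per sample, ready for any regression tool: score, score
    group, response, tumor_type, dataset, survival_time, event.

    (The downstream logistic / Cox fits themselves are standard and left to
    the caller's regression package.)
    """
    required = ["response", "tumor_type", "dataset", "survival_time", "event"]
    missing = [c for c in required if c not in sample_meta.columns]
    if missing:
        raise ValidationError(f"sample_meta missing columns: {missing}")
    meta = sample_meta.reindex(scores.index)
    design = pd.DataFrame({
        "score": scores,
        "group": stratify_by_score(scores),
        **{c: meta[c] for c in required},
    })
    if path is not None:
        design.to_csv(path, sep="\t", index_label="sample")
    return design
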