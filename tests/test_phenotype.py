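"""Association fractions, the log2-ratio statistic, and score stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests

from atlaskit import phenotype as ph
from atlaskit.errors import ValidationError

from conftest import make_dataset


def labeled_dataset(label_counts):
    """Build a dataset plus labels from {(patient, cell_type): (n_plus, n_minus, n_neutral)}."""
    patients, types, labels = [], [], []
    for (patient, cell_type), (np_, nm, nn) in label_counts.items():
        n = np_ + nm + nn
        patients += [patient] * n
        types += [cell_type] * n
        labels += ["plus"] * np_ + ["minus"] * nm + ["neutral"] * nn
    ds = make_dataset(np.ones((len(patients), 2), dtype=int),
                      patients=patients, cell_types=types)
    return ds, ph.ScissorLabels(pd.Series(labels, index=ds.cells))


class TestAssocFractions:
    def test_pseudocounted_fractions(self):
        ds, labels = labeled_dataset({("p1", "T"): (5, 0, 95)})
        out = ph.assoc_fractions(labels, ds)
        row = out.loc[("p1", "T")]
        assert row["frac_plus"] == pytest.approx(0.06)   # 5/100 + 0.01
        assert row["frac_minus"] == pytest.approx(0.01)  # 0/100 + 0.01

    def test_ten_cells_excluded_eleven_retained(self):
        ds, labels = labeled_dataset({("p1", "T"): (1, 1, 8),    # 10 cells
                                      ("p1", "B"): (1, 1, 9)})  # 11 cells
        out = ph.assoc_fractions(labels, ds)
        assert ("p1", "T") not in out.index
        assert ("p1", "B") in out.index

    def test_symmetric_counts_give_equal_fractions(self):
        ds, labels = labeled_dataset({("p1", "T"): (7, 7, 6)})
        out = ph.assoc_fractions(labels, ds)
        row = out.loc[("p1", "T")]
        assert row["frac_plus"] == row["frac_minus"]

    def test_uncovered_cells_rejected(self):
        ds, labels = labeled_dataset({("p1", "T"): (5, 5, 10)})
        short = ph.ScissorLabels(labels.labels.iloc[:-1])
        with pytest.raises(ValidationError):
            ph.assoc_fractions(short, ds)


def exact_zsplit(fp, fm):
    """Exact-enumeration signed-rank oracle under the zsplit convention.

    Zero differences keep their (average) ranks, contributing half to each
    signed sum; the null enumerates all sign flips of nonzero differences.
    Returns (min(W+, W-), exact two-sided p).
    """
    d = np.asarray(fp, dtype=float) - np.asarray(fm, dtype=float)
    ranks = rankdata(np.abs(d))
    zero_half = ranks[d == 0].sum() / 2.0
    nz_ranks = ranks[d != 0]
    nz_signs = np.sign(d[d != 0])
    w_plus = zero_half + nz_ranks[nz_signs > 0].sum()
    total = ranks.sum()
    center = total / 2.0
    obs_dev = abs(w_plus - center)
    count = 0
    n_assign = 0
    for signs in itertools.product([1, -1], repeat=len(nz_ranks)):
        w = zero_half + sum(r for r, s in zip(nz_ranks, signs) if s > 0)
        count += abs(w - center) >= obs_dev - 1e-12
        n_assign += 1
    return min(w_plus, total - w_plus), count / n_assign


class TestAssocStatistic:
    def _fractions(self, per_type):
        """per_type: {cell_type: [(frac_plus, frac_minus), ...]}"""
        rows = []
        for cell_type, pairs in per_type.items():
            for i, (fp, fm) in enumerate(pairs):
                rows.append((f"p{i}", cell_type, 20, fp, fm))
        df = pd.DataFrame(rows, columns=["patient", "cell_type", "n_cells",
                                         "frac_plus", "frac_minus"])
        return df.set_index(["patient", "cell_type"])

    def test_single_patient_log2_ratio(self):
        # statistic only; the test needs >= 2 patients
        fr = self._fractions({"T": [(0.06, 0.01), (0.06, 0.01)]})
        table = ph.assoc_statistic(fr).per_type
        assert table.loc["T", "log2_ratio"] == pytest.approx(np.log2(6))

    def test_swapping_labels_negates_log2_ratio_exactly(self):
        rng = np.random.default_rng(0)
        pairs = [(0.01 + p, 0.01 + m)
                 for p, m in rng.random((8, 2)) * 0.3]
        fwd = ph.assoc_statistic(self._fractions({"T": pairs})).per_type
        rev = ph.assoc_statistic(
            self._fractions({"T": [(m, p) for p, m in pairs]})).per_type
        assert fwd.loc["T", "log2_ratio"] == -rev.loc["T", "log2_ratio"]
        assert fwd.loc["T", "p_value"] == rev.loc["T", "p_value"]

    def test_all_zero_differences_give_null_result(self):
        fr = self._fractions({"T": [(0.05, 0.05)] * 6})
        table = ph.assoc_statistic(fr).per_type
        assert table.loc["T", "log2_ratio"] == 0.0
        assert table.loc["T", "p_value"] == 1.0

    def test_single_patient_type_excluded_and_reported(self):
        fr = self._fractions({"T": [(0.1, 0.05)] * 4, "rare": [(0.2, 0.1)]})
        result = ph.assoc_statistic(fr)
        assert "rare" not in result.per_type.index
        assert result.excluded_types == ["rare"]

    def test_statistic_matches_exact_enumeration_for_small_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            fp = np.round(rng.random(n), 2) + 0.01
            fm = np.round(rng.random(n), 2) + 0.01
            k = int(rng.integers(0, n // 2 + 1))
            fm[:k] = fp[:k]  # inject zero differences
            if (fp != fm).sum() < 4:
                # with fewer than 4 nonzero differences the exact null has
                # too few support points for the approximation to track
                continue
            stat_oracle, p_exact = exact_zsplit(fp, fm)
            res = wilcoxon(fp, fm, zero_method="zsplit", method="approx")
            # the zsplit ranking logic must agree exactly on the statistic;
            # the p-value uses a normal approximation whose error against the
            # (discrete, 2^m-point) exact null can reach ~0.2 at such small n
            assert res.statistic == pytest.approx(stat_oracle)
            assert res.pvalue == pytest.approx(p_exact, abs=0.25)

    def test_bh_adjustment_matches_brute_force_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            expected = multipletests(p, method="fdr_bh")[1]
            # brute-force step-up: q_i = min over j>=i of p_(j) * m / j
            order = np.argsort(p)
            q = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                running = min(running, p[order[rank]] * m / (rank + 1))
                q[order[rank]] = running
            np.testing.assert_allclose(expected, q)

    def test_end_to_end_significance_on_strong_signal(self):
        rng = np.random.default_rng(7)
        strong = [(0.25 + e, 0.05 + f) for e, f in rng.normal(0, 0.01, (12, 2))]
        null = [(0.05 + abs(e), 0.05 + abs(f))
                for e, f in rng.normal(0, 0.01, (12, 2))]
        fr = self._fractions({"driver": strong, "bystander": null})
        table = ph.assoc_statistic(fr).per_type
        assert bool(table.loc["driver", "significant"])
        assert table.loc["driver", "log2_ratio"] > 0
        assert not bool(table.loc["bystander", "significant"])


class TestStratifyByScore:
    def test_four_distinct_scores(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = ph.stratify_by_score(scores)
        assert (groups == "low").sum() == 1
        assert (groups == "high").sum() == 1
        assert groups["a"] == "low" and groups["d"] == "high"

    def test_eight_scores_quartiles(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
        groups = ph.stratify_by_score(scores)
        assert list(scores[groups == "low"]) == [1.0, 2.0]
        assert list(scores[groups == "high"]) == [7.0, 8.0]

    def test_identical_scores_all_mid(self):
        scores = pd.Series([2.0] * 5, index=[f"s{i}" for i in range(5)])
        with pytest.warns(UserWarning):
            groups = ph.stratify_by_score(scores)
        assert (groups == "mid").all()

    def test_ties_never_straddle_groups(self):
        scores = pd.Series([1.0, 1.0, 1.0, 5.0, 9.0, 9.0, 9.0],
                           index=[f"s{i}" for i in range(7)])
        groups = ph.stratify_by_score(scores)
        for value in (1.0, 9.0):
            assert groups[scores == value].nunique() == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            ph.stratify_by_score(pd.Series([1.0, 2.0, 3.0]))


class TestExportDesign:
    def _meta(self, index):
        return pd.DataFrame({
            "response": 1, "tumor_type": "LUAD", "dataset": "d1",
            "survival_time": 12.0, "event": 0,
        }, index=index)

    def test_schema(self):
        scores = pd.Series([0.1, -0.2, 0.3, 0.4], index=list("abcd"))
        design = ph.export_association_design(scores, self._meta(scores.index))
        assert design.shape == (4, 7)
        assert list(design.columns) == ["score", "group", "response",
                                        "tumor_type", "dataset",
                                        "survival_time", "event"]

    def test_round_trip(self, tmp_path):
        scores = pd.Series([0.1, -0.2, 0.3, 0.4], index=list("abcd"))
        path = tmp_path / "design.tsv"
        design = ph.export_association_design(scores, self._meta(scores.index),
                                              path=path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        np.testing.assert_allclose(back["score"], design["score"])
        assert list(back["group"]) == list(design["group"])

    def test_missing_covariate_rejected(self):
        scores = pd.Series([0.1, -0.2, 0.3, 0.4], index=list("abcd"))
        meta = self._meta(scores.index).drop(columns=["response"])
        with pytest.raises(ValidationError):
            ph.export_association_design(scores, meta)
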