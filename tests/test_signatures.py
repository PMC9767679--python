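"""Marker statistics, threshold selection, scoring and grid-search CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from atlaskit import signatures as sg
from atlaskit.data import BulkMatrix
from atlaskit.errors import UnscorableError, ValidationError
from atlaskit.pseudobulk import LOG2_CPM, PseudobulkMatrix


def log2cpm_pb(values, cell_types, genes=None):
    """Build a log2_cpm pseudobulk directly from a group × gene array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    index = pd.Index([f"p{i}|{t}" for i, t in enumerate(cell_types)], name="group")
    groups = pd.DataFrame({
        "patient": [f"p{i}" for i in range(len(cell_types))],
        "cell_type": cell_types,
        "dataset": ["d"] * len(cell_types),
        "n_cells": [20] * len(cell_types),
    }, index=index)
    return PseudobulkMatrix(
        values=pd.DataFrame(values, index=index, columns=genes),
        groups=groups, scale=LOG2_CPM,
    )


def brute_force_auroc(target_vals, other_vals):
    """Pair-counting oracle: P(target > other), ties counted half."""
    wins = sum((t > o) + 0.5 * (t == o)
               for t in target_vals for o in other_vals)
    return wins / (len(target_vals) * len(other_vals))


class TestGeneStats:
    def test_hand_computed_fixture(self):
        # gene column: target {5,6}; type A {1,2}; type B {3,4}
        pb = log2cpm_pb([[5], [6], [1], [2], [3], [4]],
                        ["N", "N", "A", "A", "B", "B"])
        stats = sg.compute_gene_stats(pb, "N").stats
        assert stats.loc["g0", "fc"] == pytest.approx(3.0)   # 5.5 - 2.5
        assert stats.loc["g0", "sfc"] == pytest.approx(2.0)  # 5.5 - 3.5
        assert stats.loc["g0", "auroc"] == pytest.approx(1.0)

    def test_auroc_quarter(self):
        pb = log2cpm_pb([[1], [3], [2], [4]], ["N", "N", "A", "A"])
        stats = sg.compute_gene_stats(pb, "N").stats
        assert stats.loc["g0", "auroc"] == pytest.approx(0.25)

    def test_constant_gene_is_null(self):
        pb = log2cpm_pb([[2.0, 1], [2.0, 2], [2.0, 3], [2.0, 4]],
                        ["N", "N", "A", "A"])
        stats = sg.compute_gene_stats(pb, "N").stats
        assert stats.loc["g0", "fc"] == 0
        assert stats.loc["g0", "sfc"] == 0
        assert stats.loc["g0", "auroc"] == 0.5

    def test_fc_never_below_sfc(self, marker_atlas):
        from atlaskit.pseudobulk import aggregate, normalize_cpm_log2
        ds, _ = marker_atlas
        pbm = normalize_cpm_log2(aggregate(ds, min_cells=10))
        stats = sg.compute_gene_stats(pbm, "type0").stats
        assert (stats["fc"] >= stats["sfc"] - 1e-12).all()
        assert stats["auroc"].between(0, 1).all()

    def test_too_few_groups_rejected(self):
        pb = log2cpm_pb([[1], [2], [3]], ["N", "A", "A"])
        with pytest.raises(ValidationError):
            sg.compute_gene_stats(pb, "N")

    def test_auroc_matches_pair_counting_and_sklearn(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(12, 6))
        values[:, 3] = np.round(values[:, 3])  # force ties
        types = ["N"] * 5 + ["A"] * 4 + ["B"] * 3
        stats = sg.compute_gene_stats(log2cpm_pb(values, types), "N").stats
        is_t = np.array([t == "N" for t in types])
        for j, gene in enumerate(stats.index):
            expected = brute_force_auroc(values[is_t, j], values[~is_t, j])
            assert stats.loc[gene, "auroc"] == pytest.approx(expected)
            assert stats.loc[gene, "auroc"] == pytest.approx(
                roc_auc_score(is_t, values[:, j]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(8, 3))
        types = ["N"] * 4 + ["A"] * 4
        a = sg.compute_gene_stats(log2cpm_pb(values, types), "N").stats["auroc"]
        transformed = np.exp(values) + 2 * values  # strictly monotone
        b = sg.compute_gene_stats(log2cpm_pb(transformed, types), "N").stats["auroc"]
        np.testing.assert_allclose(a, b)


class TestSelectSignature:
    @pytest.fixture
    def stats(self):
        df = pd.DataFrame(
            {"fc": [3.0, 1.4, 0.0], "sfc": [2.0, 0.9, 0.0],
             "auroc": [1.0, 0.8, 0.5]},
            index=["g1", "g2", "g3"],
        )
        return sg.GeneStats(target="N", stats=df)

    def test_permissive_fixture_selects_g1_only(self, stats):
        sig = sg.select_signature(stats, 1.0, 1.5, 0.7)
        assert sig.genes == ["g1"]

    def test_infinite_thresholds_give_empty_signature(self, stats):
        sig = sg.select_signature(stats, np.inf, np.inf, np.inf)
        assert sig.genes == []

    def test_threshold_equality_is_excluded(self, stats):
        # sfc exactly at the cutoff: strict ">" drops the gene
        sig = sg.select_signature(stats, 2.0, 1.5, 0.7)
        assert sig.genes == []

    def test_ranked_by_auroc_then_fc_then_symbol(self):
        df = pd.DataFrame(
            {"fc": [2.0, 3.0, 3.0, 3.0], "sfc": [1.5] * 4,
             "auroc": [0.99, 0.9, 0.9, 0.9]},
            index=["w", "b", "a", "c"],
        )
        sig = sg.select_signature(sg.GeneStats("N", df), 1.0, 1.0, 0.8)
        assert sig.genes == ["w", "a", "b", "c"]
        top = sg.select_signature(sg.GeneStats("N", df), 1.0, 1.0, 0.8, top_n=2)
        assert top.genes == ["w", "a"]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_raising_any_threshold_never_enlarges_selection(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {"fc": rng.normal(1, 1, 30), "sfc": rng.normal(0.5, 1, 30),
             "auroc": rng.uniform(0, 1, 30)},
            index=[f"g{i}" for i in range(30)],
        )
        df["fc"] = np.maximum(df["fc"], df["sfc"])
        stats = sg.GeneStats("N", df)
        base = set(sg.select_signature(stats, 0.5, 0.5, 0.6).genes)
        for thr in [(1.0, 0.5, 0.6), (0.5, 1.0, 0.6), (0.5, 0.5, 0.8)]:
            assert set(sg.select_signature(stats, *thr).genes) <= base


class TestUnionSignature:
    def test_disjoint_18_plus_20_is_38(self):
        a = sg.SignatureSet("TAN", "neutrophil", [f"t{i}" for i in range(18)])
        b = sg.SignatureSet("NAN", "neutrophil", [f"n{i}" for i in range(20)])
        u = sg.union_signature(a, b, "TRN")
        assert len(u) == 38
        assert u.thresholds == "composite"

    def test_idempotent_and_set_semantics(self):
        a = sg.SignatureSet("a", "T", ["x", "y"])
        assert sg.union_signature(a, a, "aa").genes == ["x", "y"]
        b = sg.SignatureSet("b", "T", ["y", "z"])
        assert sg.union_signature(a, b, "ab").genes == ["x", "y", "z"]


class TestScoreSignature:
    def _bulk(self, values, genes):
        return BulkMatrix(values=pd.DataFrame(
            values, index=[f"s{i}" for i in range(len(values))], columns=genes))

    def test_single_gene_two_samples(self):
        bulk = self._bulk([[1.0], [3.0]], ["g1"])
        sig = sg.SignatureSet("s", "T", ["g1"])
        scores = sg.score_signature(bulk, sig)
        np.testing.assert_allclose(scores.to_numpy(), [-1.0, 1.0])

    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(1)
        bulk = self._bulk(rng.lognormal(size=(7, 5)), [f"g{i}" for i in range(5)])
        sig = sg.SignatureSet("s", "T", ["g0", "g2", "g4"])
        assert sg.score_signature(bulk, sig).sum() == pytest.approx(0, abs=1e-9)

    def test_absent_genes_unscorable(self):
        bulk = self._bulk([[1.0], [2.0]], ["g1"])
        with pytest.raises(UnscorableError):
            sg.score_signature(bulk, sg.SignatureSet("s", "T", ["nope"]))
        with pytest.raises(UnscorableError):
            sg.score_signature(bulk, sg.SignatureSet("s", "T", []))

    def test_constant_genes_dropped_then_unscorable(self):
        bulk = self._bulk([[1.0, 5.0], [2.0, 5.0]], ["g1", "g2"])
        sig = sg.SignatureSet("s", "T", ["g1", "g2"])
        scores = sg.score_signature(bulk, sig)  # g2 constant -> dropped
        np.testing.assert_allclose(scores.to_numpy(), [-1.0, 1.0])
        only_const = sg.SignatureSet("s", "T", ["g2"])
        with pytest.raises(UnscorableError):
            sg.score_signature(bulk, only_const)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(6)]
        values = rng.lognormal(size=(5, 6))
        a = sg.score_signature(self._bulk(values, genes),
                               sg.SignatureSet("s", "T", ["g1", "g3", "g5"]))
        perm = [3, 0, 5, 1, 4, 2]
        b = sg.score_signature(
            self._bulk(values[:, perm], [genes[j] for j in perm]),
            sg.SignatureSet("s", "T", ["g5", "g1", "g3"]))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_per_dataset_standardization(self):
        # two cohorts with different baselines: joint z would leak the shift
        values = [[10.0], [12.0], [100.0], [104.0]]
        bulk = self._bulk(values, ["g1"])
        datasets = pd.Series(["a", "a", "b", "b"],
                             index=[f"s{i}" for i in range(4)])
        scores = sg.score_signature(bulk, sg.SignatureSet("s", "T", ["g1"]),
                                    sample_datasets=datasets)
        np.testing.assert_allclose(scores.to_numpy(), [-1, 1, -1, 1])


class TestGridSpec:
    def test_default_grid_has_5000_combinations(self):
        grid = sg.GridSpec.default()
        assert grid.n_combinations == 5000
        assert len(grid.combinations()) == 5000
        assert grid.sfc_grid[0] == 0.5 and grid.sfc_grid[-1] == 2.9
        assert len(grid.auroc_grid) == 8

    def test_combinations_are_lexicographically_ordered(self):
        grid = sg.GridSpec((0.5, 1.0), (0.5, 1.0), (0.7, 0.8))
        combos = grid.combinations()
        assert combos == sorted(combos)
        assert len(combos) == 8

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValidationError):
            sg.GridSpec((1.0, 0.5), (0.5,), (0.7,))
        with pytest.raises(ValidationError):
            sg.GridSpec((), (0.5,), (0.7,))


class TestGridSearchCV:
    def test_recovers_planted_markers(self, marker_atlas):
        ds, gt = marker_atlas
        result, sig = sg.grid_search_cv(ds, "type0", grid=sg.GridSpec.reduced(),
                                        seed=3)
        planted = set(gt.markers["type0"])
        got = set(sig.genes)
        assert got, "signature should not be empty on planted-marker data"
        precision = len(got & planted) / len(got)
        recall = len(got & planted) / len(planted)
        assert precision >= 0.9
        assert recall >= 0.9
        assert result.test_r >= 0.9
        assert len(result.table) == sg.GridSpec.reduced().n_combinations
        assert result.best_combination in [tuple(c) for c in
                                           sg.GridSpec.reduced().combinations()]

    def test_singleton_grid_trivially_chosen(self, marker_atlas):
        ds, _ = marker_atlas
        grid = sg.GridSpec((1.0,), (1.5,), (0.9,))
        result, sig = sg.grid_search_cv(ds, "type0", grid=grid, seed=0)
        assert result.best_combination == (1.0, 1.5, 0.9)
        assert len(result.table) == 1
        assert sig.thresholds == (1.0, 1.5, 0.9)

    def test_deterministic_under_fixed_seed(self, marker_atlas):
        ds, _ = marker_atlas
        grid = sg.GridSpec((1.0, 1.5), (1.0, 1.5), (0.8,))
        r1, s1 = sg.grid_search_cv(ds, "type1", grid=grid, seed=11)
        r2, s2 = sg.grid_search_cv(ds, "type1", grid=grid, seed=11)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert s1.genes == s2.genes
        assert r1.test_r == r2.test_r

    def test_too_few_training_patients_rejected(self):
        from conftest import make_dataset
        ds = make_dataset(np.ones((8, 3), dtype=int),
                          patients=[f"p{i}" for i in range(8)] ,
                          cell_types=["T", "B"] * 4)
        with pytest.raises(ValidationError):
            sg.grid_search_cv(ds, "T", grid=sg.GridSpec((1.0,), (1.0,), (0.8,)),
                              folds=5, seed=0)
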