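"""Differential co-expression: correlation matrices, profiles, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from conftest import make_zscored
from _oracles import best_leaf_order_cost, profile_corr_leave_two_out
from signalome.diffcoexpr import (
    DiffCoexprError,
    cluster_profiles,
    condition_correlations,
    differential_matrix,
    leaf_order_objective,
    profile_correlations,
    semantic_validation,
)


def group_labels(sample_ids, n_first):
    return pd.Series(
        ["control"] * n_first + ["disease"] * (len(sample_ids) - n_first), index=sample_ids
    )


def sym_frame(A, ids=None):
    ids = ids or [f"P{i}" for i in range(A.shape[0])]
    return pd.DataFrame(A, index=ids, columns=ids)


class TestConditionCorrelations:
    def test_unit_diagonal_and_duplicate_rank_order(self, rng):
        X = rng.normal(size=(5, 24))
        X[1] = np.exp(X[0])  # identical rank order as protein 0
        mat = make_zscored(X)
        mats = condition_correlations(mat, group_labels(mat.sample_ids, 12))
        for C in (mats.c_ctrl, mats.c_dis):
            assert np.allclose(np.diag(C), 1.0)
            assert C.iloc[0, 1] == pytest.approx(1.0)
            assert np.allclose(C, C.T)

    def test_matches_pairwise_oracle(self, rng):
        X = rng.normal(size=(6, 24))
        mat = make_zscored(X)
        labels = group_labels(mat.sample_ids, 12)
        mats = condition_correlations(mat, labels)
        Xc = mat.values.to_numpy()[:, :12]
        for i in range(6):
            for j in range(6):
                expected = stats.spearmanr(Xc[i], Xc[j]).statistic
                assert mats.c_ctrl.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_small_group_rejected(self, rng):
        mat = make_zscored(rng.normal(size=(4, 8)))
        with pytest.raises(DiffCoexprError, match=">= 5"):
            condition_correlations(mat, group_labels(mat.sample_ids, 4))


class TestDifferentialMatrix:
    def test_identical_groups_give_zero(self, rng):
        C = sym_frame(np.corrcoef(rng.normal(size=(5, 30))))
        D = differential_matrix(C, C.copy())
        assert np.allclose(D, 0.0)

    def test_antisymmetric_under_condition_swap(self, rng):
        A = sym_frame(np.corrcoef(rng.normal(size=(5, 30))))
        B = sym_frame(np.corrcoef(rng.normal(size=(5, 30))))
        assert np.allclose(differential_matrix(A, B), -differential_matrix(B, A))

    def test_entry_arithmetic(self):
        ids = list("abcd")
        C1 = sym_frame(np.eye(4), ids)
        C2 = sym_frame(np.eye(4), ids)
        C1.iloc[0, 1] = C1.iloc[1, 0] = -0.8
        C2.iloc[0, 1] = C2.iloc[1, 0] = 0.8
        D = differential_matrix(C1, C2)
        assert D.iloc[0, 1] == pytest.approx(1.6)
        assert np.allclose(np.diag(D), 0.0)

    def test_label_mismatch_rejected(self, rng):
        A = sym_frame(np.eye(4), list("abcd"))
        B = sym_frame(np.eye(4), list("abce"))
        with pytest.raises(DiffCoexprError, match="different protein"):
            differential_matrix(A, B)


class TestProfileCorrelations:
    def test_matches_leave_two_out_oracle(self, rng):
        A = rng.normal(size=(9, 9))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        R = profile_correlations(sym_frame(A))
        for i in range(9):
            for j in range(i + 1, 9):
                assert R.iloc[i, j] == pytest.approx(
                    profile_corr_leave_two_out(A, i, j), abs=1e-12
                )

    def test_duplicated_proteins_have_unit_profile_correlation(self, rng):
        X = rng.normal(size=(8, 40))
        X[1] = X[0] + 1e-9 * rng.normal(size=40)  # effectively duplicated protein
        mat = make_zscored(X)
        mats = condition_correlations(mat, group_labels(mat.sample_ids, 20))
        R = profile_correlations(mats.d)
        assert R.iloc[0, 1] > 0.999

    def test_zero_differential_matrix_is_an_error(self):
        with pytest.raises(DiffCoexprError, match="zero-variance"):
            profile_correlations(sym_frame(np.zeros((6, 6))))

    def test_invariant_to_condition_relabeling(self, rng):
        A = rng.normal(size=(7, 7))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        R_pos = profile_correlations(sym_frame(A))
        R_neg = profile_correlations(sym_frame(-A))
        assert np.allclose(R_pos, R_neg, atol=1e-12)


class TestChainInvariances:
    def test_invariant_to_sample_order_and_monotone_transforms(self, rng):
        X = rng.normal(size=(6, 30))
        ids = [f"S{j:02d}" for j in range(30)]
        mat = make_zscored(X, sample_ids=ids)
        labels = group_labels(ids, 15)
        D1 = condition_correlations(mat, labels).d

        perm = rng.permutation(30)
        mat2 = make_zscored(X[:, perm], sample_ids=[ids[i] for i in perm])
        D2 = condition_correlations(mat2, labels).d
        assert np.allclose(D1, D2, atol=1e-12)

        # monotone transform per protein per condition leaves ranks intact
        X3 = X.copy()
        X3[2, :15] = np.exp(X3[2, :15])
        X3[4, 15:] = X3[4, 15:] ** 3
        D3 = condition_correlations(make_zscored(X3, sample_ids=ids), labels).d
        assert np.allclose(D1, D3, atol=1e-12)


class TestClusterProfiles:
    def test_k_equals_n_gives_singletons(self, rng):
        A = np.corrcoef(rng.normal(size=(6, 50)))
        cl = cluster_profiles(sym_frame(A), k=6)
        assert sorted(cl.labels) == [1, 2, 3, 4, 5, 6]

    def test_k_out_of_range_rejected(self, rng):
        A = np.corrcoef(rng.normal(size=(4, 20)))
        with pytest.raises(DiffCoexprError):
            cluster_profiles(sym_frame(A), k=5)

    def test_clusters_contiguous_in_leaf_order(self, rng):
        A = np.corrcoef(rng.normal(size=(20, 15)))
        cl = cluster_profiles(sym_frame(A), k=4)
        seq = [cl.labels[p] for p in cl.leaf_order]
        changes = sum(a != b for a, b in zip(seq, seq[1:]))
        assert changes == len(set(seq)) - 1

    @pytest.mark.parametrize("n", [5, 7, 8])
    def test_optimal_leaf_ordering_matches_enumeration(self, n, rng):
        A = np.corrcoef(rng.normal(size=(n, 25)))
        R = sym_frame(A)
        cl = cluster_profiles(R, k=2)
        dist = 1.0 - A
        np.fill_diagonal(dist, 0.0)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        best = best_leaf_order_cost(Z, dist)
        idx = [R.index.get_loc(p) for p in cl.leaf_order]
        achieved = sum(dist[idx[i], idx[i + 1]] for i in range(n - 1))
        assert achieved == pytest.approx(best, abs=1e-12)
        # equivalent statement on the similarity objective
        assert leaf_order_objective(R, cl.leaf_order) == pytest.approx(
            (n - 1) - best, abs=1e-12
        )


class TestSemanticValidation:
    def planted(self, rng, n=40, module=12):
        """R with a hot block and S rewarding exactly that block."""
        ids = [f"P{i}" for i in range(n)]
        R = np.full((n, n), 0.0)
        R[:module, :module] = 0.8
        R += rng.normal(0, 0.05, size=(n, n))
        R = np.clip((R + R.T) / 2, -1, 1)
        np.fill_diagonal(R, 1.0)
        S = np.full((n, n), 0.2)
        S[:module, :module] = 0.8
        np.fill_diagonal(S, 1.0)
        return sym_frame(R, ids), sym_frame(S, ids)

    def test_planted_module_similarity_detected(self, rng):
        R, S = self.planted(rng)
        out = semantic_validation(R, S, r_threshold=0.35, n_perm=2000, seed=1)
        assert out["p"] < 0.01
        assert out["observed_median"] == pytest.approx(0.8)

    def test_constant_similarity_is_never_significant(self, rng):
        R, S = self.planted(rng)
        S.iloc[:, :] = 0.5
        out = semantic_validation(R, S, r_threshold=0.35, n_perm=500, seed=2)
        assert out["p"] > 0.5

    def test_threshold_below_all_pairs_selects_everything(self, rng):
        R, S = self.planted(rng)
        out = semantic_validation(R, S, r_threshold=-1.0, n_perm=200, seed=3)
        n = R.shape[0]
        assert out["n_pairs_selected"] == n * (n - 1) // 2
        assert out["p"] > 0.5  # null draws are the observed set itself

    def test_no_pairs_above_threshold_is_an_error(self, rng):
        R, S = self.planted(rng)
        with pytest.raises(DiffCoexprError, match="no pairs"):
            semantic_validation(R, S, r_threshold=0.999, n_perm=100, seed=4)
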