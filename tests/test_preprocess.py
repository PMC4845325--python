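"""Preprocessing chain: background subtraction through Z-scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from signalome.preprocess import (
    ExpressionMatrix,
    PreprocessConfig,
    PreprocessError,
    filter_antibodies,
    iterative_median_polish,
    log2_replicate_average,
    pca_confounders,
    preprocess_cohort,
    replace_nd,
    subtract_background,
    to_replicate_matrix,
    zscore_rows,
)


def spot_table(rows):
    return pd.DataFrame(rows, columns=["array_id", "antibody_id", "replicate_index", "foreground", "background"])


class TestSubtractBackground:
    @pytest.mark.parametrize(
        "foregrounds,backgrounds,expect_net,expect_nd",
        [
            # B = median{100,100,100} = 100; 200 >= 1.1*100 -> detected
            ([200, 200, 200], [100, 100, 100], [100, 100, 100], [False] * 3),
            # foreground equal to background: 0% above -> ND
            ([100, 100, 100], [100, 100, 100], [0, 0, 0], [True] * 3),
            # 4% above background is below the 10% margin -> ND
            ([104, 104, 104], [100, 100, 100], [4, 4, 4], [True] * 3),
        ],
    )
    def test_margin_rule(self, foregrounds, backgrounds, expect_net, expect_nd):
        spots = spot_table(
            [("a1", "ab1", i + 1, f, b) for i, (f, b) in enumerate(zip(foregrounds, backgrounds))]
        )
        out = subtract_background(spots)
        assert out["net"].tolist() == expect_net
        assert out["nd"].tolist() == expect_nd

    def test_zero_background_degenerate_rule(self):
        spots = spot_table([("a1", "ab1", 1, 0.0, 0.0), ("a1", "ab1", 2, 5.0, 0.0)])
        out = subtract_background(spots)
        # B = 0: ND iff foreground <= 0
        assert out["nd"].tolist() == [True, False]

    def test_negative_intensity_rejected(self):
        spots = spot_table([("a1", "ab1", 1, -5.0, 10.0)])
        with pytest.raises(PreprocessError, match="negative"):
            subtract_background(spots)

    def test_duplicate_spot_key_rejected(self):
        spots = spot_table([("a1", "ab1", 1, 10, 1), ("a1", "ab1", 1, 11, 1)])
        with pytest.raises(PreprocessError, match="duplicate"):
            subtract_background(spots)


def matrix_with_nd(nd_frac_per_antibody: dict[str, float], n_spots: int = 100) -> ExpressionMatrix:
    """Replicate-level matrix with an exact ND fraction per antibody."""
    rows = []
    for ab, frac in nd_frac_per_antibody.items():
        n_nd = int(round(frac * n_spots))
        for i in range(n_spots):
            nd = i < n_nd
            fg = 100.0 if nd else 500.0
            rows.append((f"s{i}", ab, 1, fg, 100.0))
    return to_replicate_matrix(subtract_background(spot_table(rows)))


class TestFilterAntibodies:
    def test_strict_55_percent_boundary(self):
        mat = matrix_with_nd({"ab_56": 0.56, "ab_55": 0.55, "ab_00": 0.0})
        out, log = filter_antibodies(mat)
        assert set(out.antibody_ids) == {"ab_55", "ab_00"}
        assert log.loc["ab_56", "dropped"]
        assert log.loc["ab_56", "nd_frac"] == pytest.approx(0.56)

    def test_idempotent(self):
        mat = matrix_with_nd({"a": 0.6, "b": 0.2, "c": 0.0})
        once, _ = filter_antibodies(mat)
        twice, _ = filter_antibodies(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_removed_is_error(self):
        mat = matrix_with_nd({"a": 0.9, "b": 1.0})
        with pytest.raises(PreprocessError, match="ND"):
            filter_antibodies(mat)


class TestReplaceNd:
    def build(self, sample_reps: dict[str, list], nd_flags: dict[str, list]):
        """Matrix for one antibody given per-sample replicate nets and ND flags."""
        rows = []
        for s, reps in sample_reps.items():
            for i, v in enumerate(reps):
                rows.append((s, "ab1", i + 1, v))
        df = spot_table([(a, b, r, 0, 0) for a, b, r, _ in rows])
        df["net"] = [v for *_, v in rows]
        df["nd"] = [nd_flags[a][r - 1] for a, _, r, _ in rows]
        return to_replicate_matrix(df)

    def test_partial_nd_uses_half_sample_minimum(self):
        # replicates {ND, 8, 12}; antibody minimum across samples 6
        mat = self.build(
            {"s1": [2.0, 8.0, 12.0], "s2": [6.0, 9.0, 20.0]},
            {"s1": [True, False, False], "s2": [False, False, False]},
        )
        out = replace_nd(mat)
        assert out.values.loc["ab1", ("s1", 1)] == pytest.approx(4.0)  # max(4, 3, 1)
        assert out.stage == "imputed"

    def test_all_nd_sample_falls_back_to_half_global_minimum(self):
        mat = self.build(
            {"s1": [2.0, 2.5, 3.0], "s2": [6.0, 9.0, 20.0]},
            {"s1": [True, True, True], "s2": [False, False, False]},
        )
        out = replace_nd(mat)
        # global non-ND minimum is 6 -> max(-, 3, 1) = 3 for every s1 replicate
        assert out.values.loc["ab1", "s1"].tolist() == [3.0, 3.0, 3.0]

    def test_nd_everywhere_hits_floor(self):
        mat = self.build(
            {"s1": [0.5, 0.2, 0.1], "s2": [0.0, 0.3, 0.4]},
            {"s1": [True] * 3, "s2": [True] * 3},
        )
        out = replace_nd(mat)
        assert (out.values.loc["ab1"] == 1.0).all()

    def test_non_nd_untouched_and_floor_respected(self, rng):
        nets = rng.uniform(2, 50, size=(1, 12))
        nd = rng.random((1, 12)) < 0.4
        rows = []
        for j in range(12):
            rows.append((f"s{j // 3}", "ab1", j % 3 + 1, 0, 0))
        df = spot_table(rows)
        df["net"] = nets.ravel()
        df["nd"] = nd.ravel()
        mat = to_replicate_matrix(df)
        out = replace_nd(mat)
        vals = out.values.to_numpy().ravel()
        orig = mat.values.to_numpy().ravel()
        ndm = mat.nd_mask.to_numpy().ravel()
        assert np.array_equal(vals[~ndm], orig[~ndm])
        assert (vals[ndm] >= 1.0).all()


class TestLog2ReplicateAverage:
    def test_simple_cases(self):
        rows = [("s1", "ab1", 1, 0, 0), ("s1", "ab1", 2, 0, 0), ("s2", "ab1", 1, 0, 0), ("s2", "ab1", 2, 0, 0)]
        df = spot_table(rows)
        df["net"] = [4.0, 4.0, 2.0, 8.0]
        df["nd"] = False
        mat = to_replicate_matrix(df)
        mat.stage = "imputed"
        out = log2_replicate_average(mat)
        assert out.values.loc["ab1", "s1"] == pytest.approx(2.0)  # log2(4)
        assert out.values.loc["ab1", "s2"] == pytest.approx(2.0)  # (1+3)/2

    def test_matches_brute_force_mean_of_logs(self, rng):
        reps = rng.uniform(1, 100, size=9)
        rows = [(f"s{j // 3}", "ab1", j % 3 + 1, 0, 0) for j in range(9)]
        df = spot_table(rows)
        df["net"] = reps
        df["nd"] = False
        mat = to_replicate_matrix(df)
        mat.stage = "imputed"
        out = log2_replicate_average(mat)
        for s in range(3):
            expected = np.mean([np.log2(v) for v in reps[3 * s : 3 * s + 3]])
            assert out.values.loc["ab1", f"s{s}"] == pytest.approx(expected, abs=1e-12)

    def test_non_positive_rejected(self):
        df = spot_table([("s1", "ab1", 1, 0, 0)])
        df["net"] = [-1.0]
        df["nd"] = False
        mat = to_replicate_matrix(df)
        mat.stage = "imputed"
        with pytest.raises(PreprocessError, match="non-positive"):
            log2_replicate_average(mat)


def as_log2_matrix(X: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame(
            X,
            index=[f"ab{i}" for i in range(X.shape[0])],
            columns=[f"s{j}" for j in range(X.shape[1])],
        ),
        stage="log2_averaged",
    )


class TestMedianPolish:
    def test_fixed_point_returned_unchanged(self, rng):
        X = rng.normal(size=(21, 13))
        polished, _ = iterative_median_polish(as_log2_matrix(X))
        again, _ = iterative_median_polish(
            ExpressionMatrix(values=polished.values, stage="log2_averaged")
        )
        assert np.allclose(polished.values, again.values, atol=1e-9)

    @pytest.mark.parametrize("shape", [(20, 12), (5, 5), (40, 7)])
    def test_postconditions_on_random_input(self, shape, rng):
        X = rng.normal(2.0, 3.0, size=shape)
        out, log = iterative_median_polish(as_log2_matrix(X))
        V = out.values.to_numpy()
        assert np.abs(np.median(V, axis=1)).max() < 1e-6
        assert np.abs(np.median(V, axis=0)).max() < 1e-6
        assert np.abs((V**2).sum(axis=1) / shape[1] - 1).max() < 1e-6
        assert np.abs((V**2).sum(axis=0) / shape[0] - 1).max() < 1e-6
        assert len(log) >= 50

    def test_invariant_to_row_shift(self, rng):
        X = rng.normal(size=(15, 10))
        shifted = X.copy()
        shifted[3] += 7.5
        a, _ = iterative_median_polish(as_log2_matrix(X))
        b, _ = iterative_median_polish(as_log2_matrix(shifted))
        assert np.allclose(a.values, b.values, atol=1e-8)

    def test_constant_row_rejected(self, rng):
        X = rng.normal(size=(6, 6))
        X[2] = 3.0
        with pytest.raises(PreprocessError, match="constant row"):
            iterative_median_polish(as_log2_matrix(X))


class TestZscoreRows:
    def test_closed_form(self):
        mat = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["ab1"], columns=["a", "b", "c"]),
            stage="polished",
        )
        out = zscore_rows(mat)
        assert np.allclose(out.values.to_numpy()[0], [-1.224744871, 0.0, 1.224744871])

    def test_shift_and_scale_invariance(self, rng):
        X = rng.normal(size=(4, 9))
        base = zscore_rows(ExpressionMatrix(values=as_log2_matrix(X).values, stage="polished"))
        trans = zscore_rows(
            ExpressionMatrix(values=as_log2_matrix(3.7 * X + 11.0).values, stage="polished")
        )
        assert np.allclose(base.values, trans.values, atol=1e-10)

    def test_zero_sd_rejected(self):
        mat = ExpressionMatrix(
            values=pd.DataFrame([[2.0, 2.0, 2.0]], index=["ab1"], columns=["a", "b", "c"]),
            stage="polished",
        )
        with pytest.raises(PreprocessError, match="zero-SD"):
            zscore_rows(mat)


class TestEndToEnd:
    def test_deterministic_rerun(self, small_cohort):
        m1, qc1 = preprocess_cohort(small_cohort.spots)
        m2, qc2 = preprocess_cohort(small_cohort.spots)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert qc1["nd_fractions"] == qc2["nd_fractions"]

    def test_zscore_invariants_hold(self, small_matrix):
        V = small_matrix.values.to_numpy()
        assert np.abs(V.mean(axis=1)).max() < 1e-8
        assert np.abs(V.std(axis=1, ddof=0) - 1).max() < 1e-6


class TestPcaConfounders:
    def test_varexp_monotone_and_bounded(self, small_matrix, small_cohort):
        out = pca_confounders(small_matrix, small_cohort.meta, n_components=4)
        v = out["varexp"].to_numpy()
        assert (np.diff(v) <= 1e-12).all()
        assert v.sum() <= 1.0 + 1e-9

    def test_planted_batch_effect_detected(self, rng):
        # half the samples shifted on every protein: PC1 must track the batch
        X = rng.normal(size=(60, 30))
        batch = np.array(["one"] * 15 + ["two"] * 15)
        X[:, batch == "two"] += 2.0
        mat = ExpressionMatrix(
            values=pd.DataFrame(
                (X - X.mean(1, keepdims=True)) / X.std(1, ddof=0, keepdims=True),
                index=[f"ab{i}" for i in range(60)],
                columns=[f"s{j}" for j in range(30)],
            ),
            stage="zscored",
        )
        meta = pd.DataFrame({"sample_id": [f"s{j}" for j in range(30)], "center": batch})
        out = pca_confounders(mat, meta, n_components=2, categorical=("center",), continuous=())
        assert out["assoc_p"].loc["PC1", "center"] < 0.01

    def test_too_many_components_rejected(self, small_matrix, small_cohort):
        with pytest.raises(PreprocessError, match="n_components"):
            pca_confounders(small_matrix, small_cohort.meta, n_components=10_000)
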