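"""Preprocessing stack against independently coded brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from metamced import (FeatureMatrix, default_pseudocount, filter_features,
                      knn_impute, knn_transform, log10_transform,
                      preprocess_cdai_apply, preprocess_cdai_fit,
                      preprocess_tooai_apply, preprocess_tooai_fit,
                      quantile_apply, quantile_apply_matrix, quantile_fit,
                      scale_apply, scale_fit)
from metamced.preprocess import QuantileReference

from conftest import random_matrix


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the implementation
# ---------------------------------------------------------------------------

def oracle_quantile_fit(X: np.ndarray) -> np.ndarray:
    """Sort each complete row; average position-wise."""
    return np.mean(np.sort(X, axis=1), axis=0)


def oracle_quantile_apply(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Tie-averaged rank substitution, complete vectors only."""
    out = np.empty_like(v, dtype=float)
    order = np.argsort(v, kind="stable")
    # average ranks for ties
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0  # 0-based average rank
        i = j + 1
    for idx in range(len(v)):
        pos = ranks[idx] / (len(v) - 1)
        # linear interpolation over the reference grid
        x = pos * (len(ref) - 1)
        lo = int(np.floor(x))
        hi = min(lo + 1, len(ref) - 1)
        out[idx] = ref[lo] + (x - lo) * (ref[hi] - ref[lo])
    return out


def oracle_knn_impute(X: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive loop version: RMS distance over mutual features, mean of
    the k nearest donors that observe the target feature."""
    n, p = X.shape
    out = X.copy()
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                dists.append(np.inf)
                continue
            mutual = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if not mutual.any():
                dists.append(np.inf)
            else:
                diff = X[i, mutual] - X[j, mutual]
                dists.append(np.sqrt(np.mean(diff ** 2)))
        for f in range(p):
            if np.isnan(X[i, f]):
                donors = [(dists[j], j) for j in range(n)
                          if not np.isnan(X[j, f]) and np.isfinite(dists[j])]
                donors.sort()
                chosen = donors[:k]
                if chosen:
                    out[i, f] = np.mean([X[j, f] for _, j in chosen])
    return out


def oracle_scale(X: np.ndarray):
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    return mu, sd


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilter:
    def test_absent_feature_removed(self):
        m = random_matrix(5, 3, seed=1)
        m.intensities["F1"] = np.nan
        # an all-missing column would trip the row check only if a row were
        # empty; here rows keep observed cells
        filtered, removed = filter_features(m, 0.1)
        assert removed == ["F1"]

    def test_zero_threshold_is_identity(self):
        m = random_matrix(4, 4, missing_rate=0.3, seed=2)
        filtered, removed = filter_features(m, 0.0)
        assert removed == []
        assert filtered.feature_ids == m.feature_ids

    def test_prevalence_counted_by_hand(self):
        X = np.full((10, 3), 1.0)
        X[4:, 0] = np.nan            # feature F0 present in 4/10 samples
        m = FeatureMatrix.from_arrays(X, [f"S{i}" for i in range(10)],
                                      ["F0", "F1", "F2"], ["a"] * 10)
        filtered, removed = filter_features(m, 0.5)
        assert removed == ["F0"]
        assert filtered.feature_ids == ["F1", "F2"]

    def test_removing_everything_is_an_error(self):
        m = random_matrix(3, 2, seed=3)
        m.intensities.iloc[:, :] = np.nan
        m.intensities.iloc[0, 0] = 1.0
        with pytest.raises(RuntimeError):
            filter_features(m, 1.0)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantile:
    def test_identical_samples_give_their_sorted_vector(self):
        X = np.array([[3.0, 1.0, 2.0], [3.0, 1.0, 2.0]])
        ref = quantile_fit(pd.DataFrame(X))
        np.testing.assert_allclose(ref.reference_quantiles, [1.0, 2.0, 3.0])

    def test_positionwise_means(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        ref = quantile_fit(pd.DataFrame(X))
        np.testing.assert_allclose(ref.reference_quantiles, [2.5, 3.5, 4.5])

    def test_fit_matches_sort_average_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 50, size=(5, 4))
        ref = quantile_fit(pd.DataFrame(X))
        np.testing.assert_allclose(ref.reference_quantiles,
                                   oracle_quantile_fit(X), rtol=1e-12)

    def test_apply_rank_substitution(self):
        ref = QuantileReference(np.array([2.5, 3.5, 4.5]), 3)
        out = quantile_apply(np.array([9.0, 7.0, 8.0]), ref)
        np.testing.assert_allclose(out, [4.5, 2.5, 3.5])

    def test_apply_leaves_reference_distributed_sample_unchanged(self):
        ref = QuantileReference(np.array([1.0, 4.0, 9.0]), 3)
        out = quantile_apply(np.array([4.0, 9.0, 1.0]), ref)
        np.testing.assert_allclose(out, [4.0, 9.0, 1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_apply_matches_tie_averaged_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = QuantileReference(np.sort(rng.uniform(0, 100, 8)), 8)
        v = rng.integers(0, 5, size=8).astype(float)  # heavy ties
        np.testing.assert_allclose(quantile_apply(v, ref),
                                   oracle_quantile_apply(v, ref.reference_quantiles),
                                   rtol=1e-12)

    def test_apply_is_idempotent(self):
        rng = np.random.default_rng(9)
        ref = QuantileReference(np.sort(rng.uniform(0, 10, 12)), 12)
        v = rng.uniform(0, 1, size=12)
        once = quantile_apply(v, ref)
        twice = quantile_apply(once, ref)
        np.testing.assert_allclose(once, twice, rtol=1e-12)

    def test_missing_cells_stay_missing(self):
        ref = QuantileReference(np.array([1.0, 2.0, 3.0, 4.0]), 4)
        v = np.array([5.0, np.nan, 7.0, 6.0])
        out = quantile_apply(v, ref)
        assert np.isnan(out[1])
        # observed values span the full reference range by rank
        np.testing.assert_allclose(out[~np.isnan(v)], [1.0, 4.0, 2.5])

    def test_all_missing_vector_rejected(self):
        ref = QuantileReference(np.array([1.0, 2.0]), 2)
        with pytest.raises(ValueError):
            quantile_apply(np.array([np.nan, np.nan]), ref)

    def test_training_sample_reproduces_pooled_normalization(self):
        """Applying after fit reproduces classic pooled quantile
        normalization for a complete, tie-free training sample."""
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 100, size=(6, 9))
        ref = quantile_fit(pd.DataFrame(X))
        classic = np.empty_like(X)
        ranks = np.argsort(np.argsort(X, axis=1), axis=1)
        classic = ref.reference_quantiles[ranks]
        for i in range(X.shape[0]):
            np.testing.assert_allclose(quantile_apply(X[i], ref), classic[i],
                                       rtol=1e-12)


# ---------------------------------------------------------------------------
# log transform and scaling
# ---------------------------------------------------------------------------

class TestLogAndScale:
    def test_log10_known_values(self):
        m = FeatureMatrix.from_arrays([[1000.0, 0.0]], ["S0"], ["F0", "F1"],
                                      ["a"])
        out = log10_transform(m, pseudocount=0.0).intensities
        assert out.loc["S0", "F0"] == pytest.approx(3.0)
        out1 = log10_transform(m, pseudocount=1.0).intensities
        assert out1.loc["S0", "F1"] == pytest.approx(0.0)

    def test_log10_round_trip_12_digits(self):
        m = random_matrix(4, 5, seed=13)
        pc = 0.7
        logged = log10_transform(m, pc).intensities.to_numpy()
        back = 10.0 ** logged - pc
        np.testing.assert_allclose(back, m.intensities.to_numpy(), rtol=1e-12)

    def test_negative_intensity_rejected(self):
        m = FeatureMatrix.from_arrays([[-1.0]], ["S0"], ["F0"], ["a"])
        with pytest.raises(ValueError):
            log10_transform(m, 1.0)

    def test_default_pseudocount_is_half_min_nonzero(self):
        m = FeatureMatrix.from_arrays([[0.0, 4.0], [8.0, 2.0]],
                                      ["S0", "S1"], ["F0", "F1"], ["a", "b"])
        assert default_pseudocount(m) == pytest.approx(1.0)

    def test_scaled_training_matrix_has_zero_mean_unit_sd(self):
        m = random_matrix(8, 4, seed=17)
        state = scale_fit(m)
        out = scale_apply(m, state).intensities
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=0), 1.0, rtol=1e-12)

    def test_constant_feature_flagged_and_centered(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        m = FeatureMatrix.from_arrays(X, ["S0", "S1", "S2"], ["F0", "F1"],
                                      ["a"] * 3)
        state = scale_fit(m)
        assert state.zero_variance == ["F0"]
        out = scale_apply(m, state).intensities
        np.testing.assert_allclose(out["F0"], 0.0)

    def test_held_out_application_matches_hand_computation(self):
        train = random_matrix(6, 3, seed=19)
        test = random_matrix(4, 3, seed=23)
        mu, sd = oracle_scale(train.intensities.to_numpy())
        state = scale_fit(train)
        out = scale_apply(test, state).intensities.to_numpy()
        want = (test.intensities.to_numpy() - mu) / sd
        np.testing.assert_allclose(out, want, rtol=1e-12)

    def test_unknown_feature_rejected_at_apply(self):
        state = scale_fit(random_matrix(4, 2, seed=1))
        other = random_matrix(2, 3, seed=2)
        with pytest.raises(ValueError):
            scale_apply(other, state)


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

class TestKNNImpute:
    def test_complete_matrix_is_identity_under_both_policies(self):
        m = random_matrix(5, 4, seed=29)
        for policy in ("uniform", "selective"):
            out = knn_impute(m, k=3, policy=policy)
            pd.testing.assert_frame_equal(out.intensities, m.intensities)

    def test_three_row_toy_mean_of_two_nearest(self):
        X = np.array([[1.0, 10.0], [1.1, 20.0], [9.0, 30.0]])
        X[0, 1] = np.nan
        m = FeatureMatrix.from_arrays(X, ["S0", "S1", "S2"], ["F0", "F1"],
                                      ["a"] * 3)
        out = knn_impute(m, k=2, policy="uniform").intensities
        # nearest rows to S0 on F0: S1 (d=0.1), S2 (d=8) -> mean(20, 30)
        assert out.loc["S0", "F1"] == pytest.approx(25.0)
        np.testing.assert_allclose(out.to_numpy(), oracle_knn_impute(X, 2),
                                   rtol=1e-12)

    @pytest.mark.parametrize("seed,k", [(0, 1), (1, 3), (2, 5)])
    def test_matches_exhaustive_oracle_on_random_toys(self, seed, k):
        m = random_matrix(10, 8, missing_rate=0.25, seed=seed)
        out = knn_impute(m, k=k, policy="uniform").intensities.to_numpy()
        want = oracle_knn_impute(m.intensities.to_numpy(), k)
        np.testing.assert_allclose(out, want, rtol=1e-12)

    def test_observed_cells_never_altered(self):
        m = random_matrix(8, 6, missing_rate=0.3, seed=31)
        observed = ~m.missing_mask
        out = knn_impute(m, k=3, policy="uniform")
        before = m.intensities.to_numpy()[observed.to_numpy()]
        after = out.intensities.to_numpy()[observed.to_numpy()]
        np.testing.assert_array_equal(before, after)

    def test_selective_policy_leaves_test_rows_untouched(self):
        m = random_matrix(8, 5, missing_rate=0.3, seed=37)
        test_ids = ["S6", "S7"]
        out = knn_impute(m, k=2, policy="selective", test_samples=test_ids)
        pd.testing.assert_frame_equal(out.intensities.loc[test_ids],
                                      m.intensities.loc[test_ids])
        # training rows are imputed
        train_ids = [s for s in m.sample_ids if s not in test_ids]
        assert not out.intensities.loc[train_ids].isna().any().any()

    def test_selective_policy_uses_same_class_donors_only(self):
        # class 'a' rows share F1 near 10, class 'b' near 99; the imputed
        # 'a' cell must come from 'a' donors
        X = np.array([[1.0, np.nan], [1.2, 10.0], [1.1, 12.0],
                      [1.05, 99.0], [0.95, 101.0]])
        m = FeatureMatrix.from_arrays(X, [f"S{i}" for i in range(5)],
                                      ["F0", "F1"],
                                      ["a", "a", "a", "b", "b"])
        out = knn_impute(m, k=2, policy="selective").intensities
        assert out.loc["S0", "F1"] == pytest.approx(11.0)

    def test_empty_row_rejected(self):
        X = np.array([[np.nan, np.nan], [1.0, 2.0]])
        m = FeatureMatrix.from_arrays(X, ["S0", "S1"], ["F0", "F1"],
                                      ["a", "a"])
        with pytest.raises(ValueError):
            knn_impute(m, k=1)

    def test_transform_uses_training_donors_only(self):
        train = pd.DataFrame([[0.0, 5.0], [0.2, 7.0], [10.0, 100.0]],
                             columns=["F0", "F1"])
        target = pd.DataFrame([[0.1, np.nan]], columns=["F0", "F1"])
        out = knn_transform(train, target, k=2)
        assert out.iloc[0, 1] == pytest.approx(6.0)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

class TestRecipes:
    def test_cdai_recipe_round_trip(self, small_matrix):
        labels = small_matrix.labels
        train_ids = small_matrix.sample_ids[::2]
        test_ids = small_matrix.sample_ids[1::2]
        train = small_matrix.select_samples(train_ids)
        test = small_matrix.select_samples(test_ids)
        state, train_proc = preprocess_cdai_fit(train)
        assert not train_proc.intensities.isna().any().any()
        test_proc = preprocess_cdai_apply(state, test)
        assert test_proc.feature_ids == state.feature_ids
        assert not test_proc.intensities.isna().any().any()

    def test_tooai_recipe_keeps_test_non_imputed(self, small_matrix):
        train = small_matrix.select_samples(small_matrix.sample_ids[::2])
        test = small_matrix.select_samples(small_matrix.sample_ids[1::2])
        state, train_proc = preprocess_tooai_fit(train)
        test_proc = preprocess_tooai_apply(state, test)
        # test missing cells survive the recipe (scored as 0 downstream)
        n_missing_in = int(test.intensities.reindex(
            columns=state.feature_ids).isna().sum().sum())
        n_missing_out = int(test_proc.intensities.isna().sum().sum())
        assert n_missing_out == n_missing_in
        # training rows of each class are complete wherever donors existed
        assert train_proc.intensities.isna().sum().sum() \
            <= train.intensities.isna().sum().sum()

    def test_fit_steps_see_training_rows_only(self, small_matrix):
        """Changing test rows must not change any fitted state."""
        train = small_matrix.select_samples(small_matrix.sample_ids[:24])
        state_a, _ = preprocess_cdai_fit(train)
        state_b, _ = preprocess_cdai_fit(train.copy())
        np.testing.assert_array_equal(
            state_a.quantile_reference.reference_quantiles,
            state_b.quantile_reference.reference_quantiles)
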