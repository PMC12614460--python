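"""Split arithmetic, imputation, screening, SMOTE, and scaling contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from salp_clinrisk import cohort, preprocess
from salp_clinrisk.preprocess import (
    apply_smote,
    impute_chained,
    largest_remainder,
    screen_features,
    smote_oversample,
    split_cohort,
    standardize,
)

OUTCOME = cohort.OUTCOME_COLUMN


class TestLargestRemainder:
    def test_published_split_sizes(self):
        assert largest_remainder(774, (0.64, 0.16, 0.20)) == [495, 124, 155]

    def test_small_cohort_allocation(self):
        assert largest_remainder(10, (0.8, 0.1, 0.1)) == [8, 1, 1]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        n=st.integers(1, 5000),
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
    )
    def test_allocation_sums_and_stays_within_one_seat(self, n, weights):
        total = sum(weights)
        fractions = tuple(w / total for w in weights)
        sizes = largest_remainder(n, fractions)
        assert sum(sizes) == n
        for size, f in zip(sizes, fractions):
            assert abs(size - n * f) < 1.0


class TestSplitCohort:
    def test_partition_is_disjoint_and_exhaustive(self, missing_cohort):
        s = split_cohort(missing_cohort, seed=0)
        parts = [set(s.train), set(s.validation), set(s.test)]
        assert sum(len(p) for p in parts) == 774
        assert parts[0] | parts[1] | parts[2] == set(range(774))

    def test_sizes_match_study(self, missing_cohort):
        s = split_cohort(missing_cohort, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (495, 124, 155)

    def test_stratified_within_one_case(self, missing_cohort):
        s = split_cohort(missing_cohort, seed=4)
        y = missing_cohort[OUTCOME].to_numpy()
        prevalence = y.mean()
        for idx in (s.train, s.validation, s.test):
            assert abs(y[idx].sum() - prevalence * len(idx)) < 1.0

    def test_deterministic_under_seed(self, missing_cohort):
        a = split_cohort(missing_cohort, seed=9)
        b = split_cohort(missing_cohort, seed=9)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.test, b.test)

    def test_rejects_bad_fractions(self, missing_cohort):
        with pytest.raises(ValueError, match="sum to 1"):
            split_cohort(missing_cohort, fractions=(0.5, 0.3, 0.3))


class TestImputeChained:
    def test_complete_input_returned_unchanged(self, blobs_frame):
        out = impute_chained(blobs_frame, seed=0)
        pd.testing.assert_frame_equal(out, blobs_frame)

    def test_mcar_imputation_recovers_mean(self):
        # two correlated Gaussian columns (rho = 0.8), 20% MCAR on one
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.standard_normal(n)
        z = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "z": z, OUTCOME: rng.integers(0, 2, n)})
        mask = rng.choice(n, size=200, replace=False)
        df_miss = df.copy()
        df_miss.loc[mask, "z"] = np.nan
        out = impute_chained(df_miss, n_cycles=10, seed=1)
        assert out["z"].notna().all()
        observed = df_miss["z"].dropna()
        se = observed.std() / np.sqrt(len(observed))
        assert abs(out["z"].iloc[mask].mean() - observed.mean()) < 3 * se

    def test_observed_cells_bit_identical(self, missing_cohort):
        out = impute_chained(missing_cohort.head(200), n_cycles=3, seed=0)
        src = missing_cohort.head(200)
        observed = src.notna()
        for col in src.columns:
            obs = observed[col]
            assert np.array_equal(
                out.loc[obs, col].to_numpy(float), src.loc[obs, col].to_numpy(float)
            )

    def test_rejects_fully_missing_column(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0], OUTCOME: [0, 1]})
        with pytest.raises(ValueError, match="no observed values"):
            impute_chained(df)


class TestScreenFeatures:
    def test_no_association_binary_gives_p_one(self):
        df = pd.DataFrame(
            {
                "b": [0, 1] * 50,
                OUTCOME: [0] * 50 + [1] * 50,
            }
        )
        res = screen_features(df)
        row = res.set_index("variable").loc["b"]
        assert row["p_value"] == pytest.approx(1.0)
        assert not row["selected"]

    def test_total_separation_selected(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([np.zeros(450, int), np.ones(45, int)])
        x = np.where(y == 1, 10.0, 0.0) + rng.uniform(0, 1, size=495)
        res = screen_features(pd.DataFrame({"x": x, OUTCOME: y}))
        row = res.set_index("variable").loc["x"]
        assert row["p_value"] < 0.05 and row["selected"]

    def test_fisher_path_on_sparse_contingency(self):
        # 0/680 vs 4/43 shaped table has expected counts below 5
        y = np.concatenate([np.zeros(680, int), np.ones(47, int)])
        x = np.zeros(727, int)
        x[-4:] = 1
        res = screen_features(pd.DataFrame({"cold": x, OUTCOME: y}))
        row = res.set_index("variable").loc["cold"]
        assert row["test"] == "fisher"
        assert row["p_value"] < 0.05

    def test_constant_column_warns_and_unselected(self, blobs_frame):
        df = blobs_frame.copy()
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = screen_features(df)
        row = res.set_index("variable").loc["const"]
        assert row["p_value"] == 1.0 and not row["selected"]

    def test_top_k_limits_selection(self, blobs_frame):
        rng = np.random.default_rng(1)
        df = blobs_frame.copy()
        for i in range(6):
            df[f"extra{i}"] = df["f0"] + rng.standard_normal(len(df)) * 0.5
        res = screen_features(df, top_k=3)
        assert res["selected"].sum() == 3
        kept = res.loc[res["selected"], "p_value"]
        dropped = res.loc[~res["selected"] & (res["p_value"] < 0.05), "p_value"]
        if len(dropped):
            assert kept.max() <= dropped.min()

    def test_null_screen_selects_at_alpha_rate(self):
        """On null cohorts the p<0.05 screen fires at its nominal 5% rate."""
        rng = np.random.default_rng(7)
        n, n_vars, n_sims = 200, 10, 200
        selected = total = 0
        for _ in range(n_sims):
            df = pd.DataFrame(
                rng.standard_normal((n, n_vars)), columns=[f"v{i}" for i in range(n_vars)]
            )
            df[OUTCOME] = rng.permutation(np.repeat([0, 1], n // 2))
            res = screen_features(df)
            selected += int(res["selected"].sum())
            total += n_vars
        rate = selected / total
        # binomial 4-sigma band around 0.05 at 2000 trials
        assert abs(rate - 0.05) < 0.02, rate


class TestSmote:
    def test_balances_study_training_counts(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((495, 4))
        y = np.concatenate([np.zeros(464, int), np.ones(31, int)])
        Xr, yr = smote_oversample(X, y, seed=1)
        assert (yr == 0).sum() == 464 and (yr == 1).sum() == 464
        assert np.array_equal(Xr[:495], X)  # originals preserved, first

    def test_synthetic_points_between_parent_extremes(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(60, 3))
        y = np.concatenate([np.zeros(48, int), np.ones(12, int)])
        Xr, yr = smote_oversample(X, y, seed=3)
        minority = X[y == 1]
        synth = Xr[60:]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_balanced_input_is_noop(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 2))
        y = np.repeat([0, 1], 20)
        Xr, yr = smote_oversample(X, y, seed=0)
        assert np.array_equal(Xr, X) and np.array_equal(yr, y)

    def test_rejects_too_few_minority_rows(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        y = np.array([1] * 4 + [0] * 16)
        with pytest.raises(ValueError, match="k_neighbors"):
            smote_oversample(X, y, k_neighbors=5)

    def test_binary_columns_stay_binary(self, missing_cohort, table1_specs):
        df = impute_chained(missing_cohort.head(300), n_cycles=2, seed=0)
        out = apply_smote(df, seed=5)
        assert (out[OUTCOME] == 1).sum() == (out[OUTCOME] == 0).sum()
        for col in preprocess.infer_binary_columns(df):
            assert set(np.unique(out[col])) <= {0.0, 1.0}


class TestStandardize:
    def test_train_columns_zero_mean_unit_sd(self, blobs_frame):
        _, train_t = standardize(blobs_frame)
        feats = [c for c in train_t.columns if c != OUTCOME]
        assert np.allclose(train_t[feats].mean(), 0.0, atol=1e-8)
        assert np.allclose(train_t[feats].std(ddof=0), 1.0, atol=1e-8)

    def test_test_partition_mean_not_zero(self):
        from conftest import make_blobs_frame

        train = make_blobs_frame(seed=0)
        test = make_blobs_frame(seed=1, separation=2.0)
        _, _, test_t = standardize(train, test)
        feats = [c for c in test_t.columns if c != OUTCOME]
        assert np.abs(test_t[feats].mean()).max() > 1e-3

    def test_refit_on_test_differs_proving_no_leakage(self):
        from conftest import make_blobs_frame

        train = make_blobs_frame(seed=0)
        test = make_blobs_frame(seed=1, separation=2.0)
        params_train, *_ = standardize(train, test)
        params_test, *_ = standardize(test)
        assert not np.allclose(params_train.center, params_test.center)

    def test_zero_variance_column_scaled_by_one(self, blobs_frame):
        df = blobs_frame.copy()
        df["const"] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            params, out = standardize(df)
        assert params.scale["const"] == 1.0
        assert np.allclose(out["const"], 0.0)
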