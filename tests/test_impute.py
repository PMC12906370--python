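import zlib

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

import cogharmon as ch
from cogharmon.impute import convergence_delta, design_matrix, forest_seed

from conftest import make_table


class TestInitializeMissing:
    def test_continuous_column_filled_with_mean(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 3, 1, seed=0)
        df = t.df.copy()
        df["C"] = [100.0, np.nan, 140.0]
        out = ch.initialize_missing(ch.VisitTable(tiny_catalog, df), targets=["C"])
        assert out.df["C"].tolist() == [100.0, 120.0, 140.0]

    def test_discrete_column_filled_with_median(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 4, 1, seed=0)
        df = t.df.copy()
        df["A"] = [4.0, 4.0, np.nan, 10.0]
        out = ch.initialize_missing(ch.VisitTable(tiny_catalog, df), targets=["A"])
        assert out.df["A"].tolist() == [4.0, 4.0, 4.0, 10.0]

    def test_complete_column_untouched(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 4, 2, seed=1)
        out = ch.initialize_missing(t, targets=["A"])
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_fully_missing_column_raises_with_name(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 3, 1, seed=2)
        df = t.df.copy()
        df["B"] = np.nan
        with pytest.raises(ValueError, match="'B'"):
            ch.initialize_missing(ch.VisitTable(tiny_catalog, df), targets=["B"])


class TestConvergenceDelta:
    def test_identical_arrays_give_zero(self):
        assert convergence_delta([1.0, 2.0], [1.0, 2.0], "continuous") == 0.0

    def test_continuous_formula_hand_case(self):
        # sum((1-0)^2 + (1-0)^2) / sum(1^2 + 1^2) = 2/2
        assert convergence_delta([0.0, 0.0], [1.0, 1.0], "continuous") == 1.0

    def test_categorical_proportion_changed(self):
        prev = np.array(["a", "a", "b", "b"])
        cur = np.array(["a", "a", "b", "c"])
        assert convergence_delta(prev, cur, "categorical") == 0.25

    def test_zero_denominator_with_change_is_infinite(self):
        assert convergence_delta([1.0], [0.0], "continuous") == np.inf

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            convergence_delta([1.0], [1.0, 2.0], "continuous")


class TestImputeCore:
    def test_no_missing_values_is_identity(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 4, 3, seed=3)
        res = ch.impute(t, config=ch.ImputationConfig(n_trees=10, seed=0))
        assert res.iterations_run == 0
        pd.testing.assert_frame_equal(res.completed.df, t.df)

    def test_single_cell_matches_one_shot_forest_oracle(self, tiny_catalog):
        """One missing cell, numeric predictors: the iterative imputer's
        first sweep must agree bit-exactly with a directly-fit forest."""
        t = make_table(tiny_catalog, "X", 40, 2, seed=4)
        df = t.df.copy()
        hole = df.index[7]
        true_removed = df.loc[hole, "C"]
        df.loc[hole, "C"] = np.nan
        table = ch.VisitTable(tiny_catalog, df)
        cfg = ch.ImputationConfig(n_trees=25, seed=99, max_iterations=1)
        res = ch.impute(table, predictors=["A", "B"], targets=["C"], config=cfg)

        # independent oracle: same documented seed derivation, own fit
        oracle_seed = int(
            np.random.SeedSequence([99, 1, zlib.crc32(b"C")]).generate_state(1)[0]
            % (2**31)
        )
        obs = df["C"].notna()
        X = df[["A", "B"]].to_numpy(float)
        forest = RandomForestRegressor(
            n_estimators=25,
            min_samples_leaf=5,
            max_features=1.0 / 3.0,
            random_state=oracle_seed,
        )
        forest.fit(X[obs.to_numpy()], df.loc[obs, "C"].to_numpy(float))
        expected = forest.predict(X[[hole]])[0]
        got = res.completed.df.loc[hole, "C"]
        assert got == expected  # bit-identical
        assert got != true_removed  # the oracle is a prediction, not a lookup

    def test_observed_values_never_change(self, small_harmonized):
        _, merged, _, result = small_harmonized
        obs = merged.df[merged.score_columns].notna().to_numpy()
        before = merged.df[merged.score_columns].to_numpy()
        after = result.completed.df[merged.score_columns].to_numpy()
        np.testing.assert_array_equal(before[obs], after[obs])

    def test_completed_has_no_missing_scores(self, small_harmonized):
        _, merged, _, result = small_harmonized
        assert result.completed.df[merged.score_columns].notna().all().all()

    def test_imputed_values_respect_catalog_ranges(self, small_harmonized):
        _, merged, _, result = small_harmonized
        for spec in merged.catalog:
            vals = result.completed.df[spec.test_id]
            assert (vals >= spec.score_min).all()
            assert (vals <= spec.score_max).all()

    def test_delta_trace_length_matches_iterations(self, small_harmonized):
        *_, result = small_harmonized
        assert len(result.delta_trace) == result.iterations_run
        assert result.iterations_run >= 1

    def test_determinism_under_fixed_seed(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 25, 3, seed=5, missing=0.2)
        cfg = ch.ImputationConfig(n_trees=15, seed=7)
        a = ch.impute(t, config=cfg).completed.df
        b = ch.impute(t, config=cfg).completed.df
        pd.testing.assert_frame_equal(a, b)
        c = ch.impute(t, config=ch.ImputationConfig(n_trees=15, seed=8)).completed.df
        assert not a.equals(c)

    def test_unobserved_column_rejected(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 5, 2, seed=6)
        df = t.df.copy()
        df["A"] = np.nan
        with pytest.raises(ValueError, match="zero rows"):
            ch.MissForestImputer(ch.VisitTable(tiny_catalog, df), targets=["A"])

    def test_round_discrete_yields_integers(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 25, 3, seed=8, missing=0.2)
        cfg = ch.ImputationConfig(n_trees=10, seed=1, round_discrete=True)
        res = ch.impute(t, config=cfg)
        imputed_a = res.completed.df.loc[res.imputed_mask["A"], "A"]
        assert (imputed_a == imputed_a.round()).all()


class TestSeedPolicy:
    def test_forest_seed_is_stable_and_column_specific(self):
        s1 = forest_seed(3, "MMSE", 1)
        assert s1 == forest_seed(3, "MMSE", 1)
        assert s1 != forest_seed(3, "LMII", 1)
        assert s1 != forest_seed(3, "MMSE", 2)
        assert 0 <= s1 < 2**31


class TestDesignMatrix:
    def test_categorical_expansion_in_sorted_order(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "s": ["b", "a"]})
        X = design_matrix(df, ["x", "s"], categorical=["s"])
        # columns: x, s==a, s==b
        np.testing.assert_array_equal(X, [[1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])


class TestDistributionShift:
    def test_complete_column_has_identical_statistics(self, small_harmonized):
        _, merged, _, result = small_harmonized
        report = ch.distribution_shift_report(merged, result.completed)
        mmse = report[(report.test_id == "MMSE")]
        # MMSE is administered everywhere; small MAR gaps only
        complete = mmse[~mmse.structurally_missing]
        assert (complete["abs_diff_mean"] < 0.5).all()

    def test_structural_column_flagged_without_observed_stats(self, small_harmonized):
        _, merged, _, result = small_harmonized
        report = ch.distribution_shift_report(merged, result.completed)
        row = report[(report.test_id == "CVLT_delayed_recall") & (report.cohort_id == "ADNI")]
        assert bool(row["structurally_missing"].iloc[0])
        assert np.isnan(row["observed_mean"].iloc[0])
        assert np.isfinite(row["harmonized_mean"].iloc[0])

    def test_perfect_oracle_on_balanced_mask_shifts_nothing(self, tiny_catalog):
        # mask values whose mean equals the observed mean, restore them
        # with a perfect oracle: harmonized mean == observed mean exactly
        t = make_table(tiny_catalog, "X", 30, 2, seed=9)
        df = t.df.copy()
        df["A"] = np.tile([10.0, 20.0], 30)
        holes = df.index[[0, 1]]  # one 10 and one 20
        truth = df.loc[holes, "A"].copy()
        df.loc[holes, "A"] = np.nan
        before = ch.VisitTable(tiny_catalog, df)
        after = before.copy()
        after.df.loc[holes, "A"] = truth
        report = ch.distribution_shift_report(before, after)
        row = report[report.test_id == "A"]
        assert row["abs_diff_mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)
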