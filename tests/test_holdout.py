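import numpy as np
import pandas as pd
import pytest

import cogharmon as ch
from cogharmon.holdout import HoldoutPlan, _n_masked, max_discrepancy

from conftest import make_table


def identity_oracle_for(table):
    """Imputer that restores the original (pre-mask) values exactly."""

    def imputer(masked, config, seed):
        completed = masked.copy()
        for col in completed.score_columns:
            holes = completed.df[col].isna() & table.df[col].notna()
            completed.df.loc[holes, col] = table.df.loc[holes, col]
        return completed

    return imputer


def noisy_oracle_for(table, noise_sd):
    """Oracle plus additive Gaussian noise of the given SD."""

    def imputer(masked, config, seed):
        rng = np.random.default_rng(seed)
        completed = masked.copy()
        for col in completed.score_columns:
            holes = completed.df[col].isna() & table.df[col].notna()
            completed.df.loc[holes, col] = table.df.loc[holes, col] + rng.normal(
                0, noise_sd, int(holes.sum())
            )
        return completed

    return imputer


class TestSimulateMissing:
    def test_mask_count_is_round_fraction_of_observed(self, small_generated):
        _, merged, _ = small_generated
        n_obs = int(merged.df["MMSE"].notna().sum())
        masked, truth = ch.simulate_missing(merged, "MMSE", 0.30, seed=1)
        assert len(truth) == _n_masked(0.30, n_obs)
        assert int(masked.df["MMSE"].notna().sum()) == n_obs - len(truth)

    def test_round_half_up(self):
        assert _n_masked(0.30, 100) == 30
        assert _n_masked(0.30, 105) == 32  # 31.5 rounds up
        assert _n_masked(0.5, 3) == 2

    def test_masked_positions_were_observed(self, small_generated):
        _, merged, _ = small_generated
        masked, truth = ch.simulate_missing(merged, "LMII", 0.30, seed=2)
        assert merged.df["LMII"].iloc[truth.index].notna().all()
        assert truth.notna().all()

    def test_other_columns_untouched(self, small_generated):
        _, merged, _ = small_generated
        masked, _ = ch.simulate_missing(merged, "LMII", 0.30, seed=3)
        others = [c for c in merged.df.columns if c != "LMII"]
        pd.testing.assert_frame_equal(masked.df[others], merged.df[others])

    def test_different_seeds_give_different_masks(self, small_generated):
        _, merged, _ = small_generated
        _, t1 = ch.simulate_missing(merged, "MMSE", 0.30, seed=1)
        _, t2 = ch.simulate_missing(merged, "MMSE", 0.30, seed=2)
        assert set(t1.index) != set(t2.index)

    def test_infeasible_fraction_rejected(self, tiny_catalog):
        t = make_table(tiny_catalog, "X", 2, 1, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            ch.simulate_missing(t, "A", 0.01, seed=0)


class TestErrorMetrics:
    def test_mae_identity_is_zero(self):
        assert ch.mae([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_mae_hand_case(self):
        assert ch.mae([10.0, 20.0], [12.0, 16.0]) == pytest.approx(3.0)

    def test_mae_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            ch.mae([1.0], [1.0, 2.0])

    def test_outlier_rule_hand_case(self):
        # sd 4 -> threshold 10; |21 - 10| = 11 is an outlier
        assert ch.outlier_rate([10.0], [21.0], sd_actual=4.0) == 100.0
        assert ch.outlier_rate([10.0], [19.0], sd_actual=4.0) == 0.0

    def test_outlier_proportion(self):
        truth = [0.0, 0.0, 0.0, 0.0]
        imputed = [100.0, 0.1, 0.2, 0.3]
        assert ch.outlier_rate(truth, imputed, sd_actual=1.0) == 25.0

    def test_identity_imputer_has_no_outliers(self):
        assert ch.outlier_rate([5.0, 6.0], [5.0, 6.0], sd_actual=1.0) == 0.0


class TestMaxDiscrepancy:
    @staticmethod
    def _table(tiny_catalog, scores_by_pid):
        rows = []
        for pid, scores in scores_by_pid.items():
            for v, s in enumerate(scores):
                rows.append(
                    {
                        "participant_id": pid,
                        "cohort_id": "X",
                        "visit_index": v,
                        "time_years": float(v),
                        "age_years": 70.0,
                        "sex": "female",
                        "education_years": 12.0,
                        "apoe4": "non-carrier",
                        "cdr": 0.0,
                        "centiloid": 5.0,
                        "diagnosis": "cu",
                        "A": s,
                    }
                )
        return ch.VisitTable(tiny_catalog, pd.DataFrame(rows))

    def test_constant_performance_gives_zero(self, tiny_catalog):
        t = self._table(tiny_catalog, {"p1": [27, 27, 27]})
        disc, summary = max_discrepancy(t, "A")
        assert disc.loc["p1"] == 0.0

    def test_max_minus_min(self, tiny_catalog):
        t = self._table(tiny_catalog, {"p1": [28, 30, 29]})
        disc, _ = max_discrepancy(t, "A")
        assert disc.loc["p1"] == 2.0

    def test_summary_hand_case(self, tiny_catalog):
        t = self._table(
            tiny_catalog, {"p1": [10, 10, 10], "p2": [10, 12, 11], "p3": [10, 14, 12]}
        )
        _, summary = max_discrepancy(t, "A")
        assert summary["mean"] == pytest.approx(2.0)
        assert summary["sd"] == pytest.approx(2.0)
        assert (summary["min"], summary["max"]) == (0.0, 4.0)

    def test_invariant_to_visit_order_and_nonnegative(self, tiny_catalog):
        t1 = self._table(tiny_catalog, {"p1": [28, 30, 29]})
        t2 = self._table(tiny_catalog, {"p1": [29, 28, 30]})
        d1, _ = max_discrepancy(t1, "A")
        d2, _ = max_discrepancy(t2, "A")
        assert d1.loc["p1"] == d2.loc["p1"] >= 0

    def test_single_observation_participants_excluded(self, tiny_catalog):
        t = self._table(tiny_catalog, {"p1": [28], "p2": [10, 12, 11]})
        disc, summary = max_discrepancy(t, "A")
        assert "p1" not in disc.index
        assert summary["n"] == 1

    def test_symptomatic_participants_excluded(self, small_generated):
        _, merged, truth = small_generated
        labelled = ch.add_group_labels(merged)
        disc, _ = max_discrepancy(labelled, "MMSE")
        groups = (
            labelled.df.drop_duplicates("participant_id")
            .set_index("participant_id")["group"]
        )
        assert all(groups.loc[p] == "ABNEG_CDR0" for p in disc.index)


class TestRunValidation:
    def test_identity_oracle_scores_zero_everywhere(self, small_generated):
        _, merged, _ = small_generated
        plan = HoldoutPlan(tests=["MMSE", "LMII"], n_repeats=3, master_seed=4)
        report = ch.run_validation(merged, plan, imputer=identity_oracle_for(merged))
        assert (report.table["mae_mean"] == 0).all()
        assert (report.table["mae_sd"] == 0).all()
        assert (report.table["outlier_pct_mean"] == 0).all()

    def test_mae_nondecreasing_in_oracle_noise(self, small_generated):
        _, merged, _ = small_generated
        plan = HoldoutPlan(tests=["MMSE"], n_repeats=3, master_seed=4)
        maes = []
        for s in (0.0, 0.5, 2.0):
            rep = ch.run_validation(merged, plan, imputer=noisy_oracle_for(merged, s))
            maes.append(rep.table["mae_mean"].iloc[0])
        assert maes[0] <= maes[1] <= maes[2]

    def test_report_is_deterministic(self, small_generated):
        _, merged, _ = small_generated
        plan = HoldoutPlan(tests=["MMSE"], n_repeats=2, master_seed=9)
        imputer = noisy_oracle_for(merged, 1.0)
        r1 = ch.run_validation(merged, plan, imputer=imputer)
        r2 = ch.run_validation(merged, plan, imputer=imputer)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        pd.testing.assert_frame_equal(r1.per_repeat, r2.per_repeat)

    def test_aggregates_match_per_repeat_values_exactly(self, small_generated):
        _, merged, _ = small_generated
        plan = HoldoutPlan(tests=["MMSE", "BNT_no_cue"], n_repeats=4, master_seed=2)
        rep = ch.run_validation(merged, plan, imputer=noisy_oracle_for(merged, 1.0))
        for tid in plan.tests:
            sub = rep.per_repeat[rep.per_repeat.test_id == tid]
            row = rep.table[rep.table.test_id == tid].iloc[0]
            assert row["mae_mean"] == pytest.approx(sub["mae"].mean(), abs=0, rel=0)
            assert row["mae_sd"] == pytest.approx(sub["mae"].std(ddof=1), abs=0, rel=0)

    def test_failing_repeats_recorded_not_fatal(self, small_generated):
        _, merged, _ = small_generated

        calls = {"n": 0}

        def flaky(masked, config, seed):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("boom")
            return identity_oracle_for(merged)(masked, config, seed)

        plan = HoldoutPlan(tests=["MMSE"], n_repeats=3, master_seed=1)
        rep = ch.run_validation(merged, plan, imputer=flaky)
        assert len(rep.failures) == 1
        assert len(rep.per_repeat) == 2

    def test_plan_validation(self):
        with pytest.raises(ValueError, match="mask_fraction"):
            HoldoutPlan(tests=["MMSE"], mask_fraction=1.5)
        with pytest.raises(ValueError, match="n_repeats"):
            HoldoutPlan(tests=["MMSE"], n_repeats=0)
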