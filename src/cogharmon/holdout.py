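"""Hold-out precision validation of the harmonization procedure.

The protocol masks a fraction (default 30%) of the observed values of one
test, re-runs the full imputation on the masked table, and scores the
imputed values against the withheld truth: mean absolute error (MAE),
the rate of imputations falling more than 2.5 SD from truth (with the SD
taken from the test's observed marginal distribution), repeated over
several random masks.  As a benchmark of natural test-retest variability,
the maximum discrepancy score — each participant's highest minus lowest
observed score — is summarized over cognitively unimpaired amyloid-
negative participants, the population expected to be stable over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .impute import ImputationConfig, MissForestImputer
from .visits import GroupLabel, VisitTable, add_group_labels

__all__ = [
    "HoldoutPlan",
    "ValidationReport",
    "simulate_missing",
    "mae",
    "outlier_rate",
    "max_discrepancy",
    "run_validation",
]

#: An imputer is any callable taking (masked table, config, seed) and
#: returning a completed VisitTable.
Imputer = Callable[[VisitTable, ImputationConfig, int], VisitTable]


@dataclass
class HoldoutPlan:
    """What to mask, how often, and with which master seed."""

    tests: Sequence[str]
    mask_fraction: float = 0.30
    n_repeats: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ValidationReport:
    """Per-test accuracy/precision statistics from the masking protocol.

    ``table`` mirrors the layout of a precision-analysis table: actual
    score range, actual mean +/- SD, the CU amyloid-negative maximum-
    discrepancy benchmark, MAE mean +/- SD over repeats, and outlier %
    mean +/- SD over repeats, with verdict flags.  ``per_repeat`` keeps
    the raw per-repeat values so the aggregates can be recomputed
    exactly.
    """

    table: pd.DataFrame
    per_repeat: pd.DataFrame
    plan: HoldoutPlan
    failures: list[str] = field(default_factory=list)

    def summary(self) -> str:
        cols = [
            "test_id",
            "mae_mean",
            "mae_sd",
            "outlier_pct_mean",
            "max_discrepancy_mean",
            "mae_within_benchmark",
        ]
        return self.table[cols].to_string(index=False)


def _n_masked(fraction: float, n_observed: int) -> int:
    """Round-half-up count of cells to withhold."""
    return int(math.floor(fraction * n_observed + 0.5))


def simulate_missing(
    table: VisitTable, test_id: str, fraction: float, seed: int
) -> tuple[VisitTable, pd.Series]:
    """Mask a random subset of the observed values of one test.

    Exactly round(fraction x n_observed) observed entries are set
    missing, chosen uniformly without replacement; every other column is
    untouched.  Returns the masked table and the withheld truth indexed
    by row position.
    """
    series = table.df[test_id]
    obs_idx = np.flatnonzero(series.notna().to_numpy())
    n_mask = _n_masked(fraction, len(obs_idx))
    if n_mask < 1:
        raise ValueError(
            f"fraction {fraction} infeasible for {len(obs_idx)} observed values of {test_id}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(obs_idx, size=n_mask, replace=False))
    truth = series.iloc[chosen].copy()
    masked = table.copy()
    masked.df.iloc[chosen, masked.df.columns.get_loc(test_id)] = np.nan
    return masked, truth


def mae(truth: Sequence[float], imputed: Sequence[float]) -> float:
    """Mean absolute error between withheld truth and imputed values."""
    truth = np.asarray(truth, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed must have equal length")
    if truth.size == 0:
        raise ValueError("empty inputs")
    return float(np.mean(np.abs(imputed - truth)))


def outlier_rate(
    truth: Sequence[float], imputed: Sequence[float], sd_actual: float
) -> float:
    """Percentage of imputations more than 2.5 SD from the truth.

    ``sd_actual`` is the SD of the test's observed values in the full
    (unmasked) table.
    """
    if sd_actual <= 0:
        raise ValueError("sd_actual must be > 0")
    truth = np.asarray(truth, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    return float(100.0 * np.mean(np.abs(imputed - truth) > 2.5 * sd_actual))


def max_discrepancy(
    table: VisitTable,
    test_id: str,
    group: GroupLabel = GroupLabel.ABNEG_CDR0,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-participant max-minus-min observed score in the benchmark group.

    The benchmark population is participants carrying the requested group
    label whose CDR is 0 at every visit; participants with fewer than two
    observed values of the test are excluded.  Returns the per-participant
    discrepancies and their mean/SD/range.
    """
    df = table.df
    if "group" not in df.columns:
        df = add_group_labels(table).df
    stable = df.groupby("participant_id")["cdr"].transform("max") == 0.0
    scope = df[(df["group"] == group.value) & stable]
    per = (
        scope.dropna(subset=[test_id])
        .groupby("participant_id")[test_id]
        .agg(["max", "min", "count"])
    )
    per = per[per["count"] >= 2]
    disc = (per["max"] - per["min"]).rename("max_discrepancy")
    if disc.empty:
        summary = {"mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan, "n": 0}
    else:
        summary = {
            "mean": float(disc.mean()),
            "sd": float(disc.std(ddof=1)) if len(disc) > 1 else np.nan,
            "min": float(disc.min()),
            "max": float(disc.max()),
            "n": int(len(disc)),
        }
    return disc, summary


def _default_imputer(table: VisitTable, config: ImputationConfig, seed: int) -> VisitTable:
    cfg = ImputationConfig(**{**config.__dict__, "seed": seed})
    return MissForestImputer(table, config=cfg).fit().completed


def _repeat_seed(master_seed: int, test_index: int, repeat: int) -> int:
    return int(
        np.random.SeedSequence([master_seed, test_index, repeat]).generate_state(1)[0]
        % (2**31)
    )


def run_validation(
    table: VisitTable,
    plan: HoldoutPlan,
    config: ImputationConfig | None = None,
    imputer: Imputer | None = None,
    centiloid_threshold: float = 25.0,
) -> ValidationReport:
    """Run the full masking protocol and assemble the precision report.

    For each test in the plan and each repeat: mask a fraction of its
    observed values (one test at a time; all other columns keep their
    original values), impute every missing value in the masked table, and
    score MAE and the 2.5-SD outlier rate on the withheld positions.
    Aggregates are mean +/- SD across repeats.  A repeat whose imputation
    fails is recorded and skipped rather than aborting the report.
    """
    config = config or ImputationConfig()
    imputer = imputer or _default_imputer
    rep_rows = []
    failures: list[str] = []
    for t_idx, test_id in enumerate(plan.tests):
        series = table.df[test_id]
        sd_actual = float(series.dropna().std(ddof=1))
        for rep in range(plan.n_repeats):
            seed = _repeat_seed(plan.master_seed, t_idx, rep)
            masked, truth = simulate_missing(table, test_id, plan.mask_fraction, seed)
            try:
                completed = imputer(masked, config, seed)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures.append(f"{test_id} repeat {rep}: {exc}")
                continue
            imputed = completed.df[test_id].iloc[truth.index.to_numpy()]
            rep_rows.append(
                {
                    "test_id": test_id,
                    "repeat": rep,
                    "n_masked": len(truth),
                    "mae": mae(truth.to_numpy(), imputed.to_numpy()),
                    "outlier_pct": outlier_rate(
                        truth.to_numpy(), imputed.to_numpy(), sd_actual
                    ),
                }
            )
    per_repeat = pd.DataFrame(rep_rows)

    labelled = add_group_labels(table, centiloid_threshold)
    summary_rows = []
    for test_id in plan.tests:
        spec = table.catalog[test_id]
        obs = table.df[test_id].dropna()
        _, md = max_discrepancy(labelled, test_id)
        sub = per_repeat[per_repeat["test_id"] == test_id] if len(per_repeat) else per_repeat
        mae_mean = float(sub["mae"].mean()) if len(sub) else np.nan
        mae_sd = float(sub["mae"].std(ddof=1)) if len(sub) > 1 else np.nan
        out_mean = float(sub["outlier_pct"].mean()) if len(sub) else np.nan
        out_sd = float(sub["outlier_pct"].std(ddof=1)) if len(sub) > 1 else np.nan
        summary_rows.append(
            {
                "test_id": test_id,
                "range_min": spec.score_min,
                "range_max": spec.score_max,
                "actual_mean": float(obs.mean()),
                "actual_sd": float(obs.std(ddof=1)),
                "max_discrepancy_mean": md["mean"],
                "max_discrepancy_sd": md["sd"],
                "max_discrepancy_min": md["min"],
                "max_discrepancy_max": md["max"],
                "mae_mean": mae_mean,
                "mae_sd": mae_sd,
                "outlier_pct_mean": out_mean,
                "outlier_pct_sd": out_sd,
                "mae_within_benchmark": bool(mae_mean <= md["mean"])
                if not (np.isnan(mae_mean) or np.isnan(md["mean"]))
                else False,
            }
        )
    return ValidationReport(
        table=pd.DataFrame(summary_rows),
        per_repeat=per_repeat,
        plan=plan,
        failures=failures,
    )
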