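"""Iterative random-forest imputation of the merged visit table.

The harmonization engine fills every missing value in the merged dataset
— both sporadic gaps within an administered test and whole tests a cohort
never administered — with the MissForest scheme: missing entries are
seeded with column means (medians for integer-valued tests), then each
incomplete variable is repeatedly re-imputed by a random forest trained on
the rows where it was originally observed, using demographics, clinical
status, APOE, dataset-of-origin, and all other test scores as predictors.
Sweeps continue until the change in imputed values first increases (the
classic stopping rule), a relative-change threshold is crossed, or an
iteration cap is reached.  Every visit is treated as an independent
observation; time is not modelled explicitly.

The model object is :class:`MissForestImputer`; :meth:`MissForestImputer.fit`
returns an :class:`ImputationResult` carrying the completed table, the
convergence trace, and the imputed-cell mask.  :func:`impute` is a
one-call convenience wrapper.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .visits import VisitTable

__all__ = [
    "ImputationConfig",
    "ImputationResult",
    "MissForestImputer",
    "impute",
    "initialize_missing",
    "convergence_delta",
    "forest_seed",
    "design_matrix",
    "distribution_shift_report",
    "DEFAULT_CATEGORICAL_PREDICTORS",
]

#: Covariates treated as unordered categories when used as predictors or
#: imputation targets.  CDR is categorical, not numeric.
DEFAULT_CATEGORICAL_PREDICTORS = ("sex", "apoe4", "cdr", "cohort_id")

#: Continuous covariates available as predictors/targets.
DEFAULT_CONTINUOUS_PREDICTORS = ("age_years", "education_years")


@dataclass
class ImputationConfig:
    """Hyperparameters of the iterative forest imputer.

    Defaults follow the reference MissForest implementation: 100 trees,
    minimum leaf size 5, square-root feature subsampling for
    classification and one-third for regression, at most 10 sweeps with
    the first-increase stopping rule.  ``clip_to_range`` clamps imputed
    scores into the catalog range; ``round_discrete`` optionally rounds
    imputed integer-valued tests after convergence (off by default, for
    sensitivity analysis).
    """

    max_iterations: int = 10
    n_trees: int = 100
    min_leaf: int = 5
    stop_rule: Literal["first_increase", "threshold"] = "first_increase"
    threshold: float = 1e-4
    seed: int = 0
    clip_to_range: bool = True
    round_discrete: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.stop_rule not in ("first_increase", "threshold"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")


@dataclass
class ImputationResult:
    """Completed table plus convergence diagnostics.

    Attributes
    ----------
    completed
        Visit table with no missing entries among the imputation targets;
        originally observed values are unchanged.
    iterations_run
        Number of full sweeps executed (0 if nothing was missing).
    delta_trace
        One row per sweep with the continuous and categorical convergence
        statistics.
    imputed_mask
        Boolean frame (rows aligned with the table) marking the cells
        that were filled.
    """

    completed: VisitTable
    iterations_run: int
    delta_trace: pd.DataFrame
    imputed_mask: pd.DataFrame
    config: ImputationConfig = field(default_factory=ImputationConfig)

    def summary(self) -> str:
        lines = [
            "Iterative random-forest imputation",
            f"  sweeps run:        {self.iterations_run}",
            f"  cells imputed:     {int(self.imputed_mask.to_numpy().sum())}",
            f"  stop rule:         {self.config.stop_rule}",
        ]
        if len(self.delta_trace):
            last = self.delta_trace.iloc[-1]
            lines.append(f"  final delta (cont): {last['delta_continuous']:.6g}")
            if not np.isnan(last["delta_categorical"]):
                lines.append(f"  final delta (cat):  {last['delta_categorical']:.6g}")
        return "\n".join(lines)


def forest_seed(master_seed: int, column: str, iteration: int) -> int:
    """Deterministic per-column, per-sweep forest seed.

    Derived as ``SeedSequence([master_seed, iteration, crc32(column)])``
    reduced modulo 2**31, so results are reproducible regardless of the
    order in which columns are visited.
    """
    entropy = [int(master_seed), int(iteration), zlib.crc32(column.encode("utf-8"))]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def design_matrix(
    df: pd.DataFrame, columns: Sequence[str], categorical: Iterable[str]
) -> np.ndarray:
    """Numeric design matrix for forest fitting.

    Numeric columns enter as-is (float64); categorical columns expand in
    place to one 0/1 indicator per category, categories sorted
    lexicographically over the full frame.
    """
    cat = set(categorical)
    blocks: list[np.ndarray] = []
    for col in columns:
        if col in cat:
            values = df[col].astype(str)
            for level in sorted(values.unique()):
                blocks.append((values == level).to_numpy(float))
        else:
            blocks.append(df[col].to_numpy(float))
    return np.column_stack(blocks)


def convergence_delta(
    previous: np.ndarray | Sequence,
    current: np.ndarray | Sequence,
    scope: Literal["continuous", "categorical"],
) -> float:
    """Change in imputed values between successive sweeps.

    Continuous scope: ``sum((current - previous)**2) / sum(current**2)``
    over imputed positions (0 when both numerator and denominator are 0,
    +inf when only the denominator is).  Categorical scope: proportion of
    imputed positions whose category changed.
    """
    previous = np.asarray(previous)
    current = np.asarray(current)
    if previous.shape != current.shape:
        raise ValueError("previous and current must have equal length")
    if current.size == 0:
        return 0.0
    if scope == "continuous":
        num = float(np.sum((current.astype(float) - previous.astype(float)) ** 2))
        den = float(np.sum(current.astype(float) ** 2))
        if den == 0.0:
            return 0.0 if num == 0.0 else float("inf")
        return num / den
    if scope == "categorical":
        return float(np.mean(previous != current))
    raise ValueError(f"unknown scope {scope!r}")


def _classify_columns(columns: Iterable[str]) -> tuple[list[str], list[str]]:
    """Split columns into (continuous-or-score, categorical)."""
    cont, cat = [], []
    for col in columns:
        if col in DEFAULT_CATEGORICAL_PREDICTORS:
            cat.append(col)
        else:
            cont.append(col)
    return cont, cat


def initialize_missing(table: VisitTable, targets: Sequence[str] | None = None) -> VisitTable:
    """Seed missing entries with column means (medians for discrete tests).

    Continuous columns get the mean of their observed values; integer-
    valued (discrete) tests and categorical covariates get the median /
    mode.  Observed entries are untouched.  A target column with no
    observed values at all raises, naming the column.
    """
    out = table.copy()
    if targets is None:
        targets = [c for c in _default_targets(table) if out.df[c].isna().any()]
    for col in targets:
        series = out.df[col]
        miss = series.isna()
        if not miss.any():
            continue
        obs = series.dropna()
        if obs.empty:
            raise ValueError(f"cannot initialize column {col!r}: no observed values")
        if col in DEFAULT_CATEGORICAL_PREDICTORS:
            fill = obs.mode().iloc[0]
        elif col in table.catalog and table.catalog[col].discrete:
            fill = float(obs.median())
        else:
            fill = float(obs.mean())
        out.df.loc[miss, col] = fill
    return out


def _default_predictors(table: VisitTable) -> list[str]:
    return (
        list(DEFAULT_CONTINUOUS_PREDICTORS)
        + list(DEFAULT_CATEGORICAL_PREDICTORS)
        + table.score_columns
    )


def _default_targets(table: VisitTable) -> list[str]:
    """Score columns plus imputable demographics, in table order."""
    demo = ["age_years", "education_years", "sex", "apoe4"]
    return table.score_columns + demo


class MissForestImputer:
    """Iterative random-forest imputation model for a visit table.

    Parameters
    ----------
    table
        Merged visit table with missing entries (NaN).
    predictors
        Columns used as forest inputs; defaults to age, sex, education,
        CDR, APOE, dataset-of-origin id, and every score column (each
        target's own column is excluded when imputing it).
    targets
        Columns to impute; defaults to every score column and imputable
        demographic with at least one missing value.
    config
        Forest and stopping-rule hyperparameters.
    """

    def __init__(
        self,
        table: VisitTable,
        predictors: Sequence[str] | None = None,
        targets: Sequence[str] | None = None,
        config: ImputationConfig | None = None,
    ):
        self.table = table
        self.config = config or ImputationConfig()
        self.predictors = list(predictors) if predictors is not None else _default_predictors(table)
        if targets is None:
            targets = [c for c in _default_targets(table) if table.df[c].isna().any()]
        else:
            targets = list(targets)
        unknown = [c for c in targets if c not in table.df.columns]
        if unknown:
            raise ValueError(f"unknown target columns: {unknown}")
        for col in targets:
            if table.df[col].notna().sum() == 0:
                raise ValueError(
                    f"column {col!r} is observed in zero rows and cannot be imputed"
                )
        self.targets = targets
        self._cont_targets, self._cat_targets = _classify_columns(targets)

    # ------------------------------------------------------------------
    def _fit_one(
        self, work: pd.DataFrame, col: str, obs: np.ndarray, mis: np.ndarray, iteration: int
    ) -> np.ndarray:
        """Fit one forest for ``col`` and predict its missing rows."""
        cfg = self.config
        pred_cols = [p for p in self.predictors if p != col]
        X = design_matrix(work, pred_cols, DEFAULT_CATEGORICAL_PREDICTORS)
        seed = forest_seed(cfg.seed, col, iteration)
        if col in self._cat_targets:
            model = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                min_samples_leaf=cfg.min_leaf,
                max_features="sqrt",
                random_state=seed,
            )
            model.fit(X[obs], work.loc[obs, col].astype(str))
        else:
            model = RandomForestRegressor(
                n_estimators=cfg.n_trees,
                min_samples_leaf=cfg.min_leaf,
                max_features=1.0 / 3.0,
                random_state=seed,
            )
            model.fit(X[obs], work.loc[obs, col].to_numpy(float))
        return model.predict(X[mis])

    def fit(self) -> ImputationResult:
        """Run the iterative imputation; deterministic under a fixed seed."""
        cfg = self.config
        df = self.table.df
        miss_mask = pd.DataFrame(
            {c: df[c].isna().to_numpy() for c in self.targets}, index=df.index
        )
        n_missing = {c: int(miss_mask[c].sum()) for c in self.targets}
        active = [c for c in self.targets if n_missing[c] > 0]
        if not active:
            return ImputationResult(
                completed=self.table.copy(),
                iterations_run=0,
                delta_trace=pd.DataFrame(
                    columns=["iteration", "delta_continuous", "delta_categorical"]
                ),
                imputed_mask=miss_mask,
                config=cfg,
            )

        # ascending missingness fraction, ties broken by table order
        active.sort(key=lambda c: n_missing[c])
        work = initialize_missing(self.table, targets=active).df

        cont_active = [c for c in active if c in self._cont_targets]
        cat_active = [c for c in active if c in self._cat_targets]

        def snapshot() -> dict[str, np.ndarray]:
            return {
                c: work.loc[miss_mask[c].to_numpy(), c].to_numpy() for c in active
            }

        prev_delta_cont = np.inf
        prev_delta_cat = np.inf
        trace_rows = []
        final = work
        iterations_run = 0
        for iteration in range(1, cfg.max_iterations + 1):
            old = snapshot()
            before_sweep = work.copy()
            for col in active:
                mis = miss_mask[col].to_numpy()
                obs = ~mis
                work.loc[mis, col] = self._fit_one(work, col, obs, mis, iteration)
            new = snapshot()

            def stacked(cols: list[str], values: dict[str, np.ndarray]) -> np.ndarray:
                if not cols:
                    return np.array([])
                return np.concatenate([np.asarray(values[c]) for c in cols])

            delta_cont = (
                convergence_delta(
                    stacked(cont_active, old), stacked(cont_active, new), "continuous"
                )
                if cont_active
                else np.nan
            )
            delta_cat = (
                convergence_delta(
                    stacked(cat_active, old), stacked(cat_active, new), "categorical"
                )
                if cat_active
                else np.nan
            )
            iterations_run = iteration
            trace_rows.append(
                {
                    "iteration": iteration,
                    "delta_continuous": delta_cont,
                    "delta_categorical": delta_cat,
                }
            )
            final = work
            if cfg.stop_rule == "first_increase" and iteration >= 2:
                cont_up = not cont_active or delta_cont > prev_delta_cont
                cat_up = not cat_active or delta_cat > prev_delta_cat
                if cont_up and cat_up:
                    # return the previous sweep's values, as in the
                    # reference algorithm
                    final = before_sweep
                    break
            if cfg.stop_rule == "threshold":
                total = np.nansum([delta_cont, delta_cat])
                if total < cfg.threshold:
                    break
            if cont_active:
                prev_delta_cont = delta_cont
            if cat_active:
                prev_delta_cat = delta_cat

        completed = final.copy()
        for col in active:
            mis = miss_mask[col].to_numpy()
            if col in self.table.catalog:
                spec = self.table.catalog[col]
                if cfg.clip_to_range:
                    completed.loc[mis, col] = completed.loc[mis, col].clip(
                        spec.score_min, spec.score_max
                    )
                if cfg.round_discrete and spec.discrete:
                    completed.loc[mis, col] = completed.loc[mis, col].round()
        out_table = VisitTable(self.table.catalog, completed, validate=False)
        return ImputationResult(
            completed=out_table,
            iterations_run=iterations_run,
            delta_trace=pd.DataFrame(trace_rows),
            imputed_mask=miss_mask,
            config=cfg,
        )


def impute(
    table: VisitTable,
    predictors: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
    config: ImputationConfig | None = None,
) -> ImputationResult:
    """Impute all missing values in ``table`` (convenience wrapper)."""
    return MissForestImputer(table, predictors, targets, config).fit()


def distribution_shift_report(before: VisitTable, after: VisitTable) -> pd.DataFrame:
    """Compare observed-only vs observed+imputed score distributions.

    For every test and cohort, reports the mean and SD of the originally
    observed values alongside the mean and SD after harmonization, plus
    absolute and relative differences.  Tests that are 100% structurally
    missing in a cohort carry only the harmonized statistics.
    """
    rows = []
    for cohort in before.cohort_ids:
        b = before.df[before.df["cohort_id"] == cohort]
        a = after.df[after.df["cohort_id"] == cohort]
        for tid in before.score_columns:
            obs = b[tid].dropna()
            harm = a[tid].dropna()
            row: dict[str, object] = {"cohort_id": cohort, "test_id": tid}
            if len(obs):
                row["observed_mean"] = float(obs.mean())
                row["observed_sd"] = float(obs.std(ddof=1)) if len(obs) > 1 else np.nan
            else:
                row["observed_mean"] = np.nan
                row["observed_sd"] = np.nan
            row["harmonized_mean"] = float(harm.mean()) if len(harm) else np.nan
            row["harmonized_sd"] = float(harm.std(ddof=1)) if len(harm) > 1 else np.nan
            row["abs_diff_mean"] = (
                abs(row["harmonized_mean"] - row["observed_mean"])
                if len(obs)
                else np.nan
            )
            row["rel_diff_mean"] = (
                row["abs_diff_mean"] / abs(row["observed_mean"])
                if len(obs) and row["observed_mean"] != 0
                else np.nan
            )
            row["structurally_missing"] = len(obs) == 0
            rows.append(row)
    return pd.DataFrame(rows)
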