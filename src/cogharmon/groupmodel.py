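"""Longitudinal mixed-effects validation of harmonized composites.

For each composite, a linear mixed-effects model is fitted over time and
clinical-pathological group (amyloid-negative CDR 0 as reference) with
baseline age, sex, years of education, and dataset-of-origin as fixed
covariates and correlated per-participant random intercepts and slopes on
time.  From the fit we derive estimated marginal means at time zero
(covariates at their sample means, cohort and sex averaged with equal
weights), estimated marginal trends (slopes per year), contrasts of each
group against the reference, Cohen's d effect sizes standardized by the
subject-level SD, and Benjamini-Hochberg FDR-adjusted p-values across the
full family of contrasts in a run.

:class:`CompositeGroupModel` is the model object; its :meth:`fit` returns
a :class:`GroupModelResult`.  :func:`analyze_composites` fits all
composites of an analysis and adjusts their contrasts jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .visits import ANALYSIS_GROUPS

__all__ = [
    "ModelSpec",
    "CompositeGroupModel",
    "GroupModelResult",
    "fdr_adjust",
    "analyze_composites",
    "plot_trajectories",
]

GROUP_ORDER = [g.value for g in ANALYSIS_GROUPS]


@dataclass
class ModelSpec:
    """Configuration of one composite's mixed model."""

    outcome: str
    window_years: float = 5.0
    reference: str = "ABNEG_CDR0"
    reml: bool = True

    def __post_init__(self) -> None:
        if self.window_years <= 0:
            raise ValueError("window_years must be > 0")


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class CompositeGroupModel:
    """Mixed-effects model of one composite over time and group.

    Parameters
    ----------
    data
        Composite table from :func:`cogharmon.composites.composite_scores`
        (columns: participant_id, cohort_id, time_years, group,
        baseline_age, sex, education_years, and the outcome).
    spec
        Outcome name, follow-up window, and reference group.

    Visits beyond the follow-up window are dropped (participants kept);
    participants outside the four analysis groups or with fewer than two
    remaining visits are dropped.  Age and education are centered at the
    sample mean so the marginal mean at time zero is evaluated at
    covariate means.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        df = data.copy()
        df = df[df["time_years"] <= spec.window_years]
        df = df[df["group"].isin(GROUP_ORDER)]
        df = df[df[spec.outcome].notna()]
        keep = df.groupby("participant_id")["time_years"].transform("size") >= 2
        df = df[keep].reset_index(drop=True)
        if df.empty:
            raise ValueError("no data left after window/group restrictions")
        if spec.reference not in set(df["group"]):
            raise ValueError(f"reference group {spec.reference} absent from data")
        self.age_center = float(df["baseline_age"].mean())
        self.edu_center = float(df["education_years"].mean())
        df["age_c"] = df["baseline_age"] - self.age_center
        df["edu_c"] = df["education_years"] - self.edu_center
        df["time"] = df["time_years"].astype(float)
        self.data = df
        self.groups_present = [g for g in GROUP_ORDER if g in set(df["group"])]
        self._formula = self._build_formula()

    def _build_formula(self) -> str:
        spec = self.spec
        terms = []
        if len(self.groups_present) > 1:
            terms.append(f"time * C(group, Treatment('{spec.reference}'))")
        else:
            terms.append("time")
        terms.append("age_c")
        if self.data["sex"].nunique() > 1:
            terms.append("C(sex)")
        terms.append("edu_c")
        if self.data["cohort_id"].nunique() > 1:
            terms.append("C(cohort_id)")
        return f"{spec.outcome} ~ " + " + ".join(terms)

    def fit(self) -> "GroupModelResult":
        """REML fit with correlated random intercept and slope.

        On non-convergence or a singular 2x2 random-effects covariance,
        refits with independent intercept and slope and flags the result.
        """
        df = self.data
        re_structure = "correlated"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                self._formula, groups="participant_id", re_formula="~time", data=df
            )
            res = None
            # conjugate gradient handles the near-boundary random-slope
            # variance well; powell is the robust backup
            for method in ("cg", "powell"):
                try:
                    cand = model.fit(reml=self.spec.reml, method=method, maxiter=500)
                except Exception:
                    continue
                cov_re = np.asarray(cand.cov_re)
                ok = (
                    cand.converged
                    and np.all(np.diag(cov_re) > 0)
                    and np.linalg.det(cov_re) > 0
                )
                res = cand
                if ok:
                    break
            else:
                re_structure = "independent"
                model = MixedLM.from_formula(
                    self._formula,
                    groups="participant_id",
                    re_formula="1",
                    vc_formula={"slope": "0 + time"},
                    data=df,
                )
                res = model.fit(reml=self.spec.reml, method="cg", maxiter=500)
        return GroupModelResult(self, res, re_structure)


class GroupModelResult:
    """Estimates, uncertainties, and diagnostics from one composite fit."""

    def __init__(self, model: CompositeGroupModel, result, re_structure: str):
        self.model = model
        self.result = result
        self.re_structure = re_structure
        self.converged = bool(result.converged)
        self.spec = model.spec
        self._design_info = result.model.data.design_info
        k = len(result.fe_params)
        self._fe = np.asarray(result.fe_params)
        self._cov_fe = np.asarray(result.cov_params())[:k, :k]

    # ------------------------------------------------------------------
    # variance components
    # ------------------------------------------------------------------
    @property
    def variance_components(self) -> dict[str, float]:
        res = self.result
        if self.re_structure == "correlated":
            cov_re = np.asarray(res.cov_re)
            var_int = float(cov_re[0, 0])
            var_slope = float(cov_re[1, 1])
        else:
            var_int = float(np.asarray(res.cov_re)[0, 0])
            var_slope = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        return {
            "random_intercept_sd": float(np.sqrt(max(var_int, 0.0))),
            "random_slope_sd": float(np.sqrt(max(var_slope, 0.0))),
            "residual_sd": float(np.sqrt(res.scale)),
        }

    @property
    def subject_level_sd(self) -> float:
        """sqrt(random-intercept variance + residual variance)."""
        vc = self.variance_components
        val = vc["random_intercept_sd"] ** 2 + vc["residual_sd"] ** 2
        if val <= 0:
            raise ValueError("nonpositive variance estimate")
        return float(np.sqrt(val))

    # ------------------------------------------------------------------
    # marginal estimates
    # ------------------------------------------------------------------
    def _grid(self, group: str, time: float) -> pd.DataFrame:
        """Balanced grid over cohort and sex, covariates at centers."""
        df = self.model.data
        cohorts = sorted(df["cohort_id"].unique())
        sexes = sorted(df["sex"].unique())
        rows = [
            {
                "time": time,
                "group": group,
                "age_c": 0.0,
                "edu_c": 0.0,
                "sex": s,
                "cohort_id": c,
            }
            for c in cohorts
            for s in sexes
        ]
        return pd.DataFrame(rows)

    def _lincomb(self, grid: pd.DataFrame) -> np.ndarray:
        """Row-averaged fixed-effects design vector for a grid."""
        (X,) = build_design_matrices([self._design_info], grid)
        return np.asarray(X).mean(axis=0)

    def _estimate(self, L: np.ndarray) -> tuple[float, float]:
        est = float(L @ self._fe)
        se = float(np.sqrt(L @ self._cov_fe @ L))
        return est, se

    def marginal_baseline_means(self) -> pd.DataFrame:
        """Per-group estimated marginal mean at time zero (+/- SE)."""
        rows = []
        for g in self.model.groups_present:
            L = self._lincomb(self._grid(g, 0.0))
            est, se = self._estimate(L)
            rows.append({"group": g, "estimate": est, "se": se})
        return pd.DataFrame(rows)

    def marginal_slopes(self) -> pd.DataFrame:
        """Per-group estimated marginal trend (outcome units per year)."""
        rows = []
        for g in self.model.groups_present:
            L = self._lincomb(self._grid(g, 1.0)) - self._lincomb(self._grid(g, 0.0))
            est, se = self._estimate(L)
            rows.append({"group": g, "estimate": est, "se": se})
        return pd.DataFrame(rows)

    def contrasts(self, fdr: bool = True) -> pd.DataFrame:
        """Each group vs the reference: intercept and slope contrasts.

        Cohen's d standardizes intercept contrasts by the subject-level
        SD; slope contrasts are first multiplied by the follow-up window
        (model-implied difference in change at the horizon) and then
        standardized by the same SD.
        """
        ref = self.spec.reference
        sd = self.subject_level_sd
        window = self.spec.window_years
        rows = []
        L_ref_mean = self._lincomb(self._grid(ref, 0.0))
        L_ref_slope = self._lincomb(self._grid(ref, 1.0)) - L_ref_mean
        for g in self.model.groups_present:
            if g == ref:
                continue
            L_mean = self._lincomb(self._grid(g, 0.0))
            L_slope = self._lincomb(self._grid(g, 1.0)) - L_mean
            for kind, L, scale in (
                ("intercept", L_mean - L_ref_mean, 1.0),
                ("slope", L_slope - L_ref_slope, window),
            ):
                est, se = self._estimate(L)
                z = est / se
                p = float(2 * stats.norm.sf(abs(z)))
                rows.append(
                    {
                        "outcome": self.spec.outcome,
                        "group": g,
                        "kind": kind,
                        "estimate": est,
                        "se": se,
                        "cohen_d": est * scale / sd,
                        "z": z,
                        "p": p,
                    }
                )
        out = pd.DataFrame(rows)
        if fdr and len(out):
            out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
        return out

    # ------------------------------------------------------------------
    def summary(self) -> str:
        vc = self.variance_components
        lines = [
            f"Mixed-effects model for composite {self.spec.outcome!r}",
            f"  observations: {len(self.model.data)}  "
            f"participants: {self.model.data['participant_id'].nunique()}",
            f"  random effects: {self.re_structure}  converged: {self.converged}",
            f"  random-intercept SD {vc['random_intercept_sd']:.3f}  "
            f"random-slope SD {vc['random_slope_sd']:.3f}  "
            f"residual SD {vc['residual_sd']:.3f}",
            "",
            "Estimated marginal means at time zero:",
            self.marginal_baseline_means().to_string(index=False),
            "",
            "Estimated marginal trends (per year):",
            self.marginal_slopes().to_string(index=False),
            "",
            f"Contrasts vs {self.spec.reference}:",
            self.contrasts().to_string(index=False),
        ]
        return "\n".join(lines)


def analyze_composites(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    window_years: float = 5.0,
    reference: str = "ABNEG_CDR0",
) -> tuple[dict[str, GroupModelResult], pd.DataFrame]:
    """Fit every composite's model and FDR-adjust contrasts jointly.

    The FDR family is the full set of intercept and slope contrasts
    across all composites in the run.
    """
    results: dict[str, GroupModelResult] = {}
    tables = []
    for outcome in outcomes:
        spec = ModelSpec(outcome=outcome, window_years=window_years, reference=reference)
        res = CompositeGroupModel(data, spec).fit()
        results[outcome] = res
        tables.append(res.contrasts(fdr=False))
    contrasts = pd.concat(tables, ignore_index=True)
    contrasts["p_fdr"] = fdr_adjust(contrasts["p"].to_numpy())
    return results, contrasts


def plot_trajectories(results: dict[str, GroupModelResult], path=None):
    """Model-implied group trajectories per composite (one panel each)."""
    import matplotlib

    matplotlib.use("Agg")
    # fixed hash salt + no date metadata -> byte-identical SVG on rerun
    matplotlib.rcParams["svg.hashsalt"] = "cogharmon"
    import matplotlib.pyplot as plt

    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
    for ax, (name, res) in zip(axes[0], results.items()):
        means = res.marginal_baseline_means().set_index("group")["estimate"]
        slopes = res.marginal_slopes().set_index("group")["estimate"]
        t = np.linspace(0, res.spec.window_years, 50)
        for g in res.model.groups_present:
            ax.plot(t, means[g] + slopes[g] * t, label=g)
        ax.set_title(name)
        ax.set_xlabel("years from first visit")
        ax.set_ylabel("composite (z)")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        # drop the creation-date metadata so reruns are byte-identical
        fig.savefig(path, metadata={"Date": None})
        plt.close(fig)
    return fig
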