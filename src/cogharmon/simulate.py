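"""Synthetic multi-cohort neuropsychological data with known ground truth.

The generator emulates three longitudinal aging cohorts (named AIBL,
ADNI, OASIS after the study designs they imitate; all data are synthetic)
whose batteries overlap only partially, so that several tests are
structurally missing — never administered — in one or two cohorts.

Each participant belongs to a clinical-pathological group (amyloid x CDR)
that fixes a latent cognitive trajectory per domain: a group-level
baseline deficit and annual slope, in units of the reference-group
between-person SD, plus correlated participant-level random intercepts
and slopes shared across domains.  A test score is an affine function of
its domain's latent value plus Gaussian test-retest noise, clamped to the
instrument's range (which induces realistic ceiling effects, e.g. for the
MMSE) and rounded when the raw score is integer-valued.  Sporadic
missing-at-random gaps depend only on cohort and CDR stratum, never on
the unobserved score itself.  Visit cadence differs by cohort (6-monthly,
18-monthly, annual).

The returned :class:`GroundTruth` records every pre-masking score —
including tests the cohort "does not administer" — so downstream modules
can be scored against truth, notably the structural-imputation error that
real data can never reveal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import TestCatalog, default_catalog
from .impute import ImputationResult
from .visits import VisitTable

__all__ = [
    "CohortProfile",
    "TestModel",
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "generate",
    "truth_mae",
]

#: Latent domains carried by the generator.
LATENT_DOMAINS = ("episodic_memory", "executive_function", "language")

GROUPS = ("ABNEG_CDR0", "ABPOS_CDR0", "ABPOS_CDR05", "ABPOS_CDR1")

#: CDR level implied by each group label.
GROUP_CDR = {"ABNEG_CDR0": 0.0, "ABPOS_CDR0": 0.0, "ABPOS_CDR05": 0.5, "ABPOS_CDR1": 1.0}

GROUP_DIAGNOSIS = {0.0: "cu", 0.5: "mci", 1.0: "ad"}


@dataclass(frozen=True)
class CohortProfile:
    """Per-cohort design parameters."""

    n_participants: int = 100
    visit_spacing_years: float = 1.0
    mar_rate: float = 0.05
    age_mean: float = 73.0
    age_sd: float = 7.0
    education_mean: float = 14.0
    education_sd: float = 3.0
    female_fraction: float = 0.5


@dataclass(frozen=True)
class TestModel:
    """Affine score model for one test: mean + direction*scale*L + noise."""

    mean: float
    scale: float
    noise_sd: float


#: Variance of the latent value across the whole simulated population:
#: unit within-group (random-intercept) variance plus ~1.0 between-group
#: mixture variance under the default group proportions and deficits.
_LATENT_VARIANCE_TOTAL = 2.0


def _default_test_models() -> dict[str, TestModel]:
    # population mean, whole-sample SD, and test-retest noise SD chosen
    # to mimic the marginal distributions and retest variability of the
    # instruments in elderly research cohorts; the affine scale is set so
    # the group *mixture* reproduces the whole-sample SD
    raw: dict[str, tuple[float, float, float]] = {
        "MMSE": (26.93, 4.25, 0.85),
        "LMII": (9.52, 5.90, 1.80),
        "RAVLT_total_learning": (35.67, 13.83, 4.90),
        "RAVLT_delayed_recall": (4.62, 4.58, 1.90),
        "RAVLT_recognition_hits": (10.66, 4.06, 1.20),
        "CVLT_total_learning": (46.33, 15.90, 4.60),
        "CVLT_delayed_recall": (9.78, 4.87, 1.35),
        "CVLT_recognition_hits": (14.42, 2.24, 0.67),
        "SRT_FREE": (28.46, 8.51, 2.50),
        "TMT_B": (113.89, 72.82, 15.40),
        "digit_symbol_coding": (56.89, 17.00, 4.70),
        "digit_span_forward": (8.86, 2.54, 0.92),
        "digit_span_backward": (6.05, 2.22, 0.99),
        "BNT_no_cue": (26.39, 4.57, 0.72),
        "category_fluency_animals": (17.71, 6.05, 2.67),
        "verbal_fluency_switching": (10.83, 3.94, 2.00),
    }
    out = {}
    for tid, (mean, sd, noise) in raw.items():
        scale = float(
            np.sqrt(max((sd**2 - noise**2) / _LATENT_VARIANCE_TOTAL, 1e-6))
        )
        out[tid] = TestModel(mean=mean, scale=scale, noise_sd=noise)
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic three-cohort dataset.

    Group proportions, baseline latent deficits, and latent slopes define
    the clinical-pathological structure; cohort profiles define sample
    sizes, visit cadence, demographics, and sporadic missing-at-random
    rates.  ``shared_variance_fraction`` is the fraction of random-
    intercept (and slope) variance shared across domains, which is what
    lets tests from one domain inform imputation of another.
    """

    catalog: TestCatalog = field(default_factory=default_catalog)
    cohorts: Mapping[str, CohortProfile] = field(
        default_factory=lambda: {
            "AIBL": CohortProfile(
                n_participants=100,
                visit_spacing_years=1.5,
                mar_rate=0.05,
                age_mean=72.3,
                education_mean=12.9,
                education_sd=3.1,
            ),
            "ADNI": CohortProfile(
                n_participants=100,
                visit_spacing_years=0.5,
                mar_rate=0.19,
                age_mean=74.0,
                education_mean=16.2,
                education_sd=2.6,
            ),
            "OASIS": CohortProfile(
                n_participants=100,
                visit_spacing_years=1.0,
                mar_rate=0.02,
                age_mean=73.5,
                education_mean=15.7,
                education_sd=2.6,
            ),
        }
    )
    group_proportions: tuple[float, float, float, float] = (
        # proportional to 1198 : 524 : 995 : 433
        0.38032,
        0.16635,
        0.31587,
        0.13746,
    )
    baseline_deficits: tuple[float, float, float, float] = (0.0, -0.2, -1.5, -2.8)
    slopes_per_year: tuple[float, float, float, float] = (0.0, -0.05, -0.25, -0.45)
    min_visits: int = 3
    max_visits: int = 5
    random_intercept_sd: float = 1.0
    random_slope_sd: float = 0.05
    shared_variance_fraction: float = 0.6
    mar_cdr_multiplier: Mapping[float, float] = field(
        default_factory=lambda: {0.0: 1.0, 0.5: 1.2, 1.0: 1.5}
    )
    apoe_carrier_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "ABNEG_CDR0": 0.30,
            "ABPOS_CDR0": 0.55,
            "ABPOS_CDR05": 0.62,
            "ABPOS_CDR1": 0.68,
        }
    )
    test_models: Mapping[str, TestModel] = field(default_factory=_default_test_models)
    noise_sd_scale: float = 1.0  # global multiplier on test-retest noise

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions) - 1.0) > 1e-6:
            raise ValueError("group_proportions must sum to 1")
        if self.min_visits < 3:
            raise ValueError("min_visits must be >= 3")
        if self.max_visits < self.min_visits:
            raise ValueError("max_visits must be >= min_visits")
        for tid in self.catalog.test_ids:
            if tid not in self.test_models:
                raise ValueError(f"no test model for catalogued test {tid!r}")
            if self.test_models[tid].noise_sd <= 0:
                raise ValueError(f"noise SD must be > 0 for {tid!r}")

    def with_sizes(self, n_participants: int) -> "GeneratorConfig":
        """Copy with every cohort resized to ``n_participants``."""
        cohorts = {
            cid: replace(prof, n_participants=n_participants)
            for cid, prof in self.cohorts.items()
        }
        return replace(self, cohorts=cohorts)


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


def single_absent_catalog() -> TestCatalog:
    """Reduced catalog: shared anchors plus one cohort-specific test each.

    Keeps the six tests every cohort administers and exactly one test per
    cohort that the other two lack (CVLT-II delayed recall / RAVLT
    delayed recall / SRT-FREE), giving the simplest design in which every
    cohort has one structurally missing target with same-domain donors.
    """
    keep = {
        "MMSE",
        "LMII",
        "digit_span_forward",
        "digit_span_backward",
        "BNT_no_cue",
        "category_fluency_animals",
        "CVLT_delayed_recall",
        "RAVLT_delayed_recall",
        "SRT_FREE",
    }
    return TestCatalog([s for s in default_catalog() if s.test_id in keep])


@dataclass
class GroundTruth:
    """Everything the generator knows that the visit tables hide.

    Attributes
    ----------
    true_scores
        One row per visit with the pre-masking score of *every* test,
        including tests outside the cohort's panel, plus the per-visit
        latent domain values.
    participants
        Per participant: cohort, group label, and per-domain latent
        intercept and slope.
    """

    true_scores: pd.DataFrame
    participants: pd.DataFrame


def _draw_centiloid(rng: np.random.Generator, group: str) -> float:
    if group == "ABNEG_CDR0":
        return float(rng.uniform(-15.0, 24.9))
    loc = {"ABPOS_CDR0": 20.0, "ABPOS_CDR05": 40.0, "ABPOS_CDR1": 55.0}[group]
    sd = {"ABPOS_CDR0": 15.0, "ABPOS_CDR05": 25.0, "ABPOS_CDR1": 30.0}[group]
    return float(min(25.0 + abs(rng.normal(loc, sd)) + 0.1, 200.0))


def generate(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[list[VisitTable], GroundTruth]:
    """Generate the three synthetic cohorts and their ground truth.

    Deterministic under a fixed seed.  Participant ids are globally
    unique (``<cohort>:p<number>``), so merging leaves them unchanged and
    ground truth aligns with the merged table on
    (participant_id, visit_index).
    """
    config = config or default_config()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    catalog = config.catalog
    rho = config.shared_variance_fraction

    tables: list[VisitTable] = []
    truth_rows: list[dict] = []
    part_rows: list[dict] = []

    # normalization so the global latent (mean of domains) has unit
    # variance in the reference group
    global_sd = float(np.sqrt((1.0 + 2.0 * rho) / 3.0))

    for cohort_id, prof in config.cohorts.items():
        visit_rows: list[dict] = []
        for i in range(prof.n_participants):
            pid = f"{cohort_id}:p{i:04d}"
            g_idx = int(rng.choice(len(GROUPS), p=config.group_proportions))
            group = GROUPS[g_idx]
            cdr = GROUP_CDR[group]
            deficit = config.baseline_deficits[g_idx]
            slope = config.slopes_per_year[g_idx]

            shared_int = rng.normal()
            shared_slo = rng.normal()
            intercepts = {}
            slopes = {}
            for d in LATENT_DOMAINS:
                own_int = rng.normal()
                own_slo = rng.normal()
                b0 = config.random_intercept_sd * (
                    np.sqrt(rho) * shared_int + np.sqrt(1 - rho) * own_int
                )
                b1 = config.random_slope_sd * (
                    np.sqrt(rho) * shared_slo + np.sqrt(1 - rho) * own_slo
                )
                intercepts[d] = deficit + b0
                slopes[d] = slope + b1

            age0 = float(rng.normal(prof.age_mean, prof.age_sd))
            sex = "female" if rng.random() < prof.female_fraction else "male"
            edu = float(
                np.clip(rng.normal(prof.education_mean, prof.education_sd), 5, 22)
            )
            apoe = (
                "carrier"
                if rng.random() < config.apoe_carrier_prob[group]
                else "non-carrier"
            )
            centiloid = _draw_centiloid(rng, group)
            n_visits = int(rng.integers(config.min_visits, config.max_visits + 1))

            part_rows.append(
                {
                    "participant_id": pid,
                    "cohort_id": cohort_id,
                    "group": group,
                    **{f"intercept_{d}": intercepts[d] for d in LATENT_DOMAINS},
                    **{f"slope_{d}": slopes[d] for d in LATENT_DOMAINS},
                }
            )

            panel = set(catalog.panel(cohort_id))
            for v in range(n_visits):
                t = v * prof.visit_spacing_years
                latent = {d: intercepts[d] + slopes[d] * t for d in LATENT_DOMAINS}
                latent["global"] = float(np.mean(list(latent.values()))) / global_sd

                true_scores: dict[str, float] = {}
                observed: dict[str, float] = {}
                for spec in catalog:
                    tm = config.test_models[spec.test_id]
                    L = latent[spec.domain]
                    noise = rng.normal(0.0, tm.noise_sd * config.noise_sd_scale)
                    val = tm.mean + spec.direction * tm.scale * L + noise
                    val = float(np.clip(val, spec.score_min, spec.score_max))
                    if spec.discrete:
                        val = float(round(val))
                    true_scores[spec.test_id] = val
                    if spec.test_id in panel:
                        p_miss = min(
                            prof.mar_rate * config.mar_cdr_multiplier[cdr], 0.95
                        )
                        if rng.random() >= p_miss:
                            observed[spec.test_id] = val

                base = {
                    "participant_id": pid,
                    "cohort_id": cohort_id,
                    "visit_index": v,
                    "time_years": t,
                    "age_years": age0 + t,
                    "sex": sex,
                    "education_years": edu,
                    "apoe4": apoe,
                    "cdr": cdr,
                    "centiloid": centiloid,
                    "diagnosis": GROUP_DIAGNOSIS[cdr],
                }
                visit_rows.append({**base, **observed})
                truth_rows.append(
                    {
                        **base,
                        "group": group,
                        **true_scores,
                        **{f"latent_{d}": latent[d] for d in latent},
                    }
                )
        tables.append(VisitTable(catalog, pd.DataFrame(visit_rows)))

    truth = GroundTruth(
        true_scores=pd.DataFrame(truth_rows),
        participants=pd.DataFrame(part_rows),
    )
    return tables, truth


def truth_mae(
    imputation: ImputationResult,
    truth: GroundTruth,
    scope: str = "structural",
    tests: Sequence[str] | None = None,
) -> pd.Series:
    """Per-test MAE of imputed cells against generator ground truth.

    ``scope='structural'`` scores cells of tests outside their cohort's
    panel; ``scope='sporadic'`` scores administered-but-missing cells.
    Tests with no cells in scope are absent from the result.
    """
    if scope not in ("structural", "sporadic"):
        raise ValueError(f"scope must be 'structural' or 'sporadic', got {scope!r}")
    completed = imputation.completed
    catalog = completed.catalog
    tests = list(tests) if tests is not None else catalog.test_ids
    keys = ["participant_id", "visit_index"]
    truth_idx = truth.true_scores.set_index(keys)
    comp = completed.df.set_index(keys)
    mask = imputation.imputed_mask.copy()
    mask.index = completed.df.set_index(keys).index
    out = {}
    for tid in tests:
        if tid not in mask.columns:
            continue
        in_panel = comp["cohort_id"].map(
            lambda c, t=tid: c in catalog[t].administered_in
        )
        cells = mask[tid] & (~in_panel if scope == "structural" else in_panel)
        if not cells.any():
            continue
        pred = comp.loc[cells, tid].to_numpy(float)
        actual = truth_idx.loc[comp.index[cells], tid].to_numpy(float)
        out[tid] = float(np.mean(np.abs(pred - actual)))
    return pd.Series(out, name=f"mae_{scope}")
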