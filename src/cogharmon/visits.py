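"""Long-format participant-visit tables and the merged multi-cohort dataset.

A :class:`VisitTable` pairs a :class:`~cogharmon.catalog.TestCatalog` with a
pandas DataFrame holding one row per participant-visit: identifiers, visit
timing, demographics, APOE e4 carriage, CDR global score, amyloid burden on
the Centiloid scale, a per-participant diagnosis flag, and one column per
catalogued test.  Missing scores are NaN in memory and empty fields (or the
literal string ``NA``) on disk.

The module also implements the cohort-merging step of the harmonization
procedure (:func:`build_merged_table`), the inclusion criteria
(:func:`apply_inclusion_criteria`), clinical-pathological group labelling
from amyloid status and CDR (:func:`assign_group_label`), and the
missing-data summary (:func:`missingness_summary`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import TestCatalog

__all__ = [
    "VisitTable",
    "GroupLabel",
    "ExclusionLog",
    "ID_COLUMNS",
    "COVARIATE_COLUMNS",
    "CATEGORICAL_LEVELS",
    "assign_group_label",
    "add_group_labels",
    "build_merged_table",
    "apply_inclusion_criteria",
    "missingness_summary",
]

ID_COLUMNS = ["participant_id", "cohort_id", "visit_index", "time_years"]
COVARIATE_COLUMNS = [
    "age_years",
    "sex",
    "education_years",
    "apoe4",
    "cdr",
    "centiloid",
    "diagnosis",
]

CATEGORICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "apoe4": ("carrier", "non-carrier"),
    "diagnosis": ("cu", "mci", "ad", "non_ad", "unknown"),
}

#: CDR global scores after collapsing CDR >= 1 into a single category.
CDR_LEVELS = (0.0, 0.5, 1.0)

#: Centiloid threshold for amyloid positivity (strict inequality).
CENTILOID_THRESHOLD = 25.0


class GroupLabel(str, enum.Enum):
    """Clinical-pathological group from amyloid status x CDR."""

    ABNEG_CDR0 = "ABNEG_CDR0"
    ABPOS_CDR0 = "ABPOS_CDR0"
    ABPOS_CDR05 = "ABPOS_CDR05"
    ABPOS_CDR1 = "ABPOS_CDR1"
    EXCLUDED = "EXCLUDED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four analysis groups (EXCLUDED dropped), in severity order.
ANALYSIS_GROUPS = (
    GroupLabel.ABNEG_CDR0,
    GroupLabel.ABPOS_CDR0,
    GroupLabel.ABPOS_CDR05,
    GroupLabel.ABPOS_CDR1,
)


def assign_group_label(
    centiloid: float | None,
    cdr: float,
    threshold: float = CENTILOID_THRESHOLD,
) -> GroupLabel:
    """Map (Centiloid, CDR) to a clinical-pathological group label.

    Amyloid positivity is ``centiloid > threshold`` (strict; equality is
    negative).  Amyloid-negative participants with cognitive symptoms
    (CDR > 0) and participants without an amyloid measure are EXCLUDED.
    """
    if cdr not in CDR_LEVELS:
        raise ValueError(f"cdr must be one of {CDR_LEVELS}, got {cdr!r}")
    if centiloid is None or (isinstance(centiloid, float) and np.isnan(centiloid)):
        return GroupLabel.EXCLUDED
    if centiloid > threshold:
        if cdr == 0:
            return GroupLabel.ABPOS_CDR0
        if cdr == 0.5:
            return GroupLabel.ABPOS_CDR05
        return GroupLabel.ABPOS_CDR1
    return GroupLabel.ABNEG_CDR0 if cdr == 0 else GroupLabel.EXCLUDED


@dataclass
class ExclusionLog:
    """Counts of rows/participants removed by each inclusion rule."""

    visits_no_scores: int = 0
    participants_non_ad_diagnosis: int = 0
    participants_min_assessments: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {
            "visits_no_scores": self.visits_no_scores,
            "participants_non_ad_diagnosis": self.participants_non_ad_diagnosis,
            "participants_min_assessments": self.participants_min_assessments,
        }


class VisitTable:
    """A catalog plus one row per participant-visit.

    Parameters
    ----------
    catalog
        Test catalog; one score column per test is expected (created as
        all-missing if absent).
    df
        Long-format frame with the identifier and covariate columns and
        one numeric column per catalogued test.
    validate
        Run the structural invariants on construction (default True).
    """

    def __init__(self, catalog: TestCatalog, df: pd.DataFrame, *, validate: bool = True):
        self.catalog = catalog
        df = df.copy().reset_index(drop=True)
        for col in ID_COLUMNS + COVARIATE_COLUMNS:
            if col not in df.columns:
                if col == "diagnosis":
                    df[col] = "cu"
                else:
                    raise ValueError(f"missing required column {col!r}")
        for tid in catalog.test_ids:
            if tid not in df.columns:
                df[tid] = np.nan
            df[tid] = pd.to_numeric(df[tid], errors="coerce")
        extra = [c for c in df.columns if c not in self.expected_columns(catalog)]
        order = [c for c in self.expected_columns(catalog) if c in df.columns] + extra
        self.df = df[order]
        if validate:
            self.validate()

    @staticmethod
    def expected_columns(catalog: TestCatalog) -> list[str]:
        return ID_COLUMNS + COVARIATE_COLUMNS + catalog.test_ids

    # ------------------------------------------------------------------
    @property
    def score_columns(self) -> list[str]:
        return self.catalog.test_ids

    @property
    def n_visits(self) -> int:
        return len(self.df)

    @property
    def n_participants(self) -> int:
        return self.df["participant_id"].nunique()

    @property
    def cohort_ids(self) -> list[str]:
        return sorted(self.df["cohort_id"].unique())

    def scores(self) -> pd.DataFrame:
        """The score block (one column per test), view-copy."""
        return self.df[self.score_columns].copy()

    def copy(self) -> "VisitTable":
        return VisitTable(self.catalog, self.df.copy(), validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VisitTable):
            return NotImplemented
        if self.catalog != other.catalog:
            return False
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_like=True)
        except AssertionError:
            return False
        return True

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        df = self.df
        dup = df.duplicated(subset=["participant_id", "visit_index"])
        if dup.any():
            raise ValueError(
                f"duplicate (participant_id, visit_index): "
                f"{df.loc[dup, ['participant_id', 'visit_index']].head().to_dict('records')}"
            )
        multi = df.groupby("participant_id")["cohort_id"].nunique()
        if (multi > 1).any():
            raise ValueError(
                f"participants in more than one cohort: {list(multi[multi > 1].index[:5])}"
            )
        bad_cdr = ~df["cdr"].isin(CDR_LEVELS)
        if bad_cdr.any():
            raise ValueError(f"invalid CDR values: {sorted(df.loc[bad_cdr, 'cdr'].unique())}")
        if (df["time_years"] < 0).any():
            raise ValueError("negative time_years")
        t0 = df.loc[df["visit_index"] == 0, "time_years"]
        if not np.allclose(t0, 0.0):
            raise ValueError("time_years must be 0 at visit_index 0")
        for spec in self.catalog:
            vals = df[spec.test_id]
            out = vals.notna() & ((vals < spec.score_min) | (vals > spec.score_max))
            if out.any():
                raise ValueError(
                    f"{spec.test_id}: {int(out.sum())} scores outside "
                    f"[{spec.score_min}, {spec.score_max}]"
                )

    def check_structural_missingness(self) -> None:
        """Ensure tests outside a cohort's panel are all-missing there."""
        for cohort in self.cohort_ids:
            rows = self.df["cohort_id"] == cohort
            panel = set(self.catalog.panel(cohort))
            for tid in self.score_columns:
                if tid not in panel and self.df.loc[rows, tid].notna().any():
                    raise ValueError(
                        f"test {tid} has observed scores in cohort {cohort} "
                        "but is outside its panel"
                    )

    def enforce_structural_missingness(self) -> None:
        """Blank any score recorded for a test outside its cohort's panel."""
        for cohort in self.cohort_ids:
            rows = self.df["cohort_id"] == cohort
            panel = set(self.catalog.panel(cohort))
            for tid in self.score_columns:
                if tid not in panel:
                    self.df.loc[rows, tid] = np.nan

    # ------------------------------------------------------------------
    # delimited-text I/O
    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(
        cls, path: str | Path, catalog: TestCatalog, *, validate: bool = True
    ) -> "VisitTable":
        df = pd.read_csv(
            path,
            na_values=["", "NA"],
            keep_default_na=False,
            dtype={"participant_id": str, "cohort_id": str},
        )
        df["visit_index"] = df["visit_index"].astype(int)
        for col in ("time_years", "age_years", "education_years", "cdr", "centiloid"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        return cls(catalog, df, validate=validate)


def add_group_labels(table: VisitTable, threshold: float = CENTILOID_THRESHOLD) -> VisitTable:
    """Attach a time-invariant ``group`` column per participant.

    The label is derived from the baseline (visit_index 0) Centiloid value
    and the baseline CDR, and held fixed across each participant's visits.
    """
    out = table.copy()
    base = out.df[out.df["visit_index"] == 0].set_index("participant_id")
    labels = {
        pid: assign_group_label(
            None if pd.isna(row["centiloid"]) else float(row["centiloid"]),
            float(row["cdr"]),
            threshold,
        ).value
        for pid, row in base.iterrows()
    }
    out.df["group"] = out.df["participant_id"].map(labels)
    return out


def build_merged_table(cohort_tables: Iterable[VisitTable]) -> VisitTable:
    """Concatenate per-cohort visit tables into one merged dataset.

    Participant ids are prefixed with their cohort id (``AIBL:p001``)
    unless already so prefixed; every test outside a cohort's panel is
    forced missing in that cohort's rows; the dataset-of-origin id is kept
    in ``cohort_id``.
    """
    tables = list(cohort_tables)
    if not tables:
        raise ValueError("no tables to merge")
    catalog = tables[0].catalog
    for t in tables[1:]:
        if t.catalog != catalog:
            raise ValueError("catalog mismatch between cohort tables")
    seen: set[str] = set()
    frames = []
    for t in tables:
        for cid in t.cohort_ids:
            if cid in seen:
                raise ValueError(f"cohort id {cid} appears in more than one input table")
            seen.add(cid)
        df = t.df.copy()
        prefix = df["cohort_id"].astype(str) + ":"
        pid = df["participant_id"].astype(str)
        needs = np.array([not p.startswith(pre) for p, pre in zip(pid, prefix)])
        df["participant_id"] = np.where(needs, prefix + pid, pid)
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    dup = merged.duplicated(subset=["participant_id", "visit_index"])
    if dup.any():
        raise ValueError("duplicate (participant_id, visit_index) after merge")
    out = VisitTable(catalog, merged, validate=False)
    out.enforce_structural_missingness()
    out.validate()
    return out


def _recompute_visit_timing(df: pd.DataFrame) -> pd.DataFrame:
    """Re-index visits 0..k-1 per participant and re-origin time_years."""
    df = df.sort_values(["participant_id", "time_years", "visit_index"], kind="mergesort")
    df["visit_index"] = df.groupby("participant_id").cumcount()
    df["time_years"] = df["time_years"] - df.groupby("participant_id")["time_years"].transform(
        "min"
    )
    return df.reset_index(drop=True)


def apply_inclusion_criteria(
    table: VisitTable, min_assessments: int = 3
) -> tuple[VisitTable, ExclusionLog]:
    """Apply the study inclusion criteria to a visit table.

    Rules, in order: (1) drop visits with no neuropsychological scores
    (demographics/CDR-only records); (2) drop participants flagged with a
    non-AD-spectrum dementia diagnosis or with no recorded diagnosis;
    (3) drop participants with fewer than ``min_assessments`` remaining
    visits.  Visit indices and time origins are recomputed afterwards.
    """
    log = ExclusionLog()
    df = table.df.copy()
    score_cols = table.score_columns

    has_scores = df[score_cols].notna().any(axis=1)
    log.visits_no_scores = int((~has_scores).sum())
    df = df[has_scores]

    diag = df.groupby("participant_id")["diagnosis"].first()
    bad = diag[diag.isin(["non_ad", "unknown"]) | diag.isna()].index
    log.participants_non_ad_diagnosis = len(bad)
    df = df[~df["participant_id"].isin(bad)]

    counts = df.groupby("participant_id")["visit_index"].size()
    few = counts[counts < min_assessments].index
    log.participants_min_assessments = len(few)
    df = df[~df["participant_id"].isin(few)]

    if df.empty:
        log.notes.append("empty cohort after applying inclusion criteria")
        return VisitTable(table.catalog, df.assign(), validate=False), log

    df = _recompute_visit_timing(df)
    return VisitTable(table.catalog, df), log


def missingness_summary(table: VisitTable) -> pd.DataFrame:
    """Per-test availability and %missing, overall and by CDR stratum.

    %missing is ``(N - n) / N * 100`` where ``N`` is the number of visits
    in scope and ``n`` the number with a present score.  Rows cover every
    test per cohort and for the merged table, plus an all-test average;
    strata are ``all`` and the three CDR levels.
    """
    rows = []
    scopes: list[tuple[str, pd.DataFrame]] = [("merged", table.df)]
    for cohort in table.cohort_ids:
        scopes.append((cohort, table.df[table.df["cohort_id"] == cohort]))
    for scope_name, scope_df in scopes:
        strata: list[tuple[str, pd.DataFrame]] = [("all", scope_df)]
        for level in CDR_LEVELS:
            strata.append((f"cdr_{level:g}", scope_df[scope_df["cdr"] == level]))
        for stratum_name, sdf in strata:
            N = len(sdf)
            pcts = []
            for tid in table.score_columns:
                n = int(sdf[tid].notna().sum())
                pct = float("nan") if N == 0 else 100.0 * (N - n) / N
                pcts.append(pct)
                rows.append(
                    {
                        "scope": scope_name,
                        "stratum": stratum_name,
                        "test_id": tid,
                        "n_visits": N,
                        "n_available": n,
                        "pct_missing": pct,
                    }
                )
            rows.append(
                {
                    "scope": scope_name,
                    "stratum": stratum_name,
                    "test_id": "AVERAGE",
                    "n_visits": N,
                    "n_available": int(np.mean([r["n_available"] for r in rows[-len(pcts):]])),
                    "pct_missing": float(np.mean(pcts)) if N else float("nan"),
                }
            )
    return pd.DataFrame(rows)
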