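"""Standardized cognitive composite scores from the harmonized table.

Composites follow the standard four-step recipe: (1) compute the mean and
SD of each test's baseline values in the cognitively unimpaired (CU)
reference group, (2) express every score as a z-value against those
norms, (3) reverse the sign for tests scored in time or errors so higher
z always means better performance, and (4) average the member z-scores.
Defaults cover the PACC (MMSE, LMII, CVLT-II delayed recall, digit symbol
coding) and the episodic-memory, executive-function, and language domain
composites; apart from the PACC no test belongs to more than one domain
composite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import TestCatalog, TestSpec
from .visits import VisitTable, add_group_labels

__all__ = [
    "BaselineNorms",
    "CompositeSpec",
    "default_composites",
    "fit_baseline_norms",
    "standardize",
    "composite_scores",
]


@dataclass(frozen=True)
class CompositeSpec:
    """A named composite and its member tests."""

    name: str
    members: tuple[str, ...]

    def validate_against(self, catalog: TestCatalog) -> None:
        missing = [m for m in self.members if m not in catalog]
        if missing:
            raise ValueError(f"composite {self.name}: unknown tests {missing}")


def default_composites() -> list[CompositeSpec]:
    """PACC plus the three domain composites over the default catalog."""
    return [
        CompositeSpec(
            "PACC",
            ("MMSE", "LMII", "CVLT_delayed_recall", "digit_symbol_coding"),
        ),
        CompositeSpec("episodic_memory", ("LMII", "CVLT_delayed_recall")),
        CompositeSpec("executive_function", ("TMT_B", "digit_symbol_coding")),
        CompositeSpec("language", ("BNT_no_cue", "category_fluency_animals")),
    ]


class BaselineNorms:
    """Per-test mean and SD of CU baseline values.

    Built by :func:`fit_baseline_norms`; persists to/from a small CSV
    (columns: test_id, mean, sd).
    """

    def __init__(self, norms: Mapping[str, tuple[float, float]]):
        for tid, (_, sd) in norms.items():
            if not sd > 0:
                raise ValueError(f"degenerate norm for {tid}: SD must be > 0, got {sd}")
        self._norms = dict(norms)

    def __contains__(self, test_id: str) -> bool:
        return test_id in self._norms

    def mean(self, test_id: str) -> float:
        return self._norms[test_id][0]

    def sd(self, test_id: str) -> float:
        return self._norms[test_id][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test_id": list(self._norms),
                "mean": [v[0] for v in self._norms.values()],
                "sd": [v[1] for v in self._norms.values()],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BaselineNorms":
        df = pd.read_csv(path)
        return cls({r.test_id: (float(r.mean), float(r.sd)) for r in df.itertuples()})


def fit_baseline_norms(
    table: VisitTable,
    tests: Sequence[str] | None = None,
    *,
    amyloid_negative_only: bool = False,
) -> BaselineNorms:
    """Fit per-test norms on CU baseline records of a harmonized table.

    The CU reference group is participants with CDR 0 at baseline
    (amyloid-agnostic by default; ``amyloid_negative_only`` restricts to
    amyloid-negative CU).  Uses sample SD (n-1).  A test with zero or
    undefined SD in the reference raises, naming the test.
    """
    tests = list(tests) if tests is not None else table.score_columns
    df = table.df
    base = df[(df["visit_index"] == 0) & (df["cdr"] == 0.0)]
    if amyloid_negative_only:
        if "group" not in base.columns:
            base = add_group_labels(table).df
            base = base[(base["visit_index"] == 0) & (base["cdr"] == 0.0)]
        base = base[base["group"] == "ABNEG_CDR0"]
    if base.empty:
        raise ValueError("empty CU reference group")
    norms: dict[str, tuple[float, float]] = {}
    for tid in tests:
        vals = base[tid].dropna()
        if len(vals) < 2:
            raise ValueError(f"cannot fit norms for {tid}: fewer than 2 CU baseline values")
        sd = float(vals.std(ddof=1))
        if not sd > 0:
            raise ValueError(f"degenerate norm for {tid}: zero SD in CU baseline")
        norms[tid] = (float(vals.mean()), sd)
    return BaselineNorms(norms)


def standardize(score: float, test: TestSpec, norms: BaselineNorms) -> float:
    """z-score with the sign oriented so higher is always better."""
    return test.direction * (score - norms.mean(test.test_id)) / norms.sd(test.test_id)


def composite_scores(
    table: VisitTable,
    specs: Sequence[CompositeSpec] | None = None,
    norms: BaselineNorms | None = None,
    centiloid_threshold: float = 25.0,
) -> pd.DataFrame:
    """Per-visit composite values with covariates carried through.

    Requires a harmonized (complete) table for every member test; a
    missing member score raises.  Returns a frame keyed by
    (participant_id, visit_index) with time_years, group label, baseline
    age, sex, education, cohort, and one column per composite.
    """
    specs = list(specs) if specs is not None else default_composites()
    for s in specs:
        s.validate_against(table.catalog)
    if norms is None:
        norms = fit_baseline_norms(
            table, sorted({m for s in specs for m in s.members})
        )
    df = table.df
    if "group" not in df.columns:
        df = add_group_labels(table, centiloid_threshold).df

    member_tests = sorted({m for s in specs for m in s.members})
    incomplete = [t for t in member_tests if df[t].isna().any()]
    if incomplete:
        raise ValueError(
            f"composites require harmonized data; missing values in {incomplete}"
        )

    z = {
        t: table.catalog[t].direction
        * (df[t] - norms.mean(t))
        / norms.sd(t)
        for t in member_tests
    }
    baseline_age = df.groupby("participant_id")["age_years"].transform("first")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "cohort_id": df["cohort_id"],
            "visit_index": df["visit_index"],
            "time_years": df["time_years"],
            "group": df["group"],
            "baseline_age": baseline_age,
            "sex": df["sex"],
            "education_years": df["education_years"],
        }
    )
    for s in specs:
        out[s.name] = sum(z[m] for m in s.members) / len(s.members)
    return out
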