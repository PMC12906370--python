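"""Neuropsychological test catalog.

A :class:`TestSpec` records the metadata needed to harmonize a test across
cohorts: its score range, whether higher scores mean better or worse
performance, the cognitive domain it measures, whether scores are
integer-valued, and which cohorts administer it.  A :class:`TestCatalog` is
an ordered collection of specs; :func:`default_catalog` encodes the
16-test battery shared across the three parent studies (AIBL, ADNI,
OASIS-3), in which several tests are administered by only one or two
cohorts and are therefore 100% missing by design elsewhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["TestSpec", "TestCatalog", "default_catalog", "DOMAINS"]

DOMAINS = ("episodic_memory", "executive_function", "language", "global")


@dataclass(frozen=True)
class TestSpec:
    """Metadata for one neuropsychological test score.

    Parameters
    ----------
    test_id
        Short unique name used as the column name in visit tables.
    domain
        Cognitive domain the test measures; one of
        ``episodic_memory``, ``executive_function``, ``language``,
        ``global``.
    direction
        +1 if higher scores mean better performance, -1 for time- or
        error-scored tests (e.g. Trail-Making Test Part B) where higher
        is worse.
    score_min, score_max
        Bounds of the raw score.
    discrete
        True if the raw score is integer-valued.
    administered_in
        Cohort identifiers whose battery includes this test.
    """

    test_id: str
    domain: str
    direction: int
    score_min: float
    score_max: float
    discrete: bool
    administered_in: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for {self.test_id}")
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if not self.score_min < self.score_max:
            raise ValueError(f"{self.test_id}: score_min must be < score_max")
        if not self.administered_in:
            raise ValueError(f"{self.test_id}: administered_in may not be empty")
        object.__setattr__(self, "administered_in", frozenset(self.administered_in))


class TestCatalog:
    """Ordered collection of :class:`TestSpec` with unique ids."""

    def __init__(self, specs: Iterable[TestSpec]):
        specs = list(specs)
        ids = [s.test_id for s in specs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate test ids: {dupes}")
        self._specs: dict[str, TestSpec] = {s.test_id: s for s in specs}

    def __iter__(self) -> Iterator[TestSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, test_id: str) -> bool:
        return test_id in self._specs

    def __getitem__(self, test_id: str) -> TestSpec:
        return self._specs[test_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TestCatalog):
            return NotImplemented
        return list(self) == list(other)

    @property
    def test_ids(self) -> list[str]:
        return list(self._specs)

    @property
    def cohorts(self) -> list[str]:
        """All cohort ids mentioned by any test, sorted."""
        out: set[str] = set()
        for s in self:
            out |= s.administered_in
        return sorted(out)

    def panel(self, cohort_id: str) -> list[str]:
        """Tests administered in ``cohort_id``, in catalog order."""
        return [s.test_id for s in self if cohort_id in s.administered_in]

    # ------------------------------------------------------------------
    # delimited-text I/O (columns: test_id, domain, direction, min, max,
    # discrete, cohorts -- cohorts separated by '|')
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test_id": [s.test_id for s in self],
                "domain": [s.domain for s in self],
                "direction": [s.direction for s in self],
                "min": [s.score_min for s in self],
                "max": [s.score_max for s in self],
                "discrete": [s.discrete for s in self],
                "cohorts": ["|".join(sorted(s.administered_in)) for s in self],
            }
        )

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TestCatalog":
        specs = [
            TestSpec(
                test_id=str(row.test_id),
                domain=str(row.domain),
                direction=int(row.direction),
                score_min=float(row.min),
                score_max=float(row.max),
                discrete=str(row.discrete).lower() in ("true", "1"),
                administered_in=frozenset(str(row.cohorts).split("|")),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(specs)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "TestCatalog":
        return cls.from_frame(pd.read_csv(path))


def default_catalog() -> TestCatalog:
    """The default 16-test catalog over cohorts AIBL, ADNI, OASIS.

    Ranges follow the published psychometric bounds of each instrument;
    the administration pattern reflects which parent study's battery
    includes each test (tests outside a cohort's battery are structurally
    missing there).  TMT-B is the only time-scored test and hence the
    only one with direction -1.
    """
    A, D, O = "AIBL", "ADNI", "OASIS"
    ALL = frozenset({A, D, O})
    mk = TestSpec
    return TestCatalog(
        [
            mk("MMSE", "global", 1, 0, 30, True, ALL),
            mk("LMII", "episodic_memory", 1, 0, 25, True, ALL),
            mk("RAVLT_total_learning", "episodic_memory", 1, 0, 75, True, frozenset({D})),
            mk("RAVLT_delayed_recall", "episodic_memory", 1, 0, 15, True, frozenset({D})),
            mk("RAVLT_recognition_hits", "episodic_memory", 1, 0, 15, True, frozenset({D})),
            mk("CVLT_total_learning", "episodic_memory", 1, 0, 80, True, frozenset({A})),
            mk("CVLT_delayed_recall", "episodic_memory", 1, 0, 16, True, frozenset({A})),
            mk("CVLT_recognition_hits", "episodic_memory", 1, 0, 16, True, frozenset({A})),
            mk("SRT_FREE", "episodic_memory", 1, 0, 48, True, frozenset({O})),
            mk("TMT_B", "executive_function", -1, 5, 300, False, frozenset({D, O})),
            mk("digit_symbol_coding", "executive_function", 1, 0, 127, True, frozenset({A})),
            mk("digit_span_forward", "executive_function", 1, 0, 16, True, ALL),
            mk("digit_span_backward", "executive_function", 1, 0, 14, True, ALL),
            mk("BNT_no_cue", "language", 1, 0, 30, True, ALL),
            mk("category_fluency_animals", "language", 1, 0, 60, True, ALL),
            mk("verbal_fluency_switching", "executive_function", 1, 0, 24, True, frozenset({A})),
        ]
    )
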