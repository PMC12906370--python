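import numpy as np
import pandas as pd
import pytest

from cogharmon.catalog import TestCatalog, TestSpec
from cogharmon.visits import VisitTable
import cogharmon as ch


@pytest.fixture(scope="session")
def tiny_catalog() -> TestCatalog:
    """Three tests over two cohorts; cohort B lacks test C."""
    return TestCatalog(
        [
            TestSpec("A", "episodic_memory", 1, 0, 30, True, frozenset({"X", "Y"})),
            TestSpec("B", "language", 1, 0, 20, True, frozenset({"X", "Y"})),
            TestSpec("C", "executive_function", -1, 5, 300, False, frozenset({"X"})),
        ]
    )


def make_table(catalog, cohort, n_participants, n_visits, seed=0, missing=0.0):
    """Small synthetic cohort table with optional sporadic missingness."""
    rng = np.random.default_rng(seed)
    rows = []
    panel = set(catalog.panel(cohort))
    for i in range(n_participants):
        ability = rng.normal()
        centiloid = rng.uniform(-10, 80)
        cdr = float(rng.choice([0, 0.5, 1], p=[0.7, 0.2, 0.1]))
        for v in range(n_visits):
            row = {
                "participant_id": f"p{i}",
                "cohort_id": cohort,
                "visit_index": v,
                "time_years": v * 1.0,
                "age_years": 70 + i + v,
                "sex": "female" if i % 2 else "male",
                "education_years": 12 + (i % 6),
                "apoe4": "carrier" if i % 3 == 0 else "non-carrier",
                "cdr": cdr,
                "centiloid": centiloid,
                "diagnosis": "cu" if cdr == 0 else ("mci" if cdr == 0.5 else "ad"),
            }
            for spec in catalog:
                if spec.test_id not in panel:
                    continue
                if rng.random() < missing:
                    continue
                mid = (spec.score_min + spec.score_max) / 2
                spread = (spec.score_max - spec.score_min) / 8
                val = float(
                    np.clip(
                        mid + spec.direction * spread * ability + rng.normal(0, spread / 4),
                        spec.score_min,
                        spec.score_max,
                    )
                )
                row[spec.test_id] = round(val) if spec.discrete else val
            rows.append(row)
    return VisitTable(catalog, pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_tables(tiny_catalog):
    return [
        make_table(tiny_catalog, "X", 5, 3, seed=1),
        make_table(tiny_catalog, "Y", 4, 3, seed=2),
    ]


@pytest.fixture(scope="session")
def tiny_merged(tiny_tables):
    return ch.build_merged_table(tiny_tables)


@pytest.fixture(scope="session")
def small_generated():
    """Default-condition synthetic cohorts at reduced size, merged."""
    cfg = ch.default_config().with_sizes(60)
    tables, truth = ch.generate(cfg, seed=11)
    merged = ch.build_merged_table(tables)
    merged, _ = ch.apply_inclusion_criteria(merged)
    return cfg, merged, truth


def complete_table_from_truth(merged, truth):
    """Visit table with every score replaced by its ground-truth value."""
    complete = merged.copy()
    keyed = truth.true_scores.set_index(["participant_id", "visit_index"])
    idx = pd.MultiIndex.from_frame(complete.df[["participant_id", "visit_index"]])
    for t in merged.score_columns:
        complete.df[t] = keyed[t].loc[idx].to_numpy()
    return complete


@pytest.fixture(scope="session")
def small_harmonized(small_generated):
    cfg, merged, truth = small_generated
    result = ch.MissForestImputer(
        merged, config=ch.ImputationConfig(n_trees=30, seed=5)
    ).fit()
    return cfg, merged, truth, result
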