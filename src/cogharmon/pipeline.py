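"""Stage orchestration: simulate -> merge -> impute -> validate ->
composites -> groupmodel, with a run manifest.

Each stage reads the previous stage's declared outputs from the run
directory and can equally be invoked standalone through the CLI with the
same files.  The manifest records the configuration snapshot, master
seed, SHA-256 digests of every output file, timestamps, and per-stage
status; deterministic stages reproduce identical digests under the same
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .catalog import TestCatalog, default_catalog
from .composites import composite_scores, default_composites, fit_baseline_norms
from .groupmodel import analyze_composites, plot_trajectories
from .holdout import HoldoutPlan, run_validation
from .impute import ImputationConfig, MissForestImputer, distribution_shift_report
from .simulate import GeneratorConfig, default_config, generate
from .visits import VisitTable, apply_inclusion_criteria, build_merged_table, missingness_summary

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "STAGES"]

log = logging.getLogger("cogharmon")

STAGES = ("simulate", "merge", "impute", "validate", "composites", "groupmodel")

#: Files each stage needs before it can run, and the stage that makes them.
_REQUIRES = {
    "merge": [("cohort_AIBL.csv", "simulate"), ("catalog.csv", "simulate")],
    "impute": [("merged.csv", "merge"), ("catalog.csv", "simulate")],
    "validate": [("merged.csv", "merge"), ("catalog.csv", "simulate")],
    "composites": [("harmonized.csv", "impute"), ("catalog.csv", "simulate")],
    "groupmodel": [("composites.csv", "composites")],
}


@dataclasses.dataclass
class PipelineConfig:
    """Run-level knobs; everything else uses module defaults."""

    n_participants_per_cohort: int = 100
    min_visits: int = 3
    max_visits: int = 5
    min_assessments: int = 3
    centiloid_threshold: float = 25.0
    n_trees: int = 100
    max_iterations: int = 10
    validation_tests: Sequence[str] | None = None
    validation_repeats: int = 2
    mask_fraction: float = 0.30
    window_years: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run."""

    seed: int
    config: dict
    stages: dict = dataclasses.field(default_factory=dict)
    outputs: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float, files: list[Path]) -> None:
        self.stages[stage] = {
            "status": status,
            "seconds": round(seconds, 3),
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        for f in files:
            self.outputs[f.name] = _sha256(f)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_inputs(stage: str, outdir: Path) -> None:
    for fname, producer in _REQUIRES.get(stage, []):
        if not (outdir / fname).exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {fname}; run stage {producer!r} first"
            )


def _load_table(outdir: Path, name: str) -> VisitTable:
    catalog = TestCatalog.from_csv(outdir / "catalog.csv")
    return VisitTable.from_csv(outdir / name, catalog)


def stage_simulate(outdir: Path, cfg: PipelineConfig, seed: int) -> list[Path]:
    gen = default_config().with_sizes(cfg.n_participants_per_cohort)
    gen = dataclasses.replace(gen, min_visits=cfg.min_visits, max_visits=cfg.max_visits)
    tables, truth = generate(gen, seed=seed)
    files = []
    for t in tables:
        p = outdir / f"cohort_{t.cohort_ids[0]}.csv"
        t.to_csv(p)
        files.append(p)
    cat = outdir / "catalog.csv"
    gen.catalog.to_csv(cat)
    files.append(cat)
    tr = outdir / "ground_truth.csv"
    truth.true_scores.to_csv(tr, index=False)
    files.append(tr)
    return files


def stage_merge(outdir: Path, cfg: PipelineConfig, seed: int) -> list[Path]:
    catalog = TestCatalog.from_csv(outdir / "catalog.csv")
    cohort_files = sorted(outdir.glob("cohort_*.csv"))
    tables = [VisitTable.from_csv(p, catalog) for p in cohort_files]
    merged = build_merged_table(tables)
    merged, exclusions = apply_inclusion_criteria(merged, cfg.min_assessments)
    files = [outdir / "merged.csv", outdir / "exclusions.json", outdir / "missingness.csv"]
    merged.to_csv(files[0])
    files[1].write_text(json.dumps(exclusions.as_dict(), indent=2))
    missingness_summary(merged).to_csv(files[2], index=False)
    return files


def _imputation_config(cfg: PipelineConfig, seed: int) -> ImputationConfig:
    return ImputationConfig(
        n_trees=cfg.n_trees, max_iterations=cfg.max_iterations, seed=seed
    )


def stage_impute(outdir: Path, cfg: PipelineConfig, seed: int) -> list[Path]:
    merged = _load_table(outdir, "merged.csv")
    result = MissForestImputer(merged, config=_imputation_config(cfg, seed)).fit()
    files = [outdir / "harmonized.csv", outdir / "trace.csv", outdir / "shift_report.csv"]
    result.completed.to_csv(files[0])
    result.delta_trace.to_csv(files[1], index=False)
    distribution_shift_report(merged, result.completed).to_csv(files[2], index=False)
    return files


def stage_validate(outdir: Path, cfg: PipelineConfig, seed: int) -> list[Path]:
    merged = _load_table(outdir, "merged.csv")
    tests = list(cfg.validation_tests or merged.score_columns)
    plan = HoldoutPlan(
        tests=tests,
        mask_fraction=cfg.mask_fraction,
        n_repeats=cfg.validation_repeats,
        master_seed=seed,
    )
    report = run_validation(
        merged,
        plan,
        _imputation_config(cfg, seed),
        centiloid_threshold=cfg.centiloid_threshold,
    )
    files = [outdir / "validation_report.csv", outdir / "validation_repeats.csv"]
    report.table.to_csv(files[0], index=False)
    report.per_repeat.to_csv(files[1], index=False)
    return files


def stage_composites(outdir: Path, cfg: PipelineConfig, seed: int) -> list[Path]:
    harmonized = _load_table(outdir, "harmonized.csv")
    specs = default_composites()
    members = sorted({m for s in specs for m in s.members})
    norms = fit_baseline_norms(harmonized, members)
    comp = composite_scores(
        harmonized, specs, norms, centiloid_threshold=cfg.centiloid_threshold
    )
    files = [outdir / "composites.csv", outdir / "norms.csv"]
    comp.to_csv(files[0], index=False)
    norms.to_csv(files[1])
    return files


def stage_groupmodel(outdir: Path, cfg: PipelineConfig, seed: int) -> list[Path]:
    comp = pd.read_csv(outdir / "composites.csv")
    outcomes = [s.name for s in default_composites()]
    results, contrasts = analyze_composites(comp, outcomes, cfg.window_years)
    rows = []
    for name, res in results.items():
        means = res.marginal_baseline_means().assign(kind="intercept", outcome=name)
        slopes = res.marginal_slopes().assign(kind="slope", outcome=name)
        rows += [means, slopes]
    estimates = pd.concat(rows, ignore_index=True)
    files = [
        outdir / "group_estimates.csv",
        outdir / "group_contrasts.csv",
        outdir / "trajectories.svg",
    ]
    estimates.to_csv(files[0], index=False)
    contrasts.to_csv(files[1], index=False)
    plot_trajectories(results, files[2])
    return files


_STAGE_FN = {
    "simulate": stage_simulate,
    "merge": stage_merge,
    "impute": stage_impute,
    "validate": stage_validate,
    "composites": stage_composites,
    "groupmodel": stage_groupmodel,
}


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    stages: Sequence[str] | None = None,
    config: PipelineConfig | None = None,
) -> RunManifest:
    """Run the requested stages in order and write ``manifest.json``.

    Raises on the first failing stage after recording its status; a
    missing upstream output raises an error naming the stage to run
    first.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    stages = list(stages) if stages is not None else list(STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    stages.sort(key=STAGES.index)
    manifest = RunManifest(seed=seed, config=dataclasses.asdict(config))
    for stage in stages:
        _check_inputs(stage, outdir)
        t0 = time.time()
        log.info("stage %s: starting", stage)
        try:
            files = _STAGE_FN[stage](outdir, config, seed)
        except Exception:
            manifest.record(stage, "failed", time.time() - t0, [])
            manifest.write(outdir / "manifest.json")
            raise
        manifest.record(stage, "ok", time.time() - t0, files)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    manifest.write(outdir / "manifest.json")
    return manifest
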