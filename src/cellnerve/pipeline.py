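"""End-to-end cohort comparison and morphometric reports from a plan file.

A comparison plan names two cohorts of segmented samples (labeled volume +
cell table + stage), the stages and tissue selections to analyze, and the
test settings.  For every (stage, tissue) pair the pipeline restricts each
volume to the tissue, builds the nerves, enumerates a shared face-vector
alphabet across both cohorts, and runs the bootstrap Cramér test; results,
feature matrices, PCA scores and a reproducibility manifest are written as
plain CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cramer import TwoSampleResult, compare_feature_cohorts
from .features import FeatureMatrix, feature_matrix, pca_project
from .io import (
    SMALL_CELL_THRESHOLD,
    LabeledVolume,
    TableSchema,
    filter_small_cells,
    read_cell_table,
    read_labeled_volume,
    restrict_to_tissue,
)
from .morphometrics import cvcv, growth_table, tissue_proportions
from .nerve import Nerve, build_nerve

__all__ = [
    "SampleRef",
    "ComparisonPlan",
    "compare_nerve_cohorts",
    "run_comparison",
    "run_morphometrics",
]


@dataclass(frozen=True)
class SampleRef:
    sample_id: str
    volume: Path
    table: Path | None = None
    stage: str | None = None


@dataclass
class ComparisonPlan:
    """Declarative description of a two-cohort comparison."""

    cohorts: dict[str, list[SampleRef]]
    stages: list[str] | None = None  # None: every stage present in the plan
    tissues: dict[str, list | None] = field(default_factory=lambda: {"all": None})
    scheme: str = "block2"
    replicates: int = 1000
    seed: int | None = None
    resampling: str = "ordinary_bootstrap"
    schema: TableSchema = field(default_factory=TableSchema)
    spacing: tuple[float, float, float] | None = None
    background: tuple[int, ...] = (0,)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComparisonPlan":
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        root = path.parent
        cohorts: dict[str, list[SampleRef]] = {}
        for label, samples in cfg["cohorts"].items():
            refs = []
            for s in samples:
                refs.append(SampleRef(
                    sample_id=str(s.get("sample_id", Path(s["volume"]).stem)),
                    volume=root / s["volume"],
                    table=(root / s["table"]) if s.get("table") else None,
                    stage=s.get("stage"),
                ))
            cohorts[label] = refs
        schema = TableSchema.from_mapping(cfg.get("schema", {}))
        return cls(
            cohorts=cohorts,
            stages=cfg.get("stages"),
            tissues=cfg.get("tissues", {"all": None}),
            scheme=cfg.get("scheme", "block2"),
            replicates=int(cfg.get("replicates", 1000)),
            seed=cfg.get("seed"),
            resampling=cfg.get("resampling", "ordinary_bootstrap"),
            schema=schema,
            spacing=tuple(cfg["spacing"]) if "spacing" in cfg else None,
            background=tuple(cfg.get("background", (0,))),
        )

    def validate(self) -> None:
        if len(self.cohorts) != 2:
            raise ValueError(f"a comparison needs exactly two cohorts, got {list(self.cohorts)}")
        for label, refs in self.cohorts.items():
            if not refs:
                raise ValueError(f"cohort {label!r} has no samples")
            for ref in refs:
                if not Path(ref.volume).exists():
                    raise ValueError(f"missing volume file: {ref.volume}")
                if ref.table is not None and not Path(ref.table).exists():
                    raise ValueError(f"missing table file: {ref.table}")

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, (SampleRef, TableSchema)):
                return o.__dict__
            raise TypeError(type(o))

        blob = json.dumps(self.__dict__, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def compare_nerve_cohorts(
    cohort_a: Sequence[Nerve],
    cohort_b: Sequence[Nerve],
    labels: tuple[str, str] = ("A", "B"),
    B: int = 1000,
    seed: int | None = None,
    resampling: str = "ordinary_bootstrap",
    stage: str | None = None,
    tissue: str | None = None,
) -> tuple[TwoSampleResult, FeatureMatrix]:
    """Shared-alphabet feature matrix + Cramér bootstrap test for two cohorts."""
    fm = feature_matrix({labels[0]: list(cohort_a), labels[1]: list(cohort_b)},
                        stage=stage, tissue=tissue)
    result = compare_feature_cohorts(fm, B=B, seed=seed, resampling=resampling)
    return result, fm


def _child_seed(master: int | None, index: int) -> int:
    ss = np.random.SeedSequence(master).spawn(index + 1)[index]
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def _load_sample(ref: SampleRef, plan: ComparisonPlan):
    vol = read_labeled_volume(
        ref.volume, spacing=plan.spacing, background=plan.background
    )
    table = read_cell_table(ref.table, plan.schema) if ref.table else None
    return vol, table


def run_comparison(plan: ComparisonPlan, out_dir: str | Path) -> pd.DataFrame:
    """Execute every (stage, tissue) comparison of the plan.

    Returns the results table (one row per stage × tissue with T, p, m, n)
    and writes results, per-comparison feature matrices, PCA scores and a
    manifest under ``out_dir``.  Cells with fewer than two samples in a
    cohort are flagged ``skipped``, never silently dropped.
    """
    plan.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (label_a, refs_a), (label_b, refs_b) = plan.cohorts.items()
    stages = plan.stages
    if stages is None:
        found = {r.stage for refs in plan.cohorts.values() for r in refs}
        stages = sorted(s for s in found if s is not None) or [None]

    rows = []
    test_index = 0
    for stage in stages:
        for tissue_name, tissue_ids in plan.tissues.items():
            sel_a = [r for r in refs_a if stage is None or r.stage == stage]
            sel_b = [r for r in refs_b if stage is None or r.stage == stage]
            row = {"stage": stage, "tissue": tissue_name,
                   "m": len(sel_a), "n": len(sel_b)}
            if len(sel_a) < 2 or len(sel_b) < 2:
                rows.append({**row, "statistic": np.nan, "p_value": np.nan,
                             "status": "skipped: <2 samples in a cohort"})
                test_index += 1
                continue
            nerves = {label_a: [], label_b: []}
            for label, sel in ((label_a, sel_a), (label_b, sel_b)):
                for ref in sel:
                    vol, table = _load_sample(ref, plan)
                    if tissue_ids is not None:
                        if table is None:
                            raise ValueError(
                                f"sample {ref.sample_id}: tissue selection requires a cell table"
                            )
                        vol = restrict_to_tissue(vol, table, tissue_ids)
                    nerves[label].append(build_nerve(vol, scheme=plan.scheme))
            seed = _child_seed(plan.seed, test_index)
            result, fm = compare_nerve_cohorts(
                nerves[label_a], nerves[label_b], labels=(label_a, label_b),
                B=plan.replicates, seed=seed, resampling=plan.resampling,
                stage=stage, tissue=tissue_name,
            )
            tag = f"{stage or 'all'}_{tissue_name}"
            fm.to_frame().to_csv(out_dir / f"features_{tag}.csv", index=False)
            k = min(2, fm.values.shape[0] - 1, fm.values.shape[1])
            if k >= 1:
                scores = pca_project(fm, k=k)
                pca_df = fm.meta.copy()
                for j in range(k):
                    pca_df[f"PC{j + 1}"] = scores[:, j]
                pca_df.to_csv(out_dir / f"pca_{tag}.csv", index=False)
            rows.append({**row, "statistic": result.statistic,
                         "p_value": result.p_value, "B": result.replicates,
                         "seed": result.seed, "status": "ok"})
            test_index += 1

    results = pd.DataFrame(rows)
    results.to_csv(out_dir / "results.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config_hash": plan.config_hash(),
        "master_seed": plan.seed,
        "replicates": plan.replicates,
        "resampling": plan.resampling,
        "scheme": plan.scheme,
        "n_tests": int(len(results)),
        "note": "per-test p-values are reported raw (no multiplicity adjustment)",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def run_morphometrics(
    plan_or_table: ComparisonPlan | pd.DataFrame,
    out_dir: str | Path | None = None,
    threshold: float = SMALL_CELL_THRESHOLD,
    per_sample_cv: bool = False,
    division_tally: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Morphometric report: CVcv, growth, proportions (and division summary).

    Accepts either a plan (cell tables are loaded from its samples, with the
    cohort label attached) or an already-merged cell table.  The small-cell
    filter is applied first.  By default CVcv pools cells across samples of
    a (cohort, stage, tissue); ``per_sample_cv`` computes one CV per sample
    instead.
    """
    if isinstance(plan_or_table, ComparisonPlan):
        plan = plan_or_table
        plan.validate()
        parts = []
        for label, refs in plan.cohorts.items():
            for ref in refs:
                if ref.table is None:
                    raise ValueError(f"sample {ref.sample_id} has no cell table")
                t = read_cell_table(ref.table, plan.schema)
                t["cohort"] = label
                parts.append(t)
        table = pd.concat(parts, ignore_index=True)
    else:
        table = plan_or_table
    table = filter_small_cells(table, threshold)

    group_cols = ["cohort", "stage", "tissue_id"]
    if per_sample_cv:
        group_cols = group_cols + ["sample_id"]
    cv_rows = []
    for key, grp in table.groupby(group_cols, observed=True):
        if len(grp) < 2:
            continue
        cv_rows.append(dict(zip(group_cols, key if isinstance(key, tuple) else (key,)),
                            n_cells=len(grp), cvcv=cvcv(grp["volume"])))
    outputs: dict[str, pd.DataFrame] = {"cvcv": pd.DataFrame(cv_rows)}

    for measure in ("tissue_volume", "cell_count"):
        parts = []
        for cohort, grp in table.groupby("cohort", observed=True):
            if grp["stage"].nunique() < 2:
                continue
            g = growth_table(grp, measure=measure)
            g.insert(0, "cohort", cohort)
            parts.append(g)
        if parts:
            outputs[f"growth_{measure}"] = pd.concat(parts, ignore_index=True)

    for measure in ("volume", "cell_count"):
        outputs[f"proportions_{measure}"] = tissue_proportions(table, measure=measure)

    if division_tally is not None:
        from .morphometrics import division_summary

        outputs["division_summary"] = division_summary(division_tally)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in outputs.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
    return outputs
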