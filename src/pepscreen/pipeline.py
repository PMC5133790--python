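"""End-to-end orchestration: simulate -> compile -> search -> screen -> report.

One :class:`RunConfig` fixes every knob of a run — generator settings,
matching tolerances, cross-validation layout, consensus thresholds and the
seed — and :func:`run_pipeline` executes the stages, writing each stage's
output plus the resolved configuration into a run directory so a rerun
with the same config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import biomarker_screen, model_search, peaklist_io, splsda, synthetic
from .compile_align import AbundanceMatrix, compile_dataset

logger = logging.getLogger("pepscreen")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "pepscreen_run"
    # generator (None field values fall back to SimConfig defaults)
    sim: dict = field(default_factory=dict)
    # compilation
    ppm_tol: float = 50.0
    mt_tol_min: float = 2.0
    log1p: bool = False  # log-transform abundances before modeling
    # search
    groupings: tuple[str, ...] = model_search.GROUPINGS
    n_peptides_grid: list[int] | None = None  # None = full 1..50
    n_folds: int = 10
    cv_repeats: int = 1
    # screening
    screen_grouping: str = "three_group_week"
    top_models: int = 5
    load_threshold: float = 0.15
    min_frequency_pct: float = 30.0
    # exports
    export_fingerprints: bool = False
    fingerprint_bins: tuple[int, int] = (30, 30)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["groupings"] = list(self.groupings)
        doc["fingerprint_bins"] = list(self.fingerprint_bins)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    def sim_config(self) -> synthetic.SimConfig:
        return synthetic.SimConfig(seed=self.seed, **self.sim)


@dataclass
class PipelineResult:
    config: RunConfig
    matrix: AbundanceMatrix
    results: list[model_search.ModelResult]
    best_by_week: dict[int, list[model_search.ModelResult]]
    weekly_models: dict[int, list[splsda.SplsdaModel]]
    weekly_selected: dict[int, set[int]]
    records: list[biomarker_screen.BiomarkerRecord]
    unique_count: int
    truth: synthetic.GroundTruth | None
    recovery: synthetic.RecoveryMetrics | None
    out_dir: Path


def _screen_week(
    week: int,
    results: list[model_search.ModelResult],
    matrix: AbundanceMatrix,
    cfg: RunConfig,
) -> tuple[list[model_search.ModelResult], list[splsda.SplsdaModel], set[int]]:
    best = model_search.select_best(
        results, cfg.screen_grouping, week, k=cfg.top_models
    )
    sub = matrix.subset_week(week)
    y = model_search.labels_for(sub.samples, cfg.screen_grouping)
    models = [
        splsda.fit(
            sub.values, y, ncomp=r.spec.ncomp, keep_x=r.spec.n_peptides,
            feature_ids=matrix.peptide_ids,
        )
        for r in best
    ]
    ccfg = biomarker_screen.ConsensusConfig(
        load_threshold=cfg.load_threshold,
        min_frequency_pct=cfg.min_frequency_pct,
        n_models=len(models),
    )
    selected = biomarker_screen.consensus_biomarkers(models, ccfg)
    return best, models, selected


def run_pipeline(cfg: RunConfig, runs=None, truth=None) -> PipelineResult:
    """Execute every stage and write the run directory.

    ``runs``/``truth`` may be supplied to reuse pre-generated data;
    otherwise the generator is invoked with ``cfg.sim_config()``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cfg.to_yaml(out / "config.yaml")

        stage = "simulate"
        if runs is None:
            runs, truth = synthetic.generate(cfg.sim_config())
        logger.info("simulate: %d runs", len(runs))

        stage = "compile"
        matrix = compile_dataset(runs, cfg.ppm_tol, cfg.mt_tol_min)
        if cfg.log1p:
            matrix = AbundanceMatrix(
                matrix.samples, matrix.peptides, np.log1p(matrix.values)
            )
        matrix.write_csv(out / "abundance_matrix.csv")
        logger.info(
            "compile: %d samples x %d master peptides",
            len(matrix.samples), len(matrix.peptides),
        )

        stage = "search"
        specs = model_search.enumerate_grid(
            n_peptides=cfg.n_peptides_grid, groupings=cfg.groupings
        )
        results = model_search.run_search(
            matrix, specs, n_folds=cfg.n_folds, seed=cfg.seed,
            cv_repeats=cfg.cv_repeats,
        )
        table = model_search.results_table(results)
        table.to_csv(out / "grid_results.csv", index=False)
        for grouping in cfg.groupings:
            sl = table[table["grouping"] == grouping]["error_rate"]
            logger.info(
                "search %s: error rate %.3f-%.3f (mean %.3f) over %d models",
                grouping, sl.min(), sl.max(), sl.mean(), len(sl),
            )

        stage = "screen"
        weeks = sorted(matrix.samples["week"].unique())
        best_by_week, weekly_models, weekly_selected = {}, {}, {}
        for week in weeks:
            best, models, selected = _screen_week(week, results, matrix, cfg)
            best_by_week[week] = best
            weekly_models[week] = models
            weekly_selected[week] = selected
            if models:
                np.savetxt(
                    out / f"scores_week{week}.csv",
                    np.column_stack(
                        [models[0].x_scores[:, h] for h in range(models[0].ncomp)]
                    ),
                    delimiter=",",
                    header=",".join(f"comp{h + 1}" for h in range(models[0].ncomp)),
                    comments="",
                )
            logger.info("screen week %d: %d consensus peptides", week, len(selected))

        stage = "report"
        ccfg = biomarker_screen.ConsensusConfig(
            load_threshold=cfg.load_threshold,
            min_frequency_pct=cfg.min_frequency_pct,
            n_models=cfg.top_models,
        )
        records, unique_count = biomarker_screen.build_panel(
            weekly_selected, matrix, ccfg
        )
        peaklist_io.write_report(records, out / "panel_report.csv")

        recovery = None
        if truth is not None:
            mapping = truth.map_masters(matrix.peptides)
            sel_true = {
                wk: {mapping[pid] for pid in sel if pid in mapping}
                for wk, sel in weekly_selected.items()
            }
            recovery = synthetic.evaluate_recovery(sel_true, truth)
            logger.info(
                "recovery: sensitivity %.2f, false by week %s",
                recovery.sensitivity, recovery.false_by_week,
            )

        if cfg.export_fingerprints:
            nt, nm = cfg.fingerprint_bins
            for g in ("N", "HA", "HL"):
                subgroups = ("NA", "NL") if g == "N" else (g,)
                for week in weeks:
                    sel_runs = [
                        r for r in runs if r.group in subgroups and r.week == week
                    ]
                    if sel_runs:
                        grid = peaklist_io.fingerprint(sel_runs, nt, nm)
                        peaklist_io.write_fingerprint(
                            grid, out / f"fingerprint_{g}_W{week}.csv"
                        )

        summary = {
            "week_rows": len(records),
            "unique_peptides": unique_count,
            "selected_by_week": {
                str(w): sorted(s) for w, s in weekly_selected.items()
            },
        }
        if recovery is not None:
            summary["sensitivity"] = recovery.sensitivity
            summary["false_by_week"] = {
                str(w): n for w, n in recovery.false_by_week.items()
            }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:
        logger.exception("pipeline failed in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    return PipelineResult(
        config=cfg,
        matrix=matrix,
        results=results,
        best_by_week=best_by_week,
        weekly_models=weekly_models,
        weekly_selected=weekly_selected,
        records=records,
        unique_count=unique_count,
        truth=truth,
        recovery=recovery,
        out_dir=out,
    )
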