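"""End-to-end pipeline: input -> curation -> filtration -> wrapper -> report.

Mirrors the four analysis stages as a reproducible batch run. A single
master seed deterministically derives the per-stage seeds (fold shuffling,
swarm, evaluation CV), and every stage writes its artifacts plus a manifest
into the run directory, so a run can be reproduced from the manifest alone.
Curation is obligatory for SOFT inputs (raw GDS tables are non-curated and
huge) unless explicitly overridden.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import curation as cur
from . import dataset as dio
from . import evaluation as ev
from . import filters as flt
from . import gbpso

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

FILTER_CHOICES = ("tt", "wrs", "ttwrs", "all")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_path: str = ""
    input_format: str = "csv"  # csv | soft
    classes: str | None = None  # SOFT class ranges, e.g. "1-35;36-48"
    class_names: tuple[str, str] = ("class1", "class2")
    curate: bool | None = None  # None: on for soft, off for csv
    force_no_curate: bool = False  # explicit override of the soft rule
    curation: cur.CurationConfig = field(default_factory=cur.CurationConfig)
    filter: str = "tt"  # tt | wrs | ttwrs | all
    n_filtered: int = 200
    filter_folds: int = 10
    gbpso: gbpso.GbpsoConfig = field(default_factory=gbpso.GbpsoConfig)
    outdir: str = "hidimsel_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(4)
    names = ("filter", "swarm", "fitness_cv", "eval")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return the full list of violations (empty when valid)."""
    errors = []
    if not cfg.input_path:
        errors.append("input_path is required")
    if cfg.input_format not in ("csv", "soft"):
        errors.append(f"unknown input format {cfg.input_format!r}")
    if cfg.input_format == "soft" and not cfg.classes:
        errors.append("SOFT input requires the class ranges (e.g. '1-35;36-48')")
    if cfg.input_format == "soft" and cfg.curate is False and not cfg.force_no_curate:
        errors.append(
            "gene reduction is obligatory for SOFT inputs; "
            "pass force_no_curate to override"
        )
    if cfg.filter not in FILTER_CHOICES:
        errors.append(f"filter must be one of {FILTER_CHOICES}")
    if cfg.n_filtered < 1:
        errors.append("n_filtered must be >= 1")
    if cfg.filter_folds < 1:
        errors.append("filter_folds must be >= 1")
    return errors


def _read_input(cfg: PipelineConfig, log) -> dio.ExpressionDataset:
    if cfg.input_format == "csv":
        return dio.read_csv_dataset(cfg.input_path)
    spec = dio.SoftClassSpec.parse(cfg.classes, cfg.class_names)
    ds, parse_log = dio.read_soft_gds(cfg.input_path, spec)
    for line in parse_log.lines:
        log(f"soft-parse: {line}")
    return ds


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured pipeline; returns the run directory.

    Artifacts: ``curated.csv``, per-filter score tables and filtered
    datasets, selection results (gene lists and fitness traces), evaluation
    reports, the final subset's heatmap matrix, ``manifest.yaml`` and
    ``run.log``. On a stage failure partial outputs are kept and a FAILED
    marker file records the stage and message.
    """
    errors = validate_config(cfg)
    if errors:
        raise PipelineError("config", "; ".join(errors))

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().strftime("%H:%M:%S")
        log_lines.append(f"{stamp} {msg}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {
        "config": _config_dict(cfg),
        "stage_seeds": seeds,
        "gene_counts": {},
    }
    stage = "input"
    try:
        ds = _read_input(cfg, log)
        manifest["gene_counts"]["input"] = ds.n_genes
        log(f"input: {ds.n_genes} genes x {ds.n_samples} samples")

        stage = "curation"
        do_curate = cfg.curate if cfg.curate is not None else (cfg.input_format == "soft")
        if cfg.force_no_curate:
            do_curate = False
        if do_curate:
            ds, report = cur.curate(ds, cfg.curation)
            report.to_tsv(outdir / "curation_report.tsv")
            dio.write_dataset_csv(ds, outdir / "curated.csv")
            log(
                f"curation: kept {report.keep_count}/{report.before_count} genes"
            )
        manifest["gene_counts"]["curated"] = ds.n_genes

        stage = "filtration"
        branches = ["tt", "wrs", "ttwrs"] if cfg.filter == "all" else [cfg.filter]
        base_tables: dict[str, flt.GeneScoreTable] = {}
        for f in ("tt", "wrs"):
            if f in branches or "ttwrs" in branches:
                base_tables[f] = flt.kfold_filter_weights(
                    ds, f, K=cfg.filter_folds, seed=seeds["filter"]
                )
        tables: dict[str, flt.GeneScoreTable] = {}
        for b in branches:
            tables[b] = (
                flt.combine_tt_wrs(base_tables["tt"], base_tables["wrs"])
                if b == "ttwrs"
                else base_tables[b]
            )
            tables[b].to_tsv(outdir / f"scores_{b}.tsv")

        results: dict[str, dict] = {}
        final_branch = branches[-1]
        for b in branches:
            stage = f"filtration:{b}"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                filtered = flt.select_top(tables[b], ds, cfg.n_filtered)
            dio.write_dataset_csv(filtered, outdir / f"filtered_{b}.csv")
            manifest["gene_counts"][f"filtered_{b}"] = filtered.n_genes
            log(f"filtration[{b}]: kept top {filtered.n_genes} genes")

            stage = f"selection:{b}"
            gcfg = dataclasses.replace(
                cfg.gbpso,
                seed=seeds["swarm"],
                svm=dataclasses.replace(cfg.gbpso.svm, cv_seed=seeds["fitness_cv"]),
            )
            sel = gbpso.run_gbpso(filtered, gcfg)
            dio.write_gene_list(
                sel.selected_gene_ids,
                [1.0] * len(sel.selected_gene_ids),
                outdir / f"selected_{b}.csv",
            )
            sel.trace_tsv(outdir / f"trace_{b}.tsv")
            manifest["gene_counts"][f"selected_{b}"] = len(sel.selected_gene_ids)
            log(
                f"selection[{b}]: {len(sel.selected_gene_ids)} genes, "
                f"wrapper fitness {sel.best_fitness:.4f}"
            )

            stage = f"evaluation:{b}"
            report = ev.evaluate_subset(
                filtered, sel.best_mask, gcfg.svm, repeats=1, seed=seeds["fitness_cv"]
            )
            (outdir / f"evaluation_{b}.txt").write_text(report.summary() + "\n")
            report.to_tsv(outdir / f"evaluation_{b}_folds.tsv")
            results[b] = {
                "n_selected": len(sel.selected_gene_ids),
                "wrapper_fitness": sel.best_fitness,
                "accuracy_pct": report.accuracy_pct,
                "accuracy_sd_pct": report.accuracy_sd_pct,
                "precision_pct": report.precision_pct,
            }
            if b == final_branch:
                ev.heatmap_matrix(
                    filtered, sel.selected_gene_ids, path=outdir / "heatmap_matrix.tsv"
                )
        manifest["results"] = results
    except PipelineError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        log(f"FAILED at {stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    log("done")
    return outdir


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["class_names"] = list(cfg.class_names)
    return d
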