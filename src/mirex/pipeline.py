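"""End-to-end orchestration of the four-variant comparison.

Order of stages: baseline runs → residuals (train+val genes) → signed and
absolute residual–CWCS rankings → top-k selection → all-miRNA / signed /
absolute variant runs → best-run aggregation → pairwise Welch comparison.
Every stage's outputs can be persisted under an output directory, and runs
already on disk are reused on a rerun (resume).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .encoding import ModelData, assemble_dataset
from .evaluation import VARIANTS, VariantReport, aggregate_runs, compare_variants
from .io_formats import ExpressionMatrix, lognorm
from .model import CNNResults, ExpressionCNN, ModelConfig, TrainConfig
from .selection import (
    SelectionResult,
    rank_mirnas,
    residuals_from_baseline,
    selection_to_tsv,
)

__all__ = ["PipelineConfig", "PipelineResult", "prepare_model_data", "mirna_log_expression", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings of the full workflow.

    ``model_config``'s ``k_mirnas`` is replaced per variant; ``n_runs``
    models are trained per variant and the best ``top_n`` (by validation
    R², configurable) are retained.  ``k`` is the selection size (10, the
    standard choice); ``k = 0`` degenerates the selected variants to the
    baseline and flags them as such in the report.
    """

    k: int = 10
    n_runs: int = 12
    top_n: int = 10
    min_targets: int = 10
    residual_partitions: tuple = ("train", "val")
    residual_source: str = "best"  # or "ensemble": average residuals over runs
    rank_by: str = "val_r2"
    model_config: ModelConfig | None = None
    train_config: TrainConfig | None = None
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.residual_source not in ("best", "ensemble"):
            raise ValueError(f"unknown residual_source {self.residual_source!r}")


@dataclass
class PipelineResult:
    reports: dict
    selections: dict
    pairwise: dict
    residuals: dict
    mirna_order: list

    def summary(self) -> str:
        lines = [
            "Four-variant comparison (test R^2 over retained runs)",
            "=" * 64,
            f"{'variant':<12}{'runs':>6}{'mean R2':>10}{'95% CI':>22}{'p vs baseline':>14}",
        ]
        for name in VARIANTS:
            rep = self.reports[name]
            p = rep.pairwise_p.get("baseline")
            p_str = "-" if p is None else f"{p:.4g}"
            flag = " (degenerate)" if rep.degenerate else ""
            lines.append(
                f"{rep.variant:<12}{rep.n_runs:>6}{rep.mean_r2:>10.4f}"
                f"{f'[{rep.ci95[0]:.4f}, {rep.ci95[1]:.4f}]':>22}{p_str:>14}{flag}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


def mirna_log_expression(matrix: ExpressionMatrix) -> dict:
    """Per-miRNA log-normalised mean expression across all samples:
    ``log10(mean(counts) + 0.1)``."""
    means = matrix.frame.mean(axis=1)
    return {m: float(lognorm(v)) for m, v in means.items()}


def prepare_model_data(records, features, mirna_expr, targets, split) -> ModelData:
    """Assemble model-ready batches from parsed inputs.

    The miRNA column order is the sorted miRNA ID list of the expression
    matrix; each gene's feature vector carries the log-normalised mean
    expression of the miRNAs that target it, zero elsewhere.
    """
    mirna_order = sorted(mirna_expr.row_ids)
    log_expr = mirna_log_expression(mirna_expr)
    targeting: dict = {}
    for t in targets:
        targeting.setdefault(t.gene_id, set()).add(t.mirna_id)
    expr_vec = np.array([log_expr[m] for m in mirna_order], dtype=np.float32)
    from .encoding import MiRNAFeatureVector

    all_ids = set(split.all_ids)
    vectors = {}
    for g in all_ids:
        mask = np.array([m in targeting.get(g, ()) for m in mirna_order])
        vectors[g] = MiRNAFeatureVector(g, np.where(mask, expr_vec, 0.0).astype(np.float32))
    return assemble_dataset(records, features, vectors, split, mirna_order)


def _run_seed(base_seed: int, run_idx: int) -> int:
    # shared across variants (common random numbers): run i of every variant
    # uses the same seed, so a k=0 "selected" variant reproduces the baseline
    # runs exactly
    return (base_seed * 9_973 + run_idx) % (2**31 - 1)


def _train_variant(
    data: ModelData,
    mirna_ids: Sequence[str],
    variant: str,
    cfg: PipelineConfig,
) -> list:
    """Train ``cfg.n_runs`` models of one variant (resuming from disk when
    possible) and return the run results."""
    sub = data.subset_mirnas(list(mirna_ids))
    template = cfg.model_config or ModelConfig.toy(window=data.window)
    mcfg = replace(template, window=data.window, k_mirnas=len(mirna_ids))
    model = ExpressionCNN(sub, mcfg)
    runs = []
    run_dir = None
    if cfg.out_dir is not None:
        run_dir = Path(cfg.out_dir) / "runs"
        run_dir.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.n_runs):
        path = run_dir / f"{variant}_{i:02d}.json" if run_dir else None
        if path is not None and path.exists():
            runs.append(CNNResults.from_json(path))
            continue
        seed = _run_seed(cfg.seed, i)
        tcfg = replace(cfg.train_config or TrainConfig.toy(), seed=seed)
        result = model.fit(tcfg)
        if path is not None:
            result.to_json(path)
        runs.append(result)
    return runs


def run_pipeline(records, features, mirna_expr, targets, split, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full comparison on parsed inputs and return the variant
    reports, the two selections, and the pairwise significance table."""
    cfg = cfg or PipelineConfig()
    data = prepare_model_data(records, features, mirna_expr, targets, split)
    out = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # stage 1: baseline ensemble
    baseline_runs = _train_variant(data, [], "baseline", cfg)

    # stage 2: residuals from the designated baseline
    key = (lambda r: -r.r2_val) if cfg.rank_by == "val_r2" else (lambda r: r.best_val_loss)
    if cfg.residual_source == "best":
        designated = min(baseline_runs, key=key)
        residuals = residuals_from_baseline(designated, cfg.residual_partitions)
    else:
        maps = [residuals_from_baseline(r, cfg.residual_partitions) for r in baseline_runs]
        genes = maps[0].keys()
        residuals = {g: float(np.mean([m[g] for m in maps])) for g in genes}

    # stage 3: rankings and top-k selection
    selections = {}
    for mode in ("signed", "absolute"):
        if cfg.k == 0:
            selections[mode] = SelectionResult(mode, [], [], 0)
            continue
        selections[mode] = rank_mirnas(
            residuals, targets, mode=mode, min_targets=cfg.min_targets, k=cfg.k
        )
        if out is not None:
            selection_to_tsv(selections[mode], out / f"selection_{mode}.tsv")

    # stage 4: variant ensembles
    variant_mirnas = {
        "all_mirna": list(data.mirna_order),
        "mirex": selections["signed"].selected,
        "abs_corr": selections["absolute"].selected,
    }
    all_runs = {"baseline": baseline_runs}
    for name in ("all_mirna", "mirex", "abs_corr"):
        all_runs[name] = _train_variant(data, variant_mirnas[name], name, cfg)

    # stage 5: aggregation and comparison
    reports = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in VARIANTS:
            reports[name] = aggregate_runs(
                all_runs[name], variant=name, top_n=cfg.top_n, rank_by=cfg.rank_by
            )
    for name in ("mirex", "abs_corr"):
        if cfg.k == 0:
            reports[name].degenerate = True
    pairwise = compare_variants([reports[name] for name in VARIANTS])

    result = PipelineResult(reports, selections, pairwise, residuals, list(data.mirna_order))
    if out is not None:
        _write_report(result, out)
    return result


def _write_report(result: PipelineResult, out: Path) -> None:
    payload = {
        name: {
            "r2_runs": rep.r2_runs,
            "mean_r2": rep.mean_r2,
            "ci95": list(rep.ci95),
            "pairwise_p": rep.pairwise_p,
            "degenerate": rep.degenerate,
        }
        for name, rep in result.reports.items()
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    with open(out / "report.tsv", "w") as fh:
        fh.write("variant\tn_runs\tmean_r2\tci_low\tci_high\tp_vs_baseline\n")
        for name in VARIANTS:
            rep = result.reports[name]
            p = rep.pairwise_p.get("baseline", float("nan"))
            fh.write(
                f"{name}\t{rep.n_runs}\t{rep.mean_r2:.6f}\t{rep.ci95[0]:.6f}\t{rep.ci95[1]:.6f}\t{p:.6g}\n"
            )
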