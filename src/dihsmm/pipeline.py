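"""End-to-end pipeline: fit -> aggregate -> classify, with a run manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .aggregation import AggregationResult, aggregate_chains
from .classification import (
    assign_stages,
    stage_occupancy,
    state_introductions,
    state_session_counts,
    typed_states,
    weight_change_summary,
)
from .config import RunConfig
from .gibbs import ChainSet, run_chains
from .trial_features import build_design, validate_trial_table

__all__ = ["PipelineResult", "run_pipeline"]


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("dihsmm")
    except Exception:
        return "unknown"


@dataclass
class PipelineResult:
    chainset: ChainSet = field(repr=False)
    aggregation: AggregationResult = field(repr=False)
    typed: pd.DataFrame
    stages: pd.DataFrame
    introductions: pd.DataFrame
    slow_changes: pd.DataFrame
    fast_changes: pd.DataFrame
    outdir: Path | None


def run_pipeline(
    config: RunConfig,
    table: pd.DataFrame,
    outdir=None,
    require_converged: bool = True,
) -> PipelineResult:
    """Execute the full analysis on one animal's trial table.

    Stages: design construction, MCMC chains, aggregation into cluster
    states, type/stage classification.  If ``outdir`` is given, every
    artifact is written there along with a manifest that suffices to re-run
    the pipeline bit-identically (config, seeds, package version).
    """
    validate_trial_table(table)
    design = build_design(
        table, steepness=config.hyper.steepness, decay=config.hyper.decay
    )
    chains_cfg = replace(config.chains, seed=config.stage_seed("chains"))

    stage = "fit"
    try:
        chainset = run_chains(design, config.hyper, chains_cfg)
        stage = "aggregate"
        agg = config.aggregation
        result = aggregate_chains(
            chainset,
            design,
            cut=agg.cut,
            n_bins=agg.n_bins,
            min_mode_samples=agg.min_mode_samples,
            min_cluster_frac=agg.min_cluster_frac,
            min_keep=min(agg.min_keep, chains_cfg.n_chains),
            rhat_threshold=agg.rhat_threshold,
            seed=config.stage_seed("aggregate"),
            require_converged=require_converged,
        )
        stage = "classify"
        typed = typed_states(result.pmfs)
        counts = state_session_counts(result.clustering, design)
        stages = assign_stages(counts, typed, design.n_sessions).stages
        intros = state_introductions(result.clustering, design, typed)
        slow, fast = weight_change_summary(typed, result.weights, result.pmfs)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage '{stage}'") from exc

    out = PipelineResult(
        chainset=chainset,
        aggregation=result,
        typed=typed,
        stages=stages,
        introductions=intros,
        slow_changes=slow,
        fast_changes=fast,
        outdir=None,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chainset.save(outdir / "chains.h5")
        clustering = result.clustering
        pd.DataFrame(
            {
                "trial": range(1, design.n_trials + 1),
                "cluster_state": clustering.labels,
                "connectedness": clustering.connectedness,
            }
        ).to_csv(outdir / "clustering.csv", index=False)
        result.pmfs.to_csv(outdir / "pmfs.csv", index=False)
        result.weights.to_csv(outdir / "state_weights.csv", index=False)
        typed.to_csv(outdir / "states_typed.csv", index=False)
        stages.to_csv(outdir / "stages.csv", index=False)
        stage_occupancy(stages).to_csv(outdir / "stage_occupancy.csv", index=False)
        intros.to_csv(outdir / "introductions.csv", index=False)
        slow.to_csv(outdir / "weight_changes_slow.csv", index=False)
        fast.to_csv(outdir / "weight_changes_fast.csv", index=False)
        report = result.report
        with open(outdir / "convergence.json", "w") as fh:
            json.dump(
                {
                    "max_rhat": report.max_rhat,
                    "threshold": report.threshold,
                    "converged": report.converged,
                    "selected_chains": list(map(int, report.selected_chains)),
                    "rhat": report.rhat.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )
        config.to_yaml(outdir / "config.yaml")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "config_digest": config.digest(),
                    "seed": config.seed,
                    "dihsmm_version": _version(),
                    "n_trials": int(design.n_trials),
                    "n_sessions": int(design.n_sessions),
                },
                fh,
                indent=2,
            )
        out.outdir = outdir
    return out
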