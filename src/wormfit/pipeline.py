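"""End-to-end pipeline: simulate (or load) counts, then run every analysis.

The report bundle collects the stages in order: fitness estimators per
plate, within-block variability summaries and mean-variance diagnostics,
split-sample repeatability, and the two headline method-comparison models
(p at replicate level; SD of log CI at block-group level).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .metrics import add_fitness_columns
from .repeatability import split_sample_analysis, split_sample_filter
from .simulate import SimulationConfig, simulate_assay, simulate_split_samples
from .variability import METRICS, group_summaries, mean_variance_diagnostics
from .varmodel import analyze_p, analyze_sd_logci
from .io import write_json, write_observations

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path
    observations_path: str | Path | None = None  # None: simulate
    simulation: SimulationConfig | None = None
    n_split_wells: int = 336
    seed: int = 0
    write_plots: bool = False


def _mean_variance_plot(scatter: dict, corr: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 2, figsize=(8, 10))
    for row, metric in enumerate(METRICS):
        pts = scatter[metric]
        r = corr.loc[corr["metric"] == metric].iloc[0]
        for col, meas in enumerate(("md", "sd")):
            ax = axes[row, col]
            ax.scatter(pts["mean"], pts[meas], s=12, alpha=0.7)
            rr = r["r_mean_md"] if meas == "md" else r["r_mean_sd"]
            ax.set_xlabel(f"mean {metric}")
            ax.set_ylabel(f"{meas.upper()} {metric}")
            ax.set_title(f"r = {rr:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Stage failures abort with the failing stage named; outputs written
    before the failure are retained, with MANIFEST.json marking the run
    incomplete.  Deterministic given (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "complete": False,
        "stages": [],
    }
    report: dict = {}
    t0 = time.time()

    def _stage(name):
        manifest["stages"].append({"name": name, "t_start": time.time() - t0})
        write_json(manifest, out / "MANIFEST.json")

    try:
        _stage("inputs")
        if config.observations_path is not None:
            from .io import read_observations

            obs = read_observations(config.observations_path)
        else:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            obs, truth = simulate_assay(sim)
            truth.to_csv(out / "truth.csv", index=False)
        if obs.empty:
            raise ValueError("empty observation table: nothing to analyze")
        write_observations(obs, out / "observations.csv")

        _stage("metrics")
        est = add_fitness_columns(obs)
        est.to_csv(out / "estimates.csv", index=False)

        _stage("variability")
        summaries = {m: group_summaries(est, m) for m in METRICS}
        for m, s in summaries.items():
            s.to_csv(out / f"summaries_{m}.csv", index=False)
        corr, scatter = mean_variance_diagnostics(summaries)
        corr.to_csv(out / "mean_variance_correlations.csv", index=False)
        report["mean_variance_correlations"] = corr
        if config.write_plots:
            _mean_variance_plot(scatter, corr, out / "mean_variance.png")

        _stage("repeatability")
        sim = config.simulation or SimulationConfig(seed=config.seed)
        splits, _ = simulate_split_samples(sim, config.n_split_wells)
        kept, filt = split_sample_filter(splits)
        split_rep = split_sample_analysis(kept)
        report["split_filter"] = filt
        report["split_analysis"] = split_rep

        _stage("model_p")
        rep_p = analyze_p(est)
        report["f_test_p"] = rep_p["f_test"]
        report["best_model_p"] = rep_p["best_spec"].label()

        _stage("model_sd_logci")
        rep_sd = analyze_sd_logci(est)
        report["f_test_sd_logci"] = rep_sd["f_test"]
        report["best_model_sd_logci"] = rep_sd["best_spec"].label()

        rep_p["model_table"].to_csv(out / "model_table_p.csv", index=False)
        rep_sd["model_table"].to_csv(out / "model_table_sd_logci.csv", index=False)
        write_json(
            {
                k: v
                for k, v in report.items()
                if not isinstance(v, pd.DataFrame)
            }
            | {"mean_variance_correlations": report["mean_variance_correlations"]},
            out / "report.json",
        )
        manifest["complete"] = True
        write_json(manifest, out / "MANIFEST.json")
    except Exception as exc:
        failing = manifest["stages"][-1]["name"] if manifest["stages"] else "init"
        manifest["failed_stage"] = failing
        manifest["error"] = str(exc)
        write_json(manifest, out / "MANIFEST.json")
        raise RuntimeError(f"pipeline failed in stage {failing!r}: {exc}") from exc
    return report
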