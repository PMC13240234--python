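"""End-to-end analysis orchestration.

Given a relocation table, the pipeline preprocesses it into valid
trajectory segments, builds the dataset partitions of interest (per
group across the whole record; both groups pooled within each dietary
period; or the per-group-per-period cross), fits the four candidate
movement models to each dataset, selects by AICc, runs pseudo-residual
diagnostics on the best model, and derives behavioral-state summaries.
Every table is written as CSV next to a JSON dump of the fitted
parameters, so a run is fully reproducible from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geo
from .diagnostics import diagnose
from .inference import MODELS, FitOptions, ModelFit, best_model, fit_model, model_comparison, state_summary
from .likelihoods import Observations

__all__ = ["AnalysisConfig", "ReportBundle", "make_datasets", "run_analysis"]

logger = logging.getLogger("gibbonwalk")


@dataclass
class AnalysisConfig:
    """Everything a run needs; serialized alongside outputs for provenance."""

    input_path: str = ""
    output_dir: str = "gibbonwalk_report"
    utm_zone: int = 49
    max_step_speed: float = 1000.0  # metres per 15-min interval
    gap_tolerance_min: float = 45.0
    min_fixes: int = 4
    min_span_min: float = 60.0
    min_step: float = 0.1
    dataset_mode: str = "by_group_and_period_pooled"
    models: tuple = MODELS
    seed: int = 0
    bins: int = 20
    ci_level: float = 0.95
    compute_cis: bool = False
    min_usable_steps: int = 100
    make_plots: bool = False

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


@dataclass
class ReportBundle:
    """In-memory twin of the written report tables."""

    segmentation_log: pd.DataFrame
    model_comparison: pd.DataFrame
    diagnostics: pd.DataFrame
    state_summary: pd.DataFrame
    fits: dict = field(default_factory=dict)  # dataset -> list[ModelFit]

    def best_fits(self) -> dict:
        return {name: best_model(fits) for name, fits in self.fits.items()}


def make_datasets(segments: list[geo.TrajectorySegment], mode: str) -> dict:
    """Partition segments into the named datasets the reports compare.

    Modes: ``by_group`` (one dataset per group, whole record),
    ``by_period_pooled`` (groups pooled within each dietary period),
    ``by_group_and_period`` (the cross), and
    ``by_group_and_period_pooled`` (union of the first two — the
    structure of the published comparison tables).  A segment belongs
    to the period of its start date.
    """
    by_group: dict[str, list] = {}
    by_period: dict[str, list] = {}
    cross: dict[str, list] = {}
    for s in segments:
        by_group.setdefault(s.group_id, []).append(s)
        by_period.setdefault(s.period.value, []).append(s)
        cross.setdefault(f"{s.group_id}:{s.period.value}", []).append(s)
    if mode == "by_group":
        return by_group
    if mode == "by_period_pooled":
        return by_period
    if mode == "by_group_and_period":
        return cross
    if mode == "by_group_and_period_pooled":
        return {**by_group, **by_period}
    raise ValueError(f"unknown dataset mode {mode!r}")


def observations_for(segments: list[geo.TrajectorySegment], min_step: float = 0.1) -> Observations:
    series = [geo.compute_step_series(s) for s in segments]
    return Observations.from_step_series(series, min_step=min_step)


def run_analysis(config: AnalysisConfig, fixes: pd.DataFrame | None = None,
                 fit_options: FitOptions | None = None) -> ReportBundle:
    """Run the full analysis and write the report bundle.

    ``fixes`` may be passed directly (e.g. from the synthetic
    generator); otherwise ``config.input_path`` is read.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    if fixes is None:
        fixes = geo.read_fixes(config.input_path)
    logger.info("read %d fixes for %d groups", len(fixes), fixes["group_id"].nunique())

    segments, seg_log = geo.preprocess(
        fixes,
        zone=config.utm_zone,
        max_step_speed=config.max_step_speed,
        min_fixes=config.min_fixes,
        min_span_min=config.min_span_min,
        gap_tolerance_min=config.gap_tolerance_min,
    )
    logger.info("retained %d valid segments", len(segments))

    datasets = make_datasets(segments, config.dataset_mode)
    cmp_rows, diag_rows, state_rows = [], [], []
    fits_by_dataset: dict[str, list[ModelFit]] = {}
    fits_json = {}

    for name in sorted(datasets):
        obs = observations_for(datasets[name], min_step=config.min_step)
        if obs.n_steps < config.min_usable_steps:
            warnings.warn(
                f"dataset {name!r} has only {obs.n_steps} steps "
                f"(< {config.min_usable_steps}); skipped"
            )
            continue
        logger.info("fitting dataset %s (%d steps)", name, obs.n_steps)
        fits = [fit_model(obs, m, seed=config.seed, options=fit_options)
                for m in config.models]
        fits_by_dataset[name] = fits
        cmp = model_comparison(fits)
        cmp.insert(0, "dataset", name)
        cmp_rows.append(cmp)

        best = best_model(fits)
        row = {"dataset": name, **diagnose(obs, best, bins=config.bins)}
        diag_rows.append(row)

        if best.model in ("CCRWo", "CCRWp"):
            ss = state_summary(best.params)
            state_rows.append(
                {
                    "dataset": name,
                    "model": best.model,
                    "pI": ss.p_i,
                    "pE": ss.p_e,
                    "sI": ss.s_i,
                    "sE": ss.s_e,
                    "rE": ss.r_e,
                }
            )
        fits_json[name] = [f.to_dict() for f in fits]

        if config.make_plots:
            _plot_dataset(out, name, obs, fits)

    bundle = ReportBundle(
        segmentation_log=seg_log,
        model_comparison=(
            pd.concat(cmp_rows, ignore_index=True) if cmp_rows else pd.DataFrame()
        ),
        diagnostics=pd.DataFrame(diag_rows),
        state_summary=pd.DataFrame(state_rows),
        fits=fits_by_dataset,
    )
    bundle.segmentation_log.to_csv(out / "segmentation_log.csv", index=False)
    bundle.model_comparison.to_csv(out / "model_comparison.csv", index=False)
    bundle.diagnostics.to_csv(out / "diagnostics.csv", index=False)
    bundle.state_summary.to_csv(out / "state_summary.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=2)
    return bundle


def _plot_dataset(out: Path, name: str, obs: Observations, fits: list[ModelFit]):
    """Step/angle histograms overlaid with each fitted marginal density."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .inference import state_summary as _ss

    steps = obs.all_steps()
    angles = obs.all_angles()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.hist(steps, bins=40, density=True, color="0.7")
    xs = np.linspace(steps.min(), np.quantile(steps, 0.995), 400)
    ax2.hist(angles, bins=36, density=True, color="0.7")
    th = np.linspace(-np.pi, np.pi, 400)
    for f in fits:
        p = f.params
        if f.model in ("BW", "TLW"):
            ax1.plot(xs, p.step.pdf(xs), label=f.model)
            ax2.plot(th, np.full_like(th, 1.0 / (2 * np.pi)), label=f.model)
        else:
            ss = _ss(p)
            w = np.array([ss.p_i, ss.p_e])
            ax1.plot(
                xs,
                w[0] * np.exp(p.step_i.logpdf(xs)) + w[1] * np.exp(p.step_e.logpdf(xs)),
                label=f.model,
            )
            if f.model == "CCRWp":
                dens = w[0] * p.angle_i.pdf(th) + w[1] * p.angle_e.pdf(th)
            else:
                dens = w[0] / (2 * np.pi) + w[1] * p.angle_e.pdf(th)
            ax2.plot(th, dens, label=f.model)
    ax1.set_xlabel("step length (m)")
    ax2.set_xlabel("turning angle (rad)")
    ax1.legend(fontsize=8)
    fig.suptitle(name)
    fig.tight_layout()
    fig.savefig(out / f"distributions_{name.replace(':', '_')}.png", dpi=120)
    plt.close(fig)
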