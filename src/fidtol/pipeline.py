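"""End-to-end pipeline: simulate -> fit -> decompose -> compare -> report.

Each stage writes plain-text artifacts (CSV/JSON) into the output directory;
:func:`run_pipeline` sequences them and emits a ``report.json`` manifest with
paths, the seed, a stable config hash and package versions, so a run is
fully reproducible from its config file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .comparison import compare_identity_models
from .config import SamplerSettings, SimulationConfig, config_hash, load_config
from .model import BivariateToleranceModel, ToleranceModel, ToleranceResults
from .responses import tally_responses
from .simulate import simulate_dataset, split_by_trial_parity, write_trials
from .variance import (
    among_individual_correlation,
    conditional_modes_table,
    enhanced_icc,
    variance_components,
)

log = logging.getLogger("fidtol")


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    sampler: SamplerSettings = Field(default_factory=lambda: SamplerSettings(chains=2, iterations=1200, warmup=400))
    output_dir: str = "fidtol_output"
    icc_include_fixed: bool = True
    icc_include_date: bool = True
    split_parity_validation: bool = False
    figures: bool = False


@dataclass
class PipelineReport:
    """Manifest of a pipeline run: artifact paths plus run metadata."""

    paths: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {"paths": self.paths, "metadata": self.metadata}
        pathlib.Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineReport":
        payload = json.loads(pathlib.Path(path).read_text())
        return cls(paths=payload["paths"], metadata=payload["metadata"])


def _versions() -> dict[str, str]:
    import arviz
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "fidtol": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "arviz": arviz.__version__,
    }


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload: dict, path: pathlib.Path) -> None:
    path.write_text(json.dumps(payload, indent=2) + "\n")


def stage_simulate(cfg: PipelineConfig, outdir: pathlib.Path, report: PipelineReport) -> pd.DataFrame:
    log.info("simulating %d individuals x %d trials/observer x 2 observers",
             cfg.simulation.n_individuals, cfg.simulation.trials_per_observer)
    trials, truth = simulate_dataset(cfg.simulation)
    p = outdir / "trials.csv"
    write_trials(trials, p)
    truth.to_csv(outdir / "truth_individual_effects.csv")
    report.paths["trials"] = str(p)
    report.paths["truth_individual_effects"] = str(outdir / "truth_individual_effects.csv")
    report.metadata["trials_sha256"] = _sha256(p)
    report.metadata["n_trials"] = int(len(trials))
    return trials


def stage_tally(trials: pd.DataFrame, outdir: pathlib.Path, report: PipelineReport) -> None:
    tally = tally_responses(trials)
    tally.to_csv(outdir / "response_tally.csv")
    report.paths["response_tally"] = str(outdir / "response_tally.csv")


def stage_fit(
    trials: pd.DataFrame, cfg: PipelineConfig, outdir: pathlib.Path, report: PipelineReport
) -> dict[str, ToleranceResults]:
    fits = {}
    for resp in ("vod", "fid"):
        log.info("fitting univariate %s model (%d chains x %d iterations)",
                 resp.upper(), cfg.sampler.chains, cfg.sampler.iterations)
        fit = ToleranceModel(trials, response=resp).fit(cfg.sampler)
        fits[resp] = fit
        fit.summary().to_csv(outdir / f"{resp}_summary.csv", index=False)
        (outdir / f"{resp}_diagnostics.json").write_text(fit.diagnostics_json())
        fit.tidy_draws().to_csv(outdir / f"{resp}_draws.csv", index=False)
        report.paths[f"{resp}_summary"] = str(outdir / f"{resp}_summary.csv")
        report.paths[f"{resp}_diagnostics"] = str(outdir / f"{resp}_diagnostics.json")
        report.paths[f"{resp}_draws"] = str(outdir / f"{resp}_draws.csv")
        report.metadata[f"{resp}_converged"] = bool(fit.converged)
    return fits


def stage_icc(
    fits: dict[str, ToleranceResults], cfg: PipelineConfig, outdir: pathlib.Path, report: PipelineReport
) -> None:
    for resp, fit in fits.items():
        vc = variance_components(fit)
        enhanced = enhanced_icc(vc, include_fixed=cfg.icc_include_fixed, include_date=cfg.icc_include_date)
        vc0 = variance_components(fit, intercept_only=True)
        classical = enhanced_icc(vc0, include_fixed=False, include_date=False)
        payload = {
            "enhanced_agreement": enhanced.to_dict(),
            "intercept_only_vs_residual": classical.to_dict(),
        }
        _write_json(payload, outdir / f"icc_{resp}.json")
        report.paths[f"icc_{resp}"] = str(outdir / f"icc_{resp}.json")
        log.info("%s ICC: enhanced %.3f [%.3f, %.3f]; intercept/residual %.3f",
                 resp.upper(), enhanced.mean, enhanced.hdi_low, enhanced.hdi_high, classical.mean)


def stage_bivariate(
    trials: pd.DataFrame, cfg: PipelineConfig, outdir: pathlib.Path, report: PipelineReport
) -> ToleranceResults:
    if cfg.split_parity_validation:
        even, odd = split_by_trial_parity(trials)
        log.info("fitting bivariate model on parity split (VOD: even half, FID: odd half)")
        model = BivariateToleranceModel(vod_data=even, fid_data=odd)
    else:
        log.info("fitting bivariate model (shared individual block)")
        model = BivariateToleranceModel(trials)
    fit = model.fit(cfg.sampler)
    fit.summary().to_csv(outdir / "bivariate_summary.csv", index=False)
    corr = among_individual_correlation(fit)
    _write_json(corr.to_dict(), outdir / "among_individual_correlation.json")
    modes = conditional_modes_table(fit)
    modes.to_csv(outdir / "conditional_modes.csv", index=False)
    report.paths["bivariate_summary"] = str(outdir / "bivariate_summary.csv")
    report.paths["among_individual_correlation"] = str(outdir / "among_individual_correlation.json")
    report.paths["conditional_modes"] = str(outdir / "conditional_modes.csv")
    report.metadata["bivariate_converged"] = bool(fit.converged)
    log.info("among-individual correlation %.3f [%.3f, %.3f]", corr.mean, corr.hdi_low, corr.hdi_high)
    return fit


def stage_stacking(
    trials: pd.DataFrame,
    fits: dict[str, ToleranceResults],
    cfg: PipelineConfig,
    outdir: pathlib.Path,
    report: PipelineReport,
) -> None:
    for resp, fit in fits.items():
        log.info("stacking %s model with vs without individual identity", resp.upper())
        comp = compare_identity_models(trials, response=resp, settings=cfg.sampler, fit_with=fit)
        (outdir / f"stacking_{resp}.json").write_text(comp.to_json() + "\n")
        report.paths[f"stacking_{resp}"] = str(outdir / f"stacking_{resp}.json")
        log.info("%s stacking weight with identity: %.3f", resp.upper(), comp.weight_with)


def stage_effects(
    fits: dict[str, ToleranceResults], outdir: pathlib.Path, report: PipelineReport
) -> None:
    for resp, fit in fits.items():
        eff = fit.conditional_effects()
        eff.to_csv(outdir / f"conditional_effects_{resp}.csv", index=False)
        report.paths[f"conditional_effects_{resp}"] = str(outdir / f"conditional_effects_{resp}.csv")


def stage_figures(outdir: pathlib.Path, report: PipelineReport) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    modes = pd.read_csv(report.paths["conditional_modes"])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(modes["vod_mode"], modes["fid_mode"], s=18)
    ax.set_xlabel("visual tolerance (VOD intercept deviation, log scale)")
    ax.set_ylabel("displacement tolerance (FID intercept deviation, log scale)")
    fig.tight_layout()
    fig.savefig(outdir / "conditional_modes.png", dpi=150)
    plt.close(fig)
    report.paths["conditional_modes_figure"] = str(outdir / "conditional_modes.png")


def run_pipeline(
    config: PipelineConfig | str | pathlib.Path,
    output_dir: str | None = None,
    data: pd.DataFrame | None = None,
) -> PipelineReport:
    """Run all stages; returns the report manifest (also written as JSON).

    ``data`` may supply a user trial table (CSV already loaded) in place of
    the simulation stage.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config, PipelineConfig)
    outdir = pathlib.Path(output_dir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    t0 = time.time()
    report.metadata.update(
        {
            "seed": cfg.simulation.seed,
            "sampler_seed": cfg.sampler.seed,
            "config_hash": config_hash(cfg),
            "versions": _versions(),
        }
    )
    if data is None:
        trials = stage_simulate(cfg, outdir, report)
    else:
        trials = data
        p = outdir / "trials.csv"
        write_trials(trials, p)
        report.paths["trials"] = str(p)
        report.metadata["trials_sha256"] = _sha256(p)
        report.metadata["n_trials"] = int(len(trials))
    stage_tally(trials, outdir, report)
    fits = stage_fit(trials, cfg, outdir, report)
    stage_icc(fits, cfg, outdir, report)
    stage_bivariate(trials, cfg, outdir, report)
    stage_stacking(trials, fits, cfg, outdir, report)
    stage_effects(fits, outdir, report)
    if cfg.figures:
        stage_figures(outdir, report)
    report.metadata["runtime_s"] = round(time.time() - t0, 2)
    report.paths["report"] = str(outdir / "report.json")
    report.save(outdir / "report.json")
    log.info("pipeline complete in %.1f s; report at %s", report.metadata["runtime_s"], outdir / "report.json")
    return report
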