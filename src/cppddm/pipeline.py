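"""End-to-end orchestration: simulate or load data, screen, decompose EEG,
extract covariates, fit the model family, and report.

Every run writes a manifest (config, seed, package version), all
intermediate tables, and a Markdown report with posterior summaries,
convergence diagnostics and the DIC comparison table, so that any output
is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hbm import (
    MODEL_TABLE,
    SamplerSettings,
    build_model,
    compare_models,
    compute_dic,
    gelman_rubin,
    sample_posterior,
)
from .io import write_behavior, write_report
from .rca import fit_rca, project_components
from .screening import EWMAConfig, apply_basic_exclusions, apply_ewma, screen_participants
from .simulate import EEGSimSpec, SimConfig, gen_behavior, gen_eeg
from .slopes import (
    RegressionWindow,
    covariate_table,
    participant_slope,
    smooth_waveform,
    window_component1,
    window_component2,
)

__all__ = ["RunConfig", "run_pipeline"]

#: windows used when data-driven detection fails on a small noisy cohort;
#: spans the generative trough-to-peak interval of the biphasic component
#: and the core ramp of the centro-parietal component
FALLBACK_WINDOWS = {
    1: RegressionWindow(-300.0, -20.0, component=1, group="fallback"),
    2: RegressionWindow(-250.0, -20.0, component=2, group="fallback"),
}


@dataclass
class RunConfig:
    mode: str = "simulate"  # or "analyze"
    out_dir: str = "results/run"
    behavior_csv: str | None = None
    eeg_h5: str | None = None
    seed: int = 0
    models: tuple = ("model1", "model4", "model6", "model7")
    with_eeg: bool = True
    # simulate-mode cohort
    n_participants: int = 16
    n_trials_per_condition: int = 40
    contaminant_prop: float = 0.1
    covariate_effects: dict = field(
        default_factory=lambda: {("delta", "age"): 0.45, ("alpha", "age"): -0.10}
    )
    n_electrodes: int = 16
    # stage settings
    ewma: EWMAConfig = field(default_factory=EWMAConfig)
    min_retained: float = 0.6
    sampler: SamplerSettings = field(
        default_factory=lambda: SamplerSettings(
            n_chains=3, n_samples=1_700, n_burnin=500, thin=1
        )
    )
    strict_rhat: float | None = None

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"mode must be 'simulate' or 'analyze', got {self.mode!r}")
        bad = [m for m in self.models if m not in MODEL_TABLE]
        if bad:
            raise ValueError(f"unknown model labels: {bad}")
        if self.mode == "analyze":
            if not self.behavior_csv or not Path(self.behavior_csv).exists():
                raise ValueError(f"behaviour CSV not found: {self.behavior_csv}")
            if self.with_eeg and (not self.eeg_h5 or not Path(self.eeg_h5).exists()):
                raise ValueError(f"EEG HDF5 not found: {self.eeg_h5}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "ewma" in raw:
            raw["ewma"] = EWMAConfig(**raw["ewma"])
        if "sampler" in raw:
            raw["sampler"] = SamplerSettings(**raw["sampler"])
        if "covariate_effects" in raw:
            raw["covariate_effects"] = {
                (k.split(":")[0], k.split(":")[1]): v for k, v in raw["covariate_effects"].items()
            }
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _manifest(config: RunConfig) -> dict:
    cfg = {
        k: (str(v) if not isinstance(v, (int, float, str, bool, type(None), list, tuple)) else v)
        for k, v in vars(config).items()
    }
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a result bundle dict.

    Stages: acquire data -> structural exclusions -> EWMA fast-guess
    filter -> participant retention -> (EEG: RCA -> windows -> slopes)
    -> hierarchical model fits -> diagnostics -> DIC comparison ->
    Markdown report.  Failures abort with the stage name; partial outputs
    stay on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    bundle: dict = {}
    stage = "setup"
    try:
        (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=1))

        stage = "data"
        if config.mode == "simulate":
            sim = SimConfig(
                n_participants=config.n_participants,
                n_trials_per_condition=config.n_trials_per_condition,
                covariate_effects=config.covariate_effects,
                contaminant_prop=config.contaminant_prop,
                seed=config.seed,
            )
            trials, truth = gen_behavior(sim)
            truth.to_csv(out / "truth_behavior.csv", index=False)
            write_behavior(trials, out / "behavior.csv")
        else:
            from .io import read_behavior

            trials = read_behavior(config.behavior_csv)
            truth = None
        log.append(f"data: {len(trials)} trials, "
                   f"{trials['participant_id'].nunique()} participants")

        stage = "screening"
        screened, excl_report = apply_basic_exclusions(trials)
        write_report(excl_report, out / "exclusions")
        for pid, row in excl_report.iterrows():
            if row["n_removed"]:
                log.append(f"screening: {pid}: removed {row['n_removed']} "
                           f"(catch {row['n_catch']}, timeout {row['n_timeout']}, "
                           f"excluded coherence {row['n_excluded_coherence']})")
        kept, ewma_report = apply_ewma(screened, config.ewma)
        write_report(ewma_report, out / "ewma")
        for pid, row in ewma_report.iterrows():
            log.append(f"ewma: {pid}: retained {100 * row['retained_fraction']:.1f}% "
                       f"(cutoff rt {row['cutoff_rt']})")
        final, part_report = screen_participants(kept, ewma_report, config.min_retained)
        write_report(part_report, out / "participants")
        n_drop = int(part_report["dropped"].sum())
        log.append(f"participants: dropped {n_drop} of {len(part_report)}")
        write_behavior(final, out / "behavior_screened.csv")
        bundle["behavior"] = final
        bundle["ewma_report"] = ewma_report
        bundle["participant_report"] = part_report

        stage = "eeg"
        covariates = None
        if config.with_eeg:
            if config.mode == "simulate":
                eeg_spec = EEGSimSpec(n_electrodes=config.n_electrodes)
                epochs, slope_truth = gen_eeg(final.reset_index(drop=True), eeg_spec,
                                              seed=config.seed, truth=truth)
                slope_truth.to_csv(out / "truth_eeg.csv", index=False)
            else:
                from .epochs import EEGEpochArray

                epochs = EEGEpochArray.from_hdf5(config.eeg_h5)
            dec = fit_rca(epochs, n_components=2)
            log.append("rca: reliability "
                       + ", ".join(f"{r:.4f}" for r in dec.reliability)
                       + "; explained "
                       + ", ".join(f"{e:.2f}" for e in dec.explained_reliability_fraction))
            proj = project_components(epochs, dec.weights)
            g1 = np.nanmean(proj[:, 0, :], axis=0)
            g2 = np.nanmean(proj[:, 1, :], axis=0)
            windows = {}
            for comp, g in ((1, g1), (2, g2)):
                sm = smooth_waveform(epochs.time_ms, g)
                try:
                    fn = window_component1 if comp == 1 else window_component2
                    windows[comp] = fn(epochs.time_ms, sm)
                except ValueError as e:
                    warnings.warn(f"component {comp} window detection failed ({e}); "
                                  "using fallback window")
                    windows[comp] = FALLBACK_WINDOWS[comp]
                log.append(f"window c{comp}: {windows[comp].start_ms:.0f}.."
                           f"{windows[comp].end_ms:.0f} ms")
            pid_arr = final["participant_id"].to_numpy()
            pids = sorted(final["participant_id"].unique())
            ages = final.groupby("participant_id")["age_years"].first().loc[pids]
            s1 = [participant_slope(epochs.time_ms,
                                    np.nanmean(proj[pid_arr == p, 0, :], axis=0), windows[1])
                  for p in pids]
            s2 = [participant_slope(epochs.time_ms,
                                    np.nanmean(proj[pid_arr == p, 1, :], axis=0), windows[2])
                  for p in pids]
            covariates = covariate_table(pids, ages.to_numpy(), s1, s2)
            covariates.to_csv(out / "covariates.csv", index=False)
            bundle["rca"] = dec
            bundle["windows"] = windows
            bundle["covariates"] = covariates
        elif any(c in covs for covs in
                 (MODEL_TABLE[m].covariate_map.values() for m in config.models)
                 for c in ("eeg1", "eeg2")):
            raise ValueError("EEG covariate models requested but with_eeg is false")

        if covariates is None and "age_years" in final.columns:
            from .slopes import zstandardize

            pids = sorted(final["participant_id"].unique())
            ages = final.groupby("participant_id")["age_years"].first().loc[pids]
            covariates = pd.DataFrame({"participant_id": pids,
                                       "age": zstandardize(ages.to_numpy())})

        stage = "modelling"
        fits = {}
        rhat_rows = []
        settings = config.sampler
        for label in config.models:
            spec = MODEL_TABLE[label]
            graph = build_model(spec, final, covariates)
            samples = sample_posterior(
                graph, SamplerSettings(settings.n_chains, settings.n_samples,
                                       settings.n_burnin, settings.thin, config.seed)
            )
            samples.to_hdf5(out / f"posterior_{label}.h5")
            rh = gelman_rubin(samples)
            rhat_rows.append({"model": label, "rhat_max": float(rh.max()),
                              "rhat_median": float(rh.median())})
            log.append(f"fit {label}: DIC {compute_dic(samples)[0]:.1f}, "
                       f"max Rhat {rh.max():.3f}")
            fits[label] = samples
        bundle["fits"] = fits
        rhat_df = pd.DataFrame(rhat_rows).set_index("model")
        if config.strict_rhat is not None and rhat_df["rhat_max"].max() > config.strict_rhat:
            raise RuntimeError(
                f"convergence failure: max Rhat {rhat_df['rhat_max'].max():.3f} "
                f"exceeds {config.strict_rhat}"
            )

        stage = "comparison"
        table = compare_models(list(fits.values())) if len(fits) > 1 else None
        if table is not None:
            table.to_csv(out / "dic_table.csv", index=False)
            bundle["dic_table"] = table

        stage = "report"
        report = ["# Pipeline run report", "",
                  f"seed: {config.seed}; mode: {config.mode}; version {__version__}", "",
                  "## Stage log", ""]
        report += [f"- {line}" for line in log]
        if fits:
            report += ["", "## Posterior summaries (group level)", ""]
            for label, samples in fits.items():
                report.append(f"### {label}")
                report.append("")
                report.append(samples.summary().round(4).to_markdown())
                report.append("")
        if table is not None:
            report += ["## DIC comparison", "", table.round(2).to_markdown(index=False), ""]
        (out / "report.md").write_text("\n".join(report))
        bundle["log"] = log
        return bundle
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
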