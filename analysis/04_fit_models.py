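"""Fit the hierarchical diffusion model family to the screened child
cohort: the no-covariate baseline (model 1), the age models (3, 4) and
the EEG-covariate models (6, 7), saving posterior draws and convergence
diagnostics.

Run:  python analysis/04_fit_models.py [seed]
(requires results/ from the previous steps; ~5 minutes)
"""

import sys
from pathlib import Path

import pandas as pd

from cppddm.hbm import MODEL_TABLE, SamplerSettings, build_model, gelman_rubin, sample_posterior
from cppddm.io import read_behavior

OUT = Path("results/fits")
MODELS = ("model1", "model3", "model4", "model6", "model7")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trials = read_behavior(Path("results/screening/behavior_children_screened.csv"))
    cov = pd.read_csv(Path("results/eeg/covariates_children.csv"))

    settings = SamplerSettings(n_chains=3, n_samples=2_000, n_burnin=500, thin=1, seed=seed)
    for label in MODELS:
        graph = build_model(MODEL_TABLE[label], trials, cov)
        samples = sample_posterior(graph, settings)
        samples.to_hdf5(OUT / f"posterior_{label}.h5")
        summ = samples.summary()
        summ.to_csv(OUT / f"summary_{label}.csv")
        rh = gelman_rubin(samples)
        line = (f"{label}: mu_delta {summ.loc['mu_delta', 'mean']:.2f}, "
                f"mu_alpha {summ.loc['mu_alpha', 'mean']:.2f}, "
                f"mu_tau {summ.loc['mu_tau', 'mean']:.2f}; max Rhat {rh.max():.3f}")
        for name in summ.index:
            if name.startswith("b_"):
                line += f"; {name} {summ.loc[name, 'mean']:.2f} (sd {summ.loc[name, 'sd']:.2f})"
        print(line)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
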