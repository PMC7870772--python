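"""DIC model comparison over the fitted family and a posterior-predictive
check of the winning model: does the covariate structure that generated
the data (age on drift and boundary) win, and do the predictive RT
quantiles and accuracies bracket the observed data?

Run:  python analysis/05_compare_models.py
(requires results/fits/ from 04_fit_models.py)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cppddm.hbm import MODEL_TABLE, build_model, compare_models, posterior_predictive, sample_posterior
from cppddm.hbm.sampler import PosteriorSamples
from cppddm.io import read_behavior

OUT = Path("results/comparison")
MODELS = ("model1", "model3", "model4", "model6", "model7")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    trials = read_behavior(Path("results/screening/behavior_children_screened.csv"))
    cov = pd.read_csv(Path("results/eeg/covariates_children.csv"))

    fits = []
    for label in MODELS:
        s = PosteriorSamples.from_hdf5(Path("results/fits") / f"posterior_{label}.h5")
        # re-attach the model graph (not serialised) for DIC computation
        s.graph = build_model(MODEL_TABLE[label], trials, cov)
        fits.append(s)

    table = compare_models(fits)
    table.to_csv(OUT / "dic_table.csv", index=False)
    print(table[["model", "covariates", "dic", "delta_dic"]].round(1).to_string(index=False))
    best = fits[[s.metadata["model"] for s in fits].index(table.iloc[0]["model"])]
    print(f"\nbest model by DIC: {table.iloc[0]['model']}")

    reps, obs = posterior_predictive(best, trials, n_rep=30, seed=0)
    merged = reps.merge(obs, on=["participant_id", "coherence_pct"], suffixes=("_rep", "_obs"))
    cover = []
    for col in ("accuracy", "q10", "q50", "q90"):
        lo = merged.groupby(["participant_id", "coherence_pct"])[f"{col}_rep"].quantile(0.025)
        hi = merged.groupby(["participant_id", "coherence_pct"])[f"{col}_rep"].quantile(0.975)
        o = obs.set_index(["participant_id", "coherence_pct"])[col]
        cover.append(((o >= lo) & (o <= hi)).mean())
        print(f"posterior predictive: observed {col} inside central 95% band "
              f"in {100 * cover[-1]:.0f}% of cells")


if __name__ == "__main__":
    main()
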