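"""EEG analysis for the child cohort: generate response-locked epochs tied
to the screened behaviour, clean them, run reliable components analysis,
select the group regression windows and extract per-participant ramp
slopes as model covariates.

Run:  python analysis/03_eeg_components.py [seed]
(requires results/ from the previous steps)
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cppddm.io import read_behavior
from cppddm.preprocess import preprocess_pipeline
from cppddm.rca import fit_rca, project_components
from cppddm.simulate import EEGSimSpec, gen_eeg
from cppddm.slopes import (
    covariate_table,
    participant_slope,
    smooth_waveform,
    window_component1,
    window_component2,
)

OUT = Path("results/eeg")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    final = read_behavior(Path("results/screening/behavior_children_screened.csv"))
    truth = pd.read_csv(Path("results/cohorts/truth_children.csv"))
    final = final.reset_index(drop=True)

    spec = EEGSimSpec(n_electrodes=32)
    epochs, slope_truth = gen_eeg(final, spec, seed=seed, truth=truth)
    epochs, trial_report = preprocess_pipeline(epochs)
    kept_rows = final.loc[epochs.trial_index].reset_index(drop=True)
    print(f"preprocessing kept {epochs.n_trials}/{len(final)} trials")

    dec = fit_rca(epochs, n_components=2)
    print("reliability eigenvalues:", np.round(dec.reliability, 4),
          "| explained fractions:", np.round(dec.explained_reliability_fraction, 2))

    proj = project_components(epochs, dec.weights)
    g1 = smooth_waveform(epochs.time_ms, np.nanmean(proj[:, 0, :], axis=0))
    g2 = smooth_waveform(epochs.time_ms, np.nanmean(proj[:, 1, :], axis=0))
    w1 = window_component1(epochs.time_ms, g1, group="children")
    w2 = window_component2(epochs.time_ms, g2, group="children")
    print(f"regression windows: c1 {w1.start_ms:.0f}..{w1.end_ms:.0f} ms, "
          f"c2 {w2.start_ms:.0f}..{w2.end_ms:.0f} ms")

    pids = sorted(kept_rows["participant_id"].unique())
    pid_arr = kept_rows["participant_id"].to_numpy()
    ages = kept_rows.groupby("participant_id")["age_years"].first().loc[pids]
    s1 = [participant_slope(epochs.time_ms,
                            np.nanmean(proj[pid_arr == p, 0, :], axis=0), w1) for p in pids]
    s2 = [participant_slope(epochs.time_ms,
                            np.nanmean(proj[pid_arr == p, 1, :], axis=0), w2) for p in pids]
    cov = covariate_table(pids, ages.to_numpy(), s1, s2)
    cov.to_csv(OUT / "covariates_children.csv", index=False)

    st = slope_truth.set_index("participant_id").loc[pids]
    r_true = np.corrcoef(cov["slope_c1"], st["slope_c1_true"])[0, 1]
    r_age1 = np.corrcoef(cov["slope_c1"], cov["age_years"])[0, 1]
    r_age2 = np.corrcoef(cov["slope_c2"], cov["age_years"])[0, 1]
    print(f"extracted c1 slope vs truth: r = {r_true:.2f}")
    print(f"slope-age correlations: c1 r = {r_age1:.2f}, c2 r = {r_age2:.2f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
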