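"""Simulate the study cohorts: a child-like group (ages 6-12.9, age effects
on drift and boundary) and an adult-like group, each with 10% fast-guess
contaminants, and write the tidy trial tables plus ground truth under
results/cohorts/.

Run:  python analysis/01_simulate_cohorts.py [seed]
"""

import sys
from pathlib import Path

from cppddm.io import write_behavior
from cppddm.simulate import ADULT_TRUTH, SimConfig, gen_behavior

OUT = Path("results/cohorts")

CHILD_CFG = dict(
    n_participants=24,
    n_trials_per_condition=40,
    covariate_effects={("delta", "age"): 0.45, ("alpha", "age"): -0.10},
    contaminant_prop=0.10,
    group_label="children",
)
ADULT_CFG = dict(
    n_participants=10,
    ages=(19.0, 35.0),
    n_trials_per_condition=40,
    group_hyperparams=ADULT_TRUTH,
    contaminant_prop=0.05,
    group_label="adults",
)


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, kw in (("children", CHILD_CFG), ("adults", ADULT_CFG)):
        trials, truth = gen_behavior(SimConfig(seed=seed, **kw))
        write_behavior(trials, OUT / f"behavior_{label}.csv")
        truth.to_csv(OUT / f"truth_{label}.csv", index=False)
        acc = trials["correct"].mean()
        med = trials.groupby("participant_id")["rt_s"].median().mean()
        print(
            f"{label}: {trials['participant_id'].nunique()} participants, "
            f"{len(trials)} trials, accuracy {acc:.3f}, "
            f"mean median RT {med:.3f} s"
        )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
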