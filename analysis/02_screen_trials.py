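"""Screen the simulated cohorts: structural exclusions, the EWMA
fast-guess filter (lambda 0.1, limit width 1.5 SD) and the participant
retention rules, reporting how much each stage removes and how many of
the known contaminant trials the EWMA cutoff catches.

Run:  python analysis/02_screen_trials.py
(requires results/cohorts/ from 01_simulate_cohorts.py)
"""

from pathlib import Path

import pandas as pd

from cppddm.io import read_behavior, write_behavior, write_report
from cppddm.screening import apply_basic_exclusions, apply_ewma, screen_participants

IN = Path("results/cohorts")
OUT = Path("results/screening")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label in ("children", "adults"):
        trials = read_behavior(IN / f"behavior_{label}.csv")
        screened, excl = apply_basic_exclusions(trials)
        kept, ewma_rep = apply_ewma(screened)
        final, part = screen_participants(kept, ewma_rep)
        write_behavior(final, OUT / f"behavior_{label}_screened.csv")
        write_report(ewma_rep, OUT / f"ewma_{label}")
        write_report(part, OUT / f"participants_{label}")

        frac = ewma_rep["retained_fraction"]
        print(f"{label}: EWMA retained mean {100 * frac.mean():.1f}% "
              f"(range {100 * frac.min():.1f}-{100 * frac.max():.1f}%); "
              f"dropped {int(part['dropped'].sum())} participants")
        if "is_contaminant" in screened.columns:
            contam = screened["is_contaminant"]
            if contam.any():
                caught = contam & ~screened.index.isin(kept.index)
                print(f"  contaminants: {int(contam.sum())} injected, "
                      f"{int(caught.sum())} removed by the EWMA cutoff "
                      f"({100 * caught.sum() / contam.sum():.0f}%)")


if __name__ == "__main__":
    main()
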