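import numpy as np
import pandas as pd
import pytest

from cppddm.simulate import SimConfig, gen_behavior


@pytest.fixture(scope="session")
def small_cohort():
    """A small child-like cohort with an age effect on drift, shared by
    tests that only need plausible screened data."""
    cfg = SimConfig(
        n_participants=8,
        n_trials_per_condition=24,
        covariate_effects={("delta", "age"): 0.45},
        seed=11,
    )
    return gen_behavior(cfg)


@pytest.fixture()
def toy_trials():
    """Hand-built trial table for screening logic tests."""
    return pd.DataFrame(
        {
            "participant_id": ["p1"] * 10,
            "group": "children",
            "age_years": 8.0,
            "coherence_pct": [30, 50, 75, 10, 10, 10, 30, 50, 100, 100],
            "direction": ["up"] * 10,
            "choice": ["up"] * 9 + ["down"],
            "rt_s": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 2.6, 0.55, 0.55, 0.6],
            "is_catch": [False] * 8 + [True, True],
            "trial_index": range(10),
        }
    )
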